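"""Per-locus case-control / onset / survival scans."""


import numpy as np
import pandas as pd
import pytest

from l1burden.assoc import casecontrol_scan, forest_table, onset_scan, survival_scan
from l1burden.design import complete_case, covariate_design
from l1burden.simulate import focused_config, simulate_cohort
from l1burden.stats import fit_logistic
from l1burden.types import GenotypeMatrix


def _planted(seed, **cfg):
    return simulate_cohort(focused_config(**cfg), seed=seed)


def _locus_column(cohort, locus_id):
    return cohort.geno.subset(loci=[locus_id])


def test_additive_equals_carrier_when_no_homozygotes():
    """For a rare locus with no Present/Present genotypes the additive scan
    coincides exactly with an explicit carrier-coded logistic fit."""
    cohort = _planted(21)
    # build a locus guaranteed free of homozygote-Present calls
    rng = np.random.default_rng(0)
    phen = cohort.phen
    n = len(phen)
    g = (rng.random(n) < 0.05).astype(np.int8)  # 0/1 only
    geno = GenotypeMatrix(list(phen["sample_id"]), ["rare"], g[:, None])
    scan = casecontrol_scan(geno, phen)
    row = scan.iloc[0]

    df = complete_case(phen, ["sex", "age_years", "seq_prep"])
    X, names = covariate_design(df, ["sex", "age_years", "seq_prep"])
    keep = geno.sample_index(df["sample_id"])
    carrier = (g[keep] > 0).astype(float)
    fit = fit_logistic(df["diagnosis"].isin(["ALS", "ALSND"]).to_numpy(float),
                       np.column_stack([X, carrier]), names=names + ["carrier"])
    assert row["odds_ratio"] == pytest.approx(np.exp(fit.coef("carrier")), rel=1e-10)


def test_casecontrol_recovers_planted_or():
    ests, ses = [], []
    for seed in range(8):
        cohort = _planted(seed, cc_log_or=np.log(1.5))
        scan = casecontrol_scan(_locus_column(cohort, cohort.truth["cc_locus_id"]), cohort.phen)
        ests.append(np.log(scan.iloc[0]["odds_ratio"]))
        ses.append((np.log(scan.iloc[0]["ci_high"]) - np.log(scan.iloc[0]["ci_low"])) / (2 * 1.96))
    sem = np.mean(ses) / np.sqrt(len(ests))
    assert np.mean(ests) == pytest.approx(np.log(1.5), abs=3 * sem + 0.02)


def test_monomorphic_locus_skipped_and_family_size():
    cohort = _planted(22)
    phen = cohort.phen
    n = len(phen)
    vals = np.column_stack([
        np.zeros(n, dtype=np.int8),                       # monomorphic
        np.random.default_rng(1).integers(0, 3, n).astype(np.int8),
    ])
    geno = GenotypeMatrix(list(phen["sample_id"]), ["mono", "poly"], vals)
    scan = casecontrol_scan(geno, phen)
    mono = scan[scan["locus_id"] == "mono"].iloc[0]
    assert mono["flags"] == "monomorphic_or_degenerate" and np.isnan(mono["p_unadj"])
    assert scan.attrs["bonferroni_m"] == 1


def test_scan_invariant_to_locus_order(small_cohort):
    from l1burden.pipeline import run_qc
    qc = run_qc(small_cohort.loci, small_cohort.geno, small_cohort.phen)
    scan1 = casecontrol_scan(qc.scan_geno, qc.phen)
    perm = list(np.random.default_rng(3).permutation(qc.scan_geno.locus_ids))
    scan2 = casecontrol_scan(qc.scan_geno.subset(loci=perm), qc.phen)
    m = scan1.set_index("locus_id")["p_unadj"]
    m2 = scan2.set_index("locus_id")["p_unadj"]
    assert np.allclose(m.sort_index().fillna(-1), m2.sort_index().fillna(-1))


# ---------------------------------------------------------------------------
# onset
# ---------------------------------------------------------------------------

def test_onset_carrier_means_toy():
    """Carriers built exactly 6.5 years younger show a 6.5-year mean gap."""
    n = 40
    g = np.array([1] * 10 + [0] * 30, dtype=np.int8)
    onset = np.where(g > 0, 52.7, 59.2)
    phen = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "diagnosis": "ALS", "sex": ["male", "female"] * 20,
        "age_years": onset, "age_at_onset_years": onset,
        "site_of_onset": "limb", "survival_months": 20.0, "event_observed": True,
        "seq_prep": "prep1", "european_fraction": 1.0,
    })
    geno = GenotypeMatrix(list(phen["sample_id"]), ["L"], g[:, None])
    scan = onset_scan(geno, phen)
    row = scan.iloc[0]
    assert row["mean_onset_absent"] - row["mean_onset_carrier"] == pytest.approx(6.5)
    assert row["estimate"] == pytest.approx(-6.5, abs=1e-8)


def test_onset_recovers_planted_carrier_effect():
    cohort = _planted(30)
    scan = onset_scan(_locus_column(cohort, cohort.truth["onset_locus_id"]), cohort.phen)
    row = scan.iloc[0]
    assert row["estimate"] == pytest.approx(-6.55, abs=3 * row["se"])


def test_onset_single_group_skipped():
    cohort = _planted(23)
    phen = cohort.phen
    geno = GenotypeMatrix(list(phen["sample_id"]), ["mono"],
                          np.ones((len(phen), 1), dtype=np.int8))
    scan = onset_scan(geno, phen)
    assert scan.iloc[0]["flags"] == "single_genotype_group"


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def test_survival_recovers_planted_hr():
    ok = 0
    for seed in range(3):
        cohort = _planted(40 + seed, survival_log_hr=np.log(1.4))
        scan = survival_scan(_locus_column(cohort, cohort.truth["survival_locus_id"]),
                             cohort.phen)
        row = scan.iloc[0]
        se = (np.log(row["ci_high"]) - np.log(row["ci_low"])) / (2 * 1.96)
        ok += bool(abs(np.log(row["hazard_ratio"]) - np.log(1.4)) <= 3 * se)
    assert ok >= 2


def test_survival_handles_censoring_only_genotype_group():
    """A genotype class whose members are all censored enters risk sets only."""
    cohort = _planted(41)
    phen = cohort.phen.copy()
    lid = cohort.truth["survival_locus_id"]
    geno = _locus_column(cohort, lid)
    carriers = [s for s, v in zip(geno.sample_ids, geno.values[:, 0]) if v > 0]
    phen.loc[phen["sample_id"].isin(carriers) & phen["event_observed"].notna(),
             "event_observed"] = False
    scan = survival_scan(geno, phen)
    assert np.isfinite(scan.iloc[0]["hazard_ratio"])


def test_forest_table_top5(default_qc):
    sub = default_qc.scan_geno.subset(loci=default_qc.scan_geno.locus_ids[:40])
    scan = onset_scan(sub, default_qc.phen)
    ft = forest_table(scan, "estimate", top=5)
    assert len(ft) == 5
    assert (ft["p_unadj"].to_numpy() == np.sort(ft["p_unadj"].to_numpy())).all()
    assert (ft["ci_low"] <= ft["effect"]).all() and (ft["effect"] <= ft["ci_high"]).all()
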
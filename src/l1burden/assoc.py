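"""Per-locus case-control, age-at-onset and survival scans.

All scans use additive allele coding (0/1/2 Present alleles per genome) and
Bonferroni correction over the number of loci actually fitted. Carrier-group
summaries (Present-carrier vs homozygous-absent) are emitted alongside the
onset scan for reporting; for rare loci with no homozygous-Present genotypes
the additive and carrier codings coincide.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import complete_case, covariate_design
from .stats import bonferroni, fit_coxph, fit_linear, fit_logistic, wald_ci, wald_p
from .types import MISSING, GenotypeMatrix

CASE_DIAGNOSES = ("ALS", "ALSND")


def _aligned(geno: GenotypeMatrix, phen: pd.DataFrame, required: list[str]) -> tuple[pd.DataFrame, np.ndarray]:
    """Complete-case phenotype rows aligned with genotype rows."""
    in_geno = phen["sample_id"].isin(set(geno.sample_ids))
    df = complete_case(phen[in_geno], required)
    rows = geno.values[geno.sample_index(df["sample_id"]), :]
    return df.reset_index(drop=True), rows


def _group_maf(g: np.ndarray, grp: np.ndarray) -> float:
    gg = g[grp & (g != MISSING)]
    if gg.size == 0:
        return float("nan")
    iaf = gg.sum() / (2.0 * gg.size)
    return float(min(iaf, 1.0 - iaf))


def casecontrol_scan(geno: GenotypeMatrix, phen: pd.DataFrame, firth: bool = True) -> pd.DataFrame:
    """Logistic scan of disease status on additive genotype + covariates.

    Covariates: sex, age (collection age for controls, onset age for cases)
    and sequencing preparation; samples with missing age are dropped
    (complete-case). Monomorphic loci are skipped with a reason. Returns a
    table sorted by unadjusted p with per-group MAFs and the odds ratio per
    Present allele.
    """
    df = phen[phen["diagnosis"].isin(CASE_DIAGNOSES + ("NNC",))]
    df, rows = _aligned(geno, df, ["sex", "age_years", "seq_prep"])
    status = df["diagnosis"].isin(CASE_DIAGNOSES).to_numpy(float)
    Xcov, names_cov = covariate_design(df, ["sex", "age_years", "seq_prep"])
    ctrl, case = status == 0, status == 1

    out = []
    for j, lid in enumerate(geno.locus_ids):
        g = rows[:, j]
        called = g != MISSING
        gv = g[called].astype(float)
        row = {
            "locus_id": lid, "minor_allele": "P",
            "maf_nnc": _group_maf(g, ctrl), "maf_case": _group_maf(g, case),
        }
        if gv.size == 0 or gv.min() == gv.max() or status[called].min() == status[called].max():
            row.update(odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                       p_unadj=np.nan, n_used=int(called.sum()), flags="monomorphic_or_degenerate")
        else:
            iaf = gv.sum() / (2 * gv.size)
            if iaf > 0.5:
                row["minor_allele"] = "A"  # Present allele is major; effect still per P allele
            X = np.column_stack([Xcov[called], gv])
            fit = fit_logistic(status[called], X, firth=firth, names=names_cov + ["genotype"])
            b, se = fit.coef("genotype"), fit.coef_se("genotype")
            lo, hi = wald_ci(b, se, exponentiate=True)
            row.update(odds_ratio=float(np.exp(b)), ci_low=lo, ci_high=hi,
                       p_unadj=wald_p(b, se), n_used=fit.n,
                       flags=";".join(sorted(fit.flags)))
        out.append(row)
    table = pd.DataFrame(out)
    fitted = table["p_unadj"].notna()
    table["p_bonferroni"] = np.nan
    if fitted.any():
        table.loc[fitted, "p_bonferroni"] = bonferroni(table.loc[fitted, "p_unadj"], int(fitted.sum()))
    table.attrs["bonferroni_m"] = int(fitted.sum())
    return table.sort_values("p_unadj", na_position="last").reset_index(drop=True)


def onset_scan(geno: GenotypeMatrix, phen: pd.DataFrame) -> pd.DataFrame:
    """Linear scan of age at onset on additive genotype, cases only.

    Covariates: sex, sequencing preparation and site of onset. Also reports
    carrier-group mean onset ages (Present carrier vs homozygous absent).
    Loci with fewer than two genotype groups among cases are skipped.
    """
    cases = phen[phen["diagnosis"].isin(CASE_DIAGNOSES)]
    df, rows = _aligned(geno, cases, ["age_at_onset_years", "sex", "seq_prep", "site_of_onset"])
    y = df["age_at_onset_years"].to_numpy(float)
    Xcov, names_cov = covariate_design(df, ["sex", "seq_prep", "site_of_onset"])

    out = []
    for j, lid in enumerate(geno.locus_ids):
        g = rows[:, j]
        called = g != MISSING
        gv = g[called].astype(float)
        carrier = gv > 0
        row = {
            "locus_id": lid,
            "n_carrier": int(carrier.sum()),
            "n_absent": int((~carrier).sum()),
            "mean_onset_carrier": float(y[called][carrier].mean()) if carrier.any() else np.nan,
            "mean_onset_absent": float(y[called][~carrier].mean()) if (~carrier).any() else np.nan,
        }
        if gv.size == 0 or gv.min() == gv.max():
            row.update(estimate=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
                       p_unadj=np.nan, n_used=int(called.sum()), flags="single_genotype_group")
        else:
            X = np.column_stack([Xcov[called], gv])
            fit = fit_linear(y[called], X, names_cov + ["genotype"])
            b, se = fit.coef("genotype"), fit.coef_se("genotype")
            lo, hi = wald_ci(b, se)
            row.update(estimate=b, se=se, ci_low=lo, ci_high=hi,
                       p_unadj=wald_p(b, se, df=fit.df_resid), n_used=fit.n, flags="")
        out.append(row)
    table = pd.DataFrame(out)
    fitted = table["p_unadj"].notna()
    table["p_bonferroni"] = np.nan
    if fitted.any():
        table.loc[fitted, "p_bonferroni"] = bonferroni(table.loc[fitted, "p_unadj"], int(fitted.sum()))
    table.attrs["bonferroni_m"] = int(fitted.sum())
    return table.sort_values("p_unadj", na_position="last").reset_index(drop=True)


def survival_scan(geno: GenotypeMatrix, phen: pd.DataFrame) -> pd.DataFrame:
    """Cox proportional-hazards scan of survival on additive genotype.

    Cases only; covariates sex, sequencing preparation, age at onset and
    site of onset. Individuals alive at last follow-up are censored and
    contribute to risk sets only.
    """
    cases = phen[phen["diagnosis"].isin(CASE_DIAGNOSES)]
    df, rows = _aligned(geno, cases, ["survival_months", "event_observed", "sex",
                                      "seq_prep", "age_at_onset_years", "site_of_onset"])
    time = df["survival_months"].to_numpy(float)
    event = df["event_observed"].to_numpy(float)
    Xcov, names_cov = covariate_design(df, ["sex", "seq_prep", "age_at_onset_years", "site_of_onset"])
    Xcov = Xcov[:, 1:]  # Cox partial likelihood has no intercept
    names_cov = names_cov[1:]

    out = []
    for j, lid in enumerate(geno.locus_ids):
        g = rows[:, j]
        called = g != MISSING
        gv = g[called].astype(float)
        row = {"locus_id": lid}
        if gv.size == 0 or gv.min() == gv.max() or event[called].sum() < 1:
            row.update(hazard_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                       p_unadj=np.nan, n_used=int(called.sum()),
                       flags="degenerate_locus")
        else:
            X = np.column_stack([Xcov[called], gv])
            fit = fit_coxph(time[called], event[called], X, names_cov + ["genotype"])
            b, se = fit.coef("genotype"), fit.coef_se("genotype")
            lo, hi = wald_ci(b, se, exponentiate=True)
            row.update(hazard_ratio=float(np.exp(b)), ci_low=lo, ci_high=hi,
                       p_unadj=wald_p(b, se), n_used=fit.n,
                       flags=";".join(sorted(fit.flags)))
        out.append(row)
    table = pd.DataFrame(out)
    fitted = table["p_unadj"].notna()
    table["p_bonferroni"] = np.nan
    if fitted.any():
        table.loc[fitted, "p_bonferroni"] = bonferroni(table.loc[fitted, "p_unadj"], int(fitted.sum()))
    table.attrs["bonferroni_m"] = int(fitted.sum())
    return table.sort_values("p_unadj", na_position="last").reset_index(drop=True)


def forest_table(scan: pd.DataFrame, effect_col: str, top: int = 5) -> pd.DataFrame:
    """Plot-ready forest table (label, effect, ci_low, ci_high) of the top loci."""
    sub = scan[scan["p_unadj"].notna()].nsmallest(top, "p_unadj")
    return pd.DataFrame({
        "label": sub["locus_id"].to_numpy(),
        "effect": sub[effect_col].to_numpy(),
        "ci_low": sub["ci_low"].to_numpy(),
        "ci_high": sub["ci_high"].to_numpy(),
        "p_unadj": sub["p_unadj"].to_numpy(),
    })
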
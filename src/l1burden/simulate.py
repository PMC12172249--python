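"""Synthetic cohort generator with the statistical structure the analyses assume.

The generator emulates a case-control whole-genome cohort of polymorphic L1
insertion loci: a bimodal insertion-allele-frequency spectrum (reference
elements mostly common, non-reference mostly rare), a curated RC catalog
partially overlapping the in-cohort loci, Hardy-Weinberg genotypes within
each group, a case-control RC burden shift induced by tilting case allele
frequencies (so HWE holds within groups), one rare onset-modifier locus
with a dominant (carrier) effect, proportional-hazards survival with
censoring at a simulated last follow-up, and planted eQTL slopes in two
motor-cortex expression matrices.

All randomness flows from a single seed through named substreams
(loci / genotypes / phenotypes / expression), so regeneration is stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .types import (
    MISSING,
    ExpressionMatrix,
    GenotypeMatrix,
    LocusRecord,
    RcCatalog,
    locus_id_for,
)

TISSUES = ("medial_motor_cortex", "lateral_motor_cortex")

#: cohort demographics used as generator defaults (counts, not rates, so the
#: printed percentages are reproducible arithmetic)
DEMOGRAPHICS = {
    "n_controls": 320,
    "n_cases": 2653,
    "n_male_controls": 157,
    "n_male_cases": 1594,
    "n_controls_age_unknown": 43,
    "n_cases_onset_unknown": 159,
}


@dataclass
class SimConfig:
    """Generator configuration; the defaults are the study conditions."""

    # cohort
    n_controls: int = DEMOGRAPHICS["n_controls"]
    n_cases: int = DEMOGRAPHICS["n_cases"]
    n_other_diagnosis: int = 15     # excluded by diagnosis at cohort selection
    n_low_european: int = 10        # excluded by ancestry at cohort selection
    # locus registry (counts after caller-evidence and HWE QC)
    n_reference_loci: int = 205
    n_non_reference_loci: int = 2598
    n_melt_fail: int = 10           # extra non-reference loci failing caller evidence
    n_hwe_fail: int = 5             # extra non-reference loci violating HWE in controls
    # insertion-allele-frequency spectrum
    ref_common_fraction: float = 0.893   # reference loci with IAF >= 0.1
    nonref_common_fraction: float = 0.057
    common_iaf_low: float = 0.1
    common_iaf_high: float = 0.98
    rare_iaf_min: float = 2e-4
    rare_iaf_exponent: float = 1.75      # density ~ p^-a on [rare_iaf_min, 0.1)
    # RC catalog and burden loci
    catalog_reference_total: int = 102
    catalog_non_reference_total: int = 177
    n_rc_loci: int = 93                  # RC loci polymorphic in the cohort
    n_rc_reference: int = 30
    n_rc_x: int = 3                      # RC loci on chrX (removed for burden)
    n_rc_high_missing: int = 1           # RC loci with >5% missingness (removed)
    n_burden_common: int = 8             # burden loci near fixation (IAF ~ 0.97)
    burden_common_iaf: tuple = (0.95, 0.99)
    burden_rare_iaf: tuple = (0.08, 0.27)
    burden_shift: float = 0.40           # case - control expected allele-count difference
    # planted per-locus effects (zero = absent)
    onset_locus_iaf: float = 0.017
    onset_carrier_effect: float = -6.55  # years, dominant coding
    cc_locus_iaf: float = 0.10
    cc_log_or: float = 0.0               # per-allele case-control log odds ratio
    survival_locus_iaf: float = 0.10
    survival_log_hr: float = 0.0         # per-allele log hazard ratio
    # phenotypes
    onset_baseline_mean: float = 59.2
    onset_noise_sd: float = 12.0
    control_age_mean: float = 57.4
    control_age_sd: float = 13.0
    male_frac_controls: float = DEMOGRAPHICS["n_male_controls"] / DEMOGRAPHICS["n_controls"]
    male_frac_cases: float = DEMOGRAPHICS["n_male_cases"] / DEMOGRAPHICS["n_cases"]
    control_age_missing: float = DEMOGRAPHICS["n_controls_age_unknown"] / DEMOGRAPHICS["n_controls"]
    case_onset_missing: float = DEMOGRAPHICS["n_cases_onset_unknown"] / DEMOGRAPHICS["n_cases"]
    alsnd_fraction: float = 0.10
    bulbar_fraction: float = 0.30
    n_seq_prep: int = 3
    survival_median_months: float = 36.0  # post-onset life expectancy 2-5 y
    followup_min_months: float = 6.0
    followup_max_months: float = 120.0
    # genotype missingness
    missing_rate: float = 0.00105        # per-call no-call rate
    high_missing_rate: float = 0.08      # at the designated high-missingness RC locus
    # expression
    n_expression_samples: int = 300
    n_transcripts: int = 150
    n_eqtl_loci: int = 30
    n_eqtl_rc: int = 2
    eqtl_slope: float = 1.0
    expression_noise_sd: float = 1.0
    expression_age_coef: float = 0.01
    expression_sex_coef: float = 0.2
    seed: int = 0

    @property
    def n_burden_loci(self) -> int:
        return self.n_rc_loci - self.n_rc_x - self.n_rc_high_missing

    def validate(self) -> None:
        if not (0 < self.n_rc_reference <= min(self.n_rc_loci, self.n_reference_loci)):
            raise ValueError("n_rc_reference out of range")
        n_rc_nonref = self.n_rc_loci - self.n_rc_reference
        if n_rc_nonref > self.n_non_reference_loci:
            raise ValueError("more non-reference RC loci than non-reference loci")
        if self.n_rc_x + self.n_rc_high_missing > n_rc_nonref:
            raise ValueError("chrX / high-missingness RC loci must fit in the non-reference RC set")
        if self.n_burden_common > self.n_burden_loci:
            raise ValueError("n_burden_common exceeds the number of burden loci")
        if self.n_rc_reference > self.catalog_reference_total or \
                n_rc_nonref > self.catalog_non_reference_total:
            raise ValueError("in-cohort RC loci exceed catalog totals")
        if self.n_expression_samples > self.n_cases:
            raise ValueError("expression samples must be drawn from cases")
        if self.n_eqtl_rc > self.n_eqtl_loci:
            raise ValueError("n_eqtl_rc exceeds n_eqtl_loci")
        for f in ("ref_common_fraction", "nonref_common_fraction"):
            if not 0 <= getattr(self, f) <= 1:
                raise ValueError(f"{f} must lie in [0, 1]")
        for f in ("onset_locus_iaf", "cc_locus_iaf", "survival_locus_iaf",
                  "missing_rate", "high_missing_rate"):
            if not 0 <= getattr(self, f) < 1:
                raise ValueError(f"{f} must lie in [0, 1)")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SimulatedCohort:
    loci: list
    geno: GenotypeMatrix
    phen: pd.DataFrame
    expressions: list
    catalog: RcCatalog
    truth: dict = field(default_factory=dict)
    config: SimConfig | None = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _rare_iaf(rng, size, cfg: SimConfig) -> np.ndarray:
    """Power-law rare-allele frequencies on [rare_iaf_min, 0.1), density ~ p^-a."""
    a = cfg.rare_iaf_exponent
    lo, hi = cfg.rare_iaf_min, cfg.common_iaf_low
    u = rng.random(size)
    e = 1.0 - a
    return (lo**e + u * (hi**e - lo**e)) ** (1.0 / e)


def _spectrum_iaf(rng, size, common_fraction, cfg: SimConfig) -> np.ndarray:
    common = rng.random(size) < common_fraction
    iaf = _rare_iaf(rng, size, cfg)
    iaf[common] = rng.uniform(cfg.common_iaf_low, cfg.common_iaf_high, common.sum())
    return iaf


def _unique_positions(rng, chroms) -> np.ndarray:
    """Random 1-based positions, unique per (chrom, pos)."""
    seen = set()
    pos = np.empty(len(chroms), dtype=int)
    for i, c in enumerate(chroms):
        while True:
            p = int(rng.integers(1_000_000, 240_000_000))
            if (c, p) not in seen:
                seen.add((c, p))
                pos[i] = p
                break
    return pos


def _logit_shift(p: np.ndarray, b: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(np.log(p / (1 - p)) + b)))


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig | None = None, seed: int | None = None) -> SimulatedCohort:
    """Generate loci, genotypes, phenotypes, expression and the RC catalog.

    Fully reproducible given the seed (``seed`` overrides ``config.seed``).
    Raises if the requested burden shift is unreachable given the burden-locus
    allele frequencies.
    """
    cfg = config or SimConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_loci, rng_geno, rng_phen, rng_expr = (np.random.default_rng(s) for s in ss.spawn(4))

    # ---- locus registry --------------------------------------------------
    n_ref, n_nonref = cfg.n_reference_loci, cfg.n_non_reference_loci
    n_fail = cfg.n_melt_fail + cfg.n_hwe_fail
    autosomes = [str(c) for c in range(1, 23)]
    chroms = list(rng_loci.choice(autosomes, size=n_ref + n_nonref + n_fail))
    n_rc_nonref = cfg.n_rc_loci - cfg.n_rc_reference
    # RC partitioning within the registry (indices into the full locus list)
    rc_ref_idx = np.arange(cfg.n_rc_reference)                       # first reference loci
    rc_nonref_idx = n_ref + np.arange(n_rc_nonref)                   # first non-reference loci
    x_idx = rc_nonref_idx[: cfg.n_rc_x]                              # chrX RC loci
    highmiss_idx = rc_nonref_idx[cfg.n_rc_x: cfg.n_rc_x + cfg.n_rc_high_missing]
    burden_idx = np.concatenate([
        rc_ref_idx, rc_nonref_idx[cfg.n_rc_x + cfg.n_rc_high_missing:]
    ])
    for i in x_idx:
        chroms[i] = "X"
    pos = _unique_positions(rng_loci, chroms)

    loci: list[LocusRecord] = []
    for i in range(n_ref + n_nonref + n_fail):
        source = "reference" if i < n_ref else "non_reference"
        rec = LocusRecord(
            locus_id=locus_id_for(chroms[i], int(pos[i]), source),
            chrom=chroms[i], pos=int(pos[i]), source=source,
        )
        if source == "non_reference":
            rec.split_reads = int(rng_loci.integers(2, 30))
            rec.assess_score = int(rng_loci.integers(3, 6))
            rec.caller_filter = "PASS"
        else:
            rec.caller_filter = "PASS"
        loci.append(rec)
    # degrade the designated caller-evidence failures
    melt_fail_idx = np.arange(n_ref + n_nonref, n_ref + n_nonref + cfg.n_melt_fail)
    for k, i in enumerate(melt_fail_idx):
        mode = k % 3
        if mode == 0:
            loci[i].split_reads = int(rng_loci.integers(0, 2))
        elif mode == 1:
            loci[i].assess_score = int(rng_loci.integers(0, 3))
        else:
            loci[i].caller_filter = "lq"
    hwe_fail_idx = np.arange(n_ref + n_nonref + cfg.n_melt_fail, n_ref + n_nonref + n_fail)

    # ---- allele frequencies ---------------------------------------------
    n_total = len(loci)
    iaf = np.empty(n_total)
    iaf[:n_ref] = _spectrum_iaf(rng_loci, n_ref, cfg.ref_common_fraction, cfg)
    iaf[n_ref:] = _spectrum_iaf(rng_loci, n_total - n_ref, cfg.nonref_common_fraction, cfg)
    # burden loci: a few near fixation, the rest at intermediate frequency,
    # sized so the per-genome allele-count distribution matches the cohort's
    nb = cfg.n_burden_loci
    iaf[burden_idx[: cfg.n_burden_common]] = rng_loci.uniform(*cfg.burden_common_iaf, cfg.n_burden_common)
    iaf[burden_idx[cfg.n_burden_common:]] = rng_loci.uniform(*cfg.burden_rare_iaf, nb - cfg.n_burden_common)
    iaf[x_idx] = rng_loci.uniform(0.1, 0.4, len(x_idx))
    iaf[highmiss_idx] = rng_loci.uniform(0.1, 0.4, len(highmiss_idx))
    # HWE violators must be common enough for the control-only exact test to see
    iaf[hwe_fail_idx] = rng_loci.uniform(0.2, 0.5, len(hwe_fail_idx))
    # planted single-locus effects live on dedicated non-RC autosomal loci
    rc_all_idx = set(rc_ref_idx) | set(rc_nonref_idx)
    free = [i for i in range(n_ref, n_ref + n_nonref) if i not in rc_all_idx]
    onset_i, cc_i, surv_i = free[0], free[1], free[2]
    iaf[onset_i] = cfg.onset_locus_iaf
    iaf[cc_i] = cfg.cc_locus_iaf
    iaf[surv_i] = cfg.survival_locus_iaf

    # case-specific tilt: burden shift spread evenly over burden loci
    iaf_case = iaf.copy()
    if cfg.burden_shift != 0.0:
        delta = cfg.burden_shift / (2.0 * nb)
        tilted = np.clip(iaf[burden_idx] + delta, None, 0.999)
        achievable = 2.0 * float((tilted - iaf[burden_idx]).sum())
        if achievable < cfg.burden_shift - 1e-9:
            raise ValueError(
                f"burden_shift {cfg.burden_shift} unreachable given burden-locus "
                f"frequencies; maximum achievable shift is {achievable:.4f}"
            )
        iaf_case[burden_idx] = tilted
    if cfg.cc_log_or != 0.0:
        iaf_case[cc_i] = _logit_shift(iaf[cc_i], cfg.cc_log_or)

    # ---- samples ---------------------------------------------------------
    n_ctrl, n_case = cfg.n_controls, cfg.n_cases
    n_decoy = cfg.n_other_diagnosis + cfg.n_low_european
    n_samples = n_ctrl + n_case + n_decoy
    sample_ids = [f"S{i:05d}" for i in range(1, n_samples + 1)]
    is_case = np.zeros(n_samples, dtype=bool)
    is_case[n_ctrl:n_ctrl + n_case] = True

    # ---- genotypes (HWE within group; hwe-fail loci all-homozygote) -----
    p_matrix = np.where(is_case[:, None], iaf_case[None, :], iaf[None, :])
    true_geno = rng_geno.binomial(2, p_matrix).astype(np.int8)
    for i in hwe_fail_idx:
        true_geno[:, i] = 2 * rng_geno.binomial(1, iaf[i], n_samples).astype(np.int8)
    miss_rate = np.full(n_total, cfg.missing_rate)
    miss_rate[highmiss_idx] = cfg.high_missing_rate
    missing_mask = rng_geno.random((n_samples, n_total)) < miss_rate[None, :]
    observed = np.where(missing_mask, MISSING, true_geno).astype(np.int8)
    geno = GenotypeMatrix(sample_ids, [l.locus_id for l in loci], observed)

    # ---- phenotypes ------------------------------------------------------
    diagnosis = np.array(["NNC"] * n_samples, dtype=object)
    diagnosis[is_case] = np.where(rng_phen.random(n_case) < cfg.alsnd_fraction, "ALSND", "ALS")
    other_sl = slice(n_ctrl + n_case, n_ctrl + n_case + cfg.n_other_diagnosis)
    diagnosis[other_sl] = [
        "other_MND" if k % 2 == 0 else "other_neuro" for k in range(cfg.n_other_diagnosis)
    ]
    low_sl = slice(n_ctrl + n_case + cfg.n_other_diagnosis, n_samples)
    diagnosis[low_sl] = "ALS"

    male_frac = np.where(is_case, cfg.male_frac_cases, cfg.male_frac_controls)
    male_frac[other_sl] = 0.5
    male_frac[low_sl] = cfg.male_frac_cases
    sex = np.where(rng_phen.random(n_samples) < male_frac, "male", "female")

    euro = rng_phen.uniform(0.905, 0.999, n_samples)
    euro[low_sl] = rng_phen.uniform(0.5, 0.9, cfg.n_low_european)

    seq_prep = np.array([f"prep{k + 1}" for k in rng_phen.integers(0, cfg.n_seq_prep, n_samples)])

    age = np.full(n_samples, np.nan)
    onset = np.full(n_samples, np.nan)
    ctrl_like = ~is_case
    age[ctrl_like] = np.clip(
        rng_phen.normal(cfg.control_age_mean, cfg.control_age_sd, int(ctrl_like.sum())), 17, 90
    )
    case_like = is_case | (np.arange(n_samples) >= n_ctrl + n_case)  # decoy ALS get onsets too
    case_like[other_sl] = False
    carrier = true_geno[:, onset_i] > 0
    onset_vals = (
        cfg.onset_baseline_mean
        + cfg.onset_carrier_effect * carrier
        + rng_phen.normal(0.0, cfg.onset_noise_sd, n_samples)
    )
    onset[case_like] = np.clip(onset_vals[case_like], 12, 90)
    age = np.where(case_like, onset, age)
    # missing ages: collection age unknown for some controls, onset for some cases
    age_missing = rng_phen.random(n_samples) < np.where(is_case, cfg.case_onset_missing,
                                                        cfg.control_age_missing)
    age[age_missing] = np.nan
    onset[age_missing] = np.nan

    site = np.array([None] * n_samples, dtype=object)
    site[case_like] = np.where(rng_phen.random(int(case_like.sum())) < cfg.bulbar_fraction,
                               "bulbar", "limb")

    survival = np.full(n_samples, np.nan)
    event = np.array([None] * n_samples, dtype=object)
    lam = np.log(2.0) / cfg.survival_median_months
    hazard_mult = np.exp(cfg.survival_log_hr * true_geno[:, surv_i].astype(float))
    t_event = rng_phen.exponential(1.0, n_samples) / (lam * hazard_mult)
    t_censor = rng_phen.uniform(cfg.followup_min_months, cfg.followup_max_months, n_samples)
    surv_obs = np.maximum(np.minimum(t_event, t_censor), 0.25).round(1)
    survival[case_like] = surv_obs[case_like]
    event[case_like] = (t_event <= t_censor)[case_like]

    phen = pd.DataFrame({
        "sample_id": sample_ids,
        "diagnosis": diagnosis,
        "sex": sex,
        "age_years": age,
        "age_at_onset_years": np.where(np.isin(diagnosis, ["ALS", "ALSND"]), onset, np.nan),
        "site_of_onset": [s if d in ("ALS", "ALSND") else None
                          for s, d in zip(site, diagnosis)],
        "survival_months": np.where(np.isin(diagnosis, ["ALS", "ALSND"]), survival, np.nan),
        "event_observed": [bool(e) if d in ("ALS", "ALSND") and e is not None else None
                           for e, d in zip(event, diagnosis)],
        "seq_prep": seq_prep,
        "european_fraction": euro,
    })

    # ---- RC catalog ------------------------------------------------------
    entries: dict[str, str] = {}
    for i in rc_ref_idx:
        entries[loci[i].locus_id] = "reference"
    for i in rc_nonref_idx:
        entries[loci[i].locus_id] = "non_reference"
    # catalog members not polymorphic in this cohort: synthetic off-registry ids
    extra_ref = cfg.catalog_reference_total - cfg.n_rc_reference
    extra_nonref = cfg.catalog_non_reference_total - n_rc_nonref
    k = 0
    while extra_ref + extra_nonref > 0:
        c = autosomes[int(rng_loci.integers(0, 22))]
        p = int(rng_loci.integers(1_000_000, 240_000_000))
        src = "reference" if extra_ref > 0 else "non_reference"
        lid = locus_id_for(c, p, src)
        if lid in entries or lid in set(geno.locus_ids):
            continue
        entries[lid] = src
        if extra_ref > 0:
            extra_ref -= 1
        else:
            extra_nonref -= 1
        k += 1
    catalog = RcCatalog(entries)
    lio.annotate_rc(loci, catalog)

    # ---- expression ------------------------------------------------------
    case_ids = np.array(sample_ids)[n_ctrl:n_ctrl + n_case]
    expr_samples = list(rng_expr.choice(case_ids, size=cfg.n_expression_samples, replace=False))
    expr_rows = geno.sample_index(expr_samples)
    transcripts = [f"T{k:04d}" for k in range(1, cfg.n_transcripts + 1)]
    # planted pairs: intermediate-frequency loci, a couple of them RC
    mid = [i for i in free[3:] if 0.1 <= iaf[i] <= 0.5]
    mid_rc = [int(i) for i in burden_idx[cfg.n_burden_common:]][: cfg.n_eqtl_rc]
    plan_loci = (mid_rc + mid)[: cfg.n_eqtl_loci]
    eqtl_pairs = [(loci[i].locus_id, transcripts[k]) for k, i in enumerate(plan_loci)]
    age_expr = np.nan_to_num(age[expr_rows], nan=float(np.nanmean(age)))
    male_expr = (sex[expr_rows] == "male").astype(float)
    expressions = []
    for tissue in TISSUES:
        vals = rng_expr.normal(0.0, cfg.expression_noise_sd,
                               (cfg.n_transcripts, cfg.n_expression_samples))
        vals += cfg.expression_age_coef * age_expr[None, :]
        vals += cfg.expression_sex_coef * male_expr[None, :]
        for k, i in enumerate(plan_loci):
            vals[k, :] += cfg.eqtl_slope * true_geno[expr_rows, i].astype(float)
        expressions.append(ExpressionMatrix(tissue, list(transcripts), list(expr_samples), vals))

    truth = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "burden_locus_ids": [loci[i].locus_id for i in burden_idx],
        "rc_x_locus_ids": [loci[i].locus_id for i in x_idx],
        "rc_high_missing_locus_ids": [loci[i].locus_id for i in highmiss_idx],
        "onset_locus_id": loci[onset_i].locus_id,
        "cc_locus_id": loci[cc_i].locus_id,
        "survival_locus_id": loci[surv_i].locus_id,
        "melt_fail_locus_ids": [loci[i].locus_id for i in melt_fail_idx],
        "hwe_fail_locus_ids": [loci[i].locus_id for i in hwe_fail_idx],
        "eqtl_pairs": eqtl_pairs,
        "iaf_control": iaf.tolist(),
        "iaf_case": iaf_case.tolist(),
        "expected_burden_shift": 2.0 * float((iaf_case[burden_idx] - iaf[burden_idx]).sum()),
        "covariate_burden_independence": "covariates are generated independently of burden",
    }
    return SimulatedCohort(loci=loci, geno=geno, phen=phen, expressions=expressions,
                           catalog=catalog, truth=truth, config=cfg)


def focused_config(**overrides) -> SimConfig:
    """Study-size cohort with the full RC/burden structure but a minimal
    non-RC locus registry.

    Convenience for single-quantity experiments (burden recovery,
    threshold-scan nulls, planted-locus recovery) where the thousands of
    decoy loci are irrelevant; cohort sizes and all effect sizes keep their
    defaults.
    """
    base = dict(n_reference_loci=40, n_non_reference_loci=80,
                n_melt_fail=0, n_hwe_fail=0, n_other_diagnosis=0, n_low_european=0,
                n_transcripts=5, n_eqtl_loci=3, n_eqtl_rc=3, n_expression_samples=100)
    base.update(overrides)
    return SimConfig(**base)


def simulate_null(config: SimConfig | None = None, seed: int | None = None) -> SimulatedCohort:
    """As :func:`simulate_cohort` with every planted effect forced to zero."""
    cfg = config or SimConfig()
    cfg = dataclasses.replace(cfg, burden_shift=0.0, onset_carrier_effect=0.0,
                              cc_log_or=0.0, survival_log_hr=0.0, eqtl_slope=0.0)
    return simulate_cohort(cfg, seed=seed)


# ---------------------------------------------------------------------------
# fixture round-trip
# ---------------------------------------------------------------------------

def write_fixture(cohort: SimulatedCohort, out_dir) -> dict[str, Path]:
    """Emit the cohort as on-disk fixtures readable by :mod:`l1burden.io`.

    Produces a MELT-dialect VCF (non-reference loci), a deletion-dialect VCF
    (reference loci), a phenotype TSV, the RC catalog TSV, one expression
    TSV per tissue, and the generator truth as JSON. Every header carries
    the seed and config hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config or SimConfig()
    meta = {"l1burden_seed": cfg.seed, "l1burden_config_hash": cfg.config_hash()}
    nonref = [l for l in cohort.loci if l.source == "non_reference"]
    ref = [l for l in cohort.loci if l.source == "reference"]
    paths = {
        "melt_vcf": out / "non_reference.melt.vcf",
        "deletion_vcf": out / "reference.del.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "rc_catalog": out / "rc_catalog.tsv",
        "truth": out / "sim_truth.json",
    }
    lio.write_mei_vcf(nonref, cohort.geno.subset(loci=[l.locus_id for l in nonref]),
                      paths["melt_vcf"], dialect="melt", metadata=meta)
    lio.write_mei_vcf(ref, cohort.geno.subset(loci=[l.locus_id for l in ref]),
                      paths["deletion_vcf"], dialect="deletion_genotyping", metadata=meta)
    lio.write_phenotype_table(cohort.phen, paths["phenotypes"], metadata=meta)
    lio.write_rc_catalog(cohort.catalog, paths["rc_catalog"])
    for expr in cohort.expressions:
        p = out / f"expression_{expr.tissue}.tsv"
        lio.write_expression_matrix(expr, p, metadata=meta)
        paths[f"expression_{expr.tissue}"] = p
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    return paths


def read_fixture(fixture_dir) -> SimulatedCohort:
    """Read a fixture directory back into in-memory objects (truth included
    when present)."""
    d = Path(fixture_dir)
    loci_m, geno_m = lio.read_mei_vcf(d / "non_reference.melt.vcf", dialect="melt")
    loci_d, geno_d = lio.read_mei_vcf(d / "reference.del.vcf", dialect="deletion_genotyping")
    loci = loci_d + loci_m
    geno = GenotypeMatrix.concat_loci([geno_d, geno_m])
    phen = lio.read_phenotype_table(d / "phenotypes.tsv")
    catalog = lio.read_rc_catalog(d / "rc_catalog.tsv")
    lio.annotate_rc(loci, catalog)
    expressions = []
    for tissue in TISSUES:
        p = d / f"expression_{tissue}.tsv"
        if p.exists():
            expressions.append(lio.read_expression_matrix(p, tissue))
    truth = {}
    tpath = d / "sim_truth.json"
    if tpath.exists():
        truth = json.loads(tpath.read_text())
    return SimulatedCohort(loci=loci, geno=geno, phen=phen, expressions=expressions,
                           catalog=catalog, truth=truth, config=None)
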
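"""Per-genome RC-L1 allele-count burden and its disease models.

The burden statistic is deliberately simple: for each individual, the
number of insertion-Present alleles summed over the retained
retrotransposition-competent loci (89 autosomal loci under the default
accounting). Association with disease uses a linear model of the count on
case/control status plus covariates, so the status coefficient is in allele
units; the threshold scan instead asks, for each cut-point k, whether
carrying >= k Present alleles raises the odds of disease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import complete_case, covariate_design
from .stats import bonferroni, fit_coxph, fit_linear, fit_logistic, wald_ci, wald_p
from .types import AssociationResult, GenotypeMatrix

DEFAULT_THRESHOLDS = (43, 44, 45, 46, 47, 48)

CASE_DIAGNOSES = ("ALS", "ALSND")


@dataclass
class BurdenProfile:
    sample_id: str
    rc_allele_count: int
    n_loci_used: int

    def __post_init__(self):
        if not 0 <= self.rc_allele_count <= 2 * self.n_loci_used:
            raise ValueError("allele count outside [0, 2 * n_loci]")


def compute_burden(geno: GenotypeMatrix) -> pd.DataFrame:
    """Row-sum of Present alleles over the burden loci.

    Requires a complete-case matrix (no missing calls); returns a frame with
    columns sample_id, rc_allele_count, n_loci_used.
    """
    if not geno.called_mask().all():
        raise ValueError("missing genotypes present; apply restrict_complete_individuals first")
    counts = geno.values.astype(int).sum(axis=1)
    return pd.DataFrame({
        "sample_id": geno.sample_ids,
        "rc_allele_count": counts,
        "n_loci_used": geno.n_loci,
    })


def _merged(profiles: pd.DataFrame, phen: pd.DataFrame) -> pd.DataFrame:
    df = profiles.merge(phen, on="sample_id", how="inner")
    df = df[df["diagnosis"].isin(CASE_DIAGNOSES + ("NNC",))].copy()
    df["status"] = df["diagnosis"].isin(CASE_DIAGNOSES).astype(float)
    return df


def burden_disease_model(profiles: pd.DataFrame, phen: pd.DataFrame) -> AssociationResult:
    """Linear model rc_allele_count ~ status + sex + age + seq_prep.

    The status coefficient is the adjusted case-minus-control difference in
    Present-allele counts (allele units).
    """
    df = _merged(profiles, phen)
    if df["status"].nunique() < 2:
        raise ValueError("need both cases and controls for the burden model")
    df = complete_case(df, ["rc_allele_count", "sex", "age_years", "seq_prep"])
    X, names = covariate_design(df, ["sex", "age_years", "seq_prep"])
    X = np.column_stack([X, df["status"].to_numpy()])
    names = names + ["status"]
    fit = fit_linear(df["rc_allele_count"].to_numpy(float), X, names)
    beta, se = fit.coef("status"), fit.coef_se("status")
    lo, hi = wald_ci(beta, se)
    p = wald_p(beta, se, df=fit.df_resid)
    return AssociationResult(
        test_id="rc_burden~status", effect=beta, se=se, ci_low=lo, ci_high=hi,
        p_unadj=p, p_adj=p, n_used=fit.n, model="linear", scale="linear",
    )


def threshold_scan(profiles: pd.DataFrame, phen: pd.DataFrame,
                   thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Logistic scan of disease status on I(burden >= k) over cut-points k.

    Returns one row per threshold with the odds ratio per >= k carrier
    status, Wald 95% CI, unadjusted and Bonferroni p (family = number of
    thresholds actually fitted), and per-group counts/percentages at >= k.
    Thresholds outside the observed burden range are recorded as degenerate
    and excluded from the Bonferroni family.
    """
    thresholds = list(thresholds)
    if any(b >= a for a, b in zip(thresholds[1:], thresholds)):
        raise ValueError("thresholds must be strictly increasing")
    df = _merged(profiles, phen)
    df = complete_case(df, ["rc_allele_count", "sex", "age_years", "seq_prep"])
    Xcov, names_cov = covariate_design(df, ["sex", "age_years", "seq_prep"])
    status = df["status"].to_numpy()
    count = df["rc_allele_count"].to_numpy()
    ctrl, case = status == 0, status == 1

    rows = []
    for k in thresholds:
        ind = (count >= k).astype(float)
        row = {
            "threshold": k,
            "n_controls_ge": int(ind[ctrl].sum()),
            "pct_controls_ge": 100.0 * ind[ctrl].mean() if ctrl.any() else np.nan,
            "n_cases_ge": int(ind[case].sum()),
            "pct_cases_ge": 100.0 * ind[case].mean() if case.any() else np.nan,
        }
        if ind.min() == ind.max():
            row.update(odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                       p_unadj=np.nan, n_used=len(df), flags="degenerate_threshold")
        else:
            X = np.column_stack([Xcov, ind])
            fit = fit_logistic(status, X, firth=True, names=names_cov + ["ge_k"])
            b, se = fit.coef("ge_k"), fit.coef_se("ge_k")
            lo, hi = wald_ci(b, se, exponentiate=True)
            row.update(odds_ratio=float(np.exp(b)), ci_low=lo, ci_high=hi,
                       p_unadj=wald_p(b, se), n_used=fit.n,
                       flags=";".join(sorted(fit.flags)))
        rows.append(row)
    out = pd.DataFrame(rows)
    fitted = out["p_unadj"].notna()
    out["p_bonferroni"] = np.nan
    if fitted.any():
        out.loc[fitted, "p_bonferroni"] = bonferroni(out.loc[fitted, "p_unadj"], int(fitted.sum()))
    return out


def burden_onset_and_survival(profiles: pd.DataFrame, phen: pd.DataFrame):
    """Burden vs age at onset (linear) and vs survival (Cox PH), cases only.

    Onset model: age_at_onset ~ count + sex + seq_prep + site_of_onset.
    Survival model: Cox PH of survival_months on count with sex, seq_prep,
    age_at_onset and site_of_onset; censored individuals enter risk sets only.
    """
    df = _merged(profiles, phen)
    cases = df[df["status"] == 1]

    onset = complete_case(cases, ["age_at_onset_years", "sex", "seq_prep", "site_of_onset"])
    Xc, names = covariate_design(onset, ["sex", "seq_prep", "site_of_onset"])
    X = np.column_stack([Xc, onset["rc_allele_count"].to_numpy(float)])
    fit = fit_linear(onset["age_at_onset_years"].to_numpy(float), X, names + ["burden"])
    b, se = fit.coef("burden"), fit.coef_se("burden")
    lo, hi = wald_ci(b, se)
    p = wald_p(b, se, df=fit.df_resid)
    onset_res = AssociationResult(
        test_id="onset~rc_burden", effect=b, se=se, ci_low=lo, ci_high=hi,
        p_unadj=p, p_adj=p, n_used=fit.n, model="linear", scale="linear",
    )

    surv = complete_case(cases, ["survival_months", "event_observed", "sex",
                                 "seq_prep", "age_at_onset_years", "site_of_onset"])
    Xc, names = covariate_design(surv, ["sex", "seq_prep", "age_at_onset_years", "site_of_onset"])
    X = np.column_stack([Xc[:, 1:], surv["rc_allele_count"].to_numpy(float)])  # Cox: no intercept
    fit = fit_coxph(surv["survival_months"].to_numpy(float),
                    surv["event_observed"].to_numpy(float), X, names[1:] + ["burden"])
    b, se = fit.coef("burden"), fit.coef_se("burden")
    lo, hi = wald_ci(b, se, exponentiate=True)
    surv_res = AssociationResult(
        test_id="survival~rc_burden", effect=float(np.exp(b)), se=se, ci_low=lo, ci_high=hi,
        p_unadj=wald_p(b, se), p_adj=wald_p(b, se), n_used=fit.n, model="coxph", scale="hr",
        flags=frozenset(fit.flags),
    )
    return onset_res, surv_res
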
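"""Statistical kernels shared by all analysis stages.

Hand-written pieces are the ones the pipeline's guarantees rest on and that
no installed library provides in the required form: the exact
Hardy-Weinberg test, Newton/IRLS logistic regression with a Firth-penalized
fallback for separated data, and a Cox proportional-hazards fit with
Breslow tie handling. Ordinary least squares, Fisher's exact test and
multiple-testing adjustments delegate to statsmodels / scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

Z95 = 1.959963984540054  # two-sided 95% normal quantile

__all__ = [
    "GenotypeCounts",
    "ModelFit",
    "hwe_exact_test",
    "fit_linear",
    "fit_logistic",
    "fit_coxph",
    "fisher_exact_2x2",
    "odds_ratio_2x2",
    "bonferroni",
    "bh_fdr",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Diploid genotype counts at one locus (absent/absent, het, present/present)."""

    n_hom_absent: int
    n_het: int
    n_hom_present: int

    def __post_init__(self):
        if min(self.n_hom_absent, self.n_het, self.n_hom_present) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_hom_absent + self.n_het + self.n_hom_present

    @property
    def minor_allele_count(self) -> int:
        a = 2 * self.n_hom_present + self.n_het
        return min(a, 2 * self.n - a)


@dataclass
class ModelFit:
    """Raw regression output feeding :class:`~l1burden.types.AssociationResult`."""

    coefficients: np.ndarray
    se: np.ndarray
    loglik: float
    vcov: np.ndarray
    converged: bool
    n: int
    names: list[str] | None = None
    df_resid: int | None = None
    flags: set = field(default_factory=set)

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.names.index(name)])


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote configurations whose probability is <= that of the observed
    configuration (the standard exact SNP-HWE formulation, no mid-p).
    Probabilities are built by the stable ratio recurrence

        P(h+2) / P(h) = (n_minor - h)(n_major - h) / ((h+2)(h+1) / 4) ...

    expressed below in its usual multiplicative form.
    """
    if counts.n < 1:
        raise ValueError("need at least one genotyped individual")
    n = counts.n
    rare = counts.minor_allele_count
    if rare == 0:
        return 1.0
    obs_het = counts.n_het
    # heterozygote count shares the parity of the minor allele count
    het_values = np.arange(rare % 2, rare + 1, 2)
    probs = np.zeros(het_values.size)
    # start from the most probable (mode) heterozygote count for stability
    mode = int(rare * (2 * n - rare) / (2 * n))
    if mode % 2 != rare % 2:
        mode += 1
    mode = min(max(mode, het_values[0]), het_values[-1])
    mode_idx = int((mode - het_values[0]) // 2)
    probs[mode_idx] = 1.0
    # going down: P(h-2) = P(h) * h*(h-1) / ((rare-h+2)*(2n-rare-h+2))
    for i in range(mode_idx, 0, -1):
        h = het_values[i]
        probs[i - 1] = probs[i] * h * (h - 1) / ((rare - h + 2) * (2 * n - rare - h + 2))
    # going up: P(h+2) = P(h) * 4*(rare-h)/2*(2n-rare-h)/2 / ((h+2)*(h+1))
    for i in range(mode_idx, het_values.size - 1):
        h = het_values[i]
        probs[i + 1] = probs[i] * (rare - h) * (2 * n - rare - h) / ((h + 2) * (h + 1))
    probs /= probs.sum()
    p_obs = probs[int((obs_het - het_values[0]) // 2)]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# Linear regression
# ---------------------------------------------------------------------------

def _check_design(X: np.ndarray, names: list[str] | None) -> list[str]:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-d")
    names = names or [f"x{j}" for j in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("column names do not match design width")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns linearly dependent on their predecessors
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return names


def fit_linear(y: np.ndarray, X: np.ndarray, names: list[str] | None = None) -> ModelFit:
    """Ordinary least squares with classical (Gaussian) standard errors."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    names = _check_design(X, names)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    res = sm.OLS(y, X).fit()
    return ModelFit(
        coefficients=np.asarray(res.params, dtype=float),
        se=np.asarray(res.bse, dtype=float),
        loglik=float(res.llf),
        vcov=np.asarray(res.cov_params(), dtype=float),
        converged=True,
        n=X.shape[0],
        names=names,
        df_resid=int(res.df_resid),
    )


# ---------------------------------------------------------------------------
# Logistic regression (Newton IRLS, optional Firth fallback)
# ---------------------------------------------------------------------------

_MAX_ABS_COEF = 15.0  # |beta| beyond this is treated as separation


def _logistic_ll(y, X, beta):
    eta = np.clip(X @ beta, -30, 30)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def _newton_logistic(y, X, max_iter=100):
    n, p = X.shape
    beta = np.zeros(p)
    ll = _logistic_ll(y, X, beta)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step halving to guarantee likelihood ascent
        new_ll = -np.inf
        for k in range(25):
            cand = beta + step / (2**k)
            new_ll = _logistic_ll(y, X, cand)
            if new_ll >= ll - 1e-12:
                break
        beta = beta + step / (2**k)
        rel = abs(new_ll - ll) / (abs(ll) + 1e-12)
        ll = new_ll
        if np.max(np.abs(score)) < 1e-8 or rel < 1e-10:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    info = X.T @ (X * (mu * (1 - mu))[:, None])
    return beta, ll, info, converged


def _firth_logistic(y, X, max_iter=100):
    """Firth bias-reduced logistic regression (penalized likelihood)."""
    n, p = X.shape
    beta = np.zeros(p)

    def penalized(beta):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        info = X.T @ (X * (mu * (1 - mu))[:, None])
        sign, logdet = np.linalg.slogdet(info)
        return _logistic_ll(y, X, beta) + 0.5 * logdet, mu, info

    pll, mu, info = penalized(beta)
    converged = False
    for _ in range(max_iter):
        w = mu * (1 - mu)
        info_inv = np.linalg.inv(info)
        # hat-matrix diagonal under the working weights
        h = w * np.einsum("ij,jk,ik->i", X, info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        new_pll = -np.inf
        for k in range(25):
            cand = beta + step / (2**k)
            new_pll, new_mu, new_info = penalized(cand)
            if new_pll >= pll - 1e-12:
                break
        beta = beta + step / (2**k)
        rel = abs(new_pll - pll) / (abs(pll) + 1e-12)
        pll, mu, info = new_pll, new_mu, new_info
        if np.max(np.abs(score)) < 1e-6 or rel < 1e-12:
            converged = True
            break
    return beta, pll, info, converged


def fit_logistic(y: np.ndarray, X: np.ndarray, firth: bool = True, names: list[str] | None = None) -> ModelFit:
    """Maximum-likelihood logistic regression by Newton/IRLS.

    If the fit shows separation (diverging coefficients or non-convergence)
    and ``firth`` is true, refits with the Firth penalty and flags the
    result ``firth_fallback``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    names = _check_design(X, names)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("degenerate outcome: all observations have the same value")

    beta, ll, info, converged = _newton_logistic(y, X)
    flags: set = set()
    separated = (not converged) or np.max(np.abs(beta)) > _MAX_ABS_COEF
    if separated:
        flags.add("separation")
        if firth:
            beta, ll, info, converged = _firth_logistic(y, X)
            flags.add("firth_fallback")
    vcov = np.linalg.inv(info)
    se = np.sqrt(np.diag(vcov))
    return ModelFit(
        coefficients=beta, se=se, loglik=ll, vcov=vcov,
        converged=converged, n=X.shape[0], names=names, flags=flags,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)
# ---------------------------------------------------------------------------

def _cox_ll_grad_hess(time, event, X, beta):
    """Breslow partial log-likelihood with gradient and Hessian.

    Observations are sorted in decreasing time order so risk-set sums
    S0 = sum(r), S1 = sum(r x), S2 = sum(r x x') are cumulative sums
    evaluated at the end of each tied-time block; blocks with d deaths
    contribute d * log(S0) etc. once (Breslow).
    """
    order = np.argsort(-time, kind="stable")
    t, d, Xs = time[order], event[order], X[order]
    eta = np.clip(Xs @ beta, -200, 200)
    r = np.exp(eta)
    rx = Xs * r[:, None]
    n, p = Xs.shape

    cs0 = np.cumsum(r)
    cs1 = np.cumsum(rx, axis=0)
    cs2 = np.cumsum(np.einsum("ni,nj->nij", Xs, rx), axis=0)
    # last index of each tied-time block
    ends = np.nonzero(np.append(t[1:] != t[:-1], True))[0]
    starts = np.concatenate([[0], ends[:-1] + 1])
    ndeaths = np.add.reduceat(d, starts)
    has = ndeaths > 0
    if not has.any():
        return 0.0, np.zeros(p), np.zeros((p, p))
    e, dd = ends[has], ndeaths[has]
    s0 = cs0[e]
    m1 = cs1[e] / s0[:, None]
    m2 = cs2[e] / s0[:, None, None]

    dmask = d.astype(bool)
    ll = float(eta[dmask].sum() - (dd * np.log(s0)).sum())
    grad = Xs[dmask].sum(axis=0) - (dd[:, None] * m1).sum(axis=0)
    hess = -(np.einsum("b,bij->ij", dd, m2) - np.einsum("b,bi,bj->ij", dd, m1, m1))
    return ll, grad, hess


def fit_coxph(time: np.ndarray, event: np.ndarray, X: np.ndarray, names: list[str] | None = None,
              max_iter=100) -> ModelFit:
    """Cox proportional-hazards fit by Newton's method, Breslow ties.

    Censored observations (event == 0) contribute to risk sets only. The
    hazard ratio for a covariate is exp(coefficient). A monotone partial
    likelihood (a coefficient diverging) is flagged ``monotone_likelihood``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    X = np.asarray(X, dtype=float)
    names = _check_design(X, names)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    if event.sum() < 1:
        raise ValueError("no events observed; Cox model cannot be fitted")
    sd = X.std(axis=0)
    if (sd == 0).any():
        const = [names[j] for j in np.where(sd == 0)[0]]
        raise ValueError(f"constant covariates are unidentifiable in a Cox model: {const}")
    # standardize for numerical stability; transform back at the end
    mean = X.mean(axis=0)
    Z = (X - mean) / sd

    beta = np.zeros(X.shape[1])
    ll, grad, hess = _cox_ll_grad_hess(time, event, Z, beta)
    converged = False
    flags: set = set()
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        new = None
        for k in range(25):
            cand = beta + step / (2**k)
            new = _cox_ll_grad_hess(time, event, Z, cand)
            if new[0] >= ll - 1e-12:
                break
        beta = beta + step / (2**k)
        rel = abs(new[0] - ll) / (abs(ll) + 1e-12)
        ll, grad, hess = new
        if np.max(np.abs(grad)) < 1e-8 or rel < 1e-10:
            converged = True
            break
    if (not converged) or np.max(np.abs(beta)) > _MAX_ABS_COEF:
        flags.add("monotone_likelihood")
    vcov_z = np.linalg.inv(-hess)
    # back-transform: beta_x = beta_z / sd
    beta_x = beta / sd
    scale = np.outer(1.0 / sd, 1.0 / sd)
    vcov = vcov_z * scale
    return ModelFit(
        coefficients=beta_x, se=np.sqrt(np.diag(vcov)), loglik=ll, vcov=vcov,
        converged=converged, n=X.shape[0], names=names, flags=flags,
    )


# ---------------------------------------------------------------------------
# 2x2 tables
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of non-negative counts.

    Conditional on the margins, sums the hypergeometric probabilities of
    all tables at most as probable as the one observed (tiny relative
    guard for floating ties).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("cell counts must be non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n, r1, c1 = a + b + c + d, a + b, a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0  # degenerate margin: only one table possible
    support = np.arange(max(0, c1 - (c + d)), min(r1, c1) + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - support[0]]
    # normalize so that including the whole support gives exactly 1
    p = pmf[pmf <= p_obs * (1.0 + 1e-12)].sum() / pmf.sum()
    return float(min(1.0, p))


def odds_ratio_2x2(table):
    """Cross-product odds ratio with Woolf 95% CI.

    Haldane-Anscombe 0.5 continuity correction is applied (and flagged)
    only when some cell is zero. Returns (or, ci_low, ci_high, flags).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("cell counts must be non-negative")
    flags = set()
    if (t == 0).any():
        t = t + 0.5
        flags.add("haldane_anscombe")
    a, b = t[0]
    c, d = t[1]
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(orr) - Z95 * se), np.exp(np.log(orr) + Z95 * se)
    return float(orr), float(lo), float(hi), flags


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bonferroni(p, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m); m defaults to len(p)."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return np.minimum(1.0, p * m)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def wald_ci(effect: float, se: float, exponentiate: bool = False):
    lo, hi = effect - Z95 * se, effect + Z95 * se
    if exponentiate:
        with np.errstate(over="ignore"):  # a diverged bound becomes inf
            return float(np.exp(lo)), float(np.exp(hi))
    return float(lo), float(hi)


def wald_p(effect: float, se: float, df: int | None = None) -> float:
    """Two-sided Wald p; Student-t when a residual df is given, else normal."""
    if se <= 0:
        return 1.0
    z = effect / se
    if df is not None:
        return float(2 * sps.t.sf(abs(z), df))
    return float(2 * sps.norm.sf(abs(z)))
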
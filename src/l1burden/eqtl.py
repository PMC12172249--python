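"""Additive linear eQTL scan of L1 genotypes against expression, with
Benjamini-Hochberg FDR within tissue, plus the RC-vs-non-RC enrichment test.

Every (locus, transcript) pair within a tissue is tested — no cis-window
restriction. Per locus, the scan is an exact per-pair OLS of expression on
genotype with age and sex covariates, computed by the Frisch-Waugh
projection so all transcripts of a tissue are fitted in one vectorized
pass; the slope, SE and p for any pair are identical to a stand-alone
:func:`~l1burden.stats.fit_linear` on that pair.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import complete_case, covariate_design
from .stats import bh_fdr, fisher_exact_2x2
from .types import MISSING, ExpressionMatrix, GenotypeMatrix


def eqtl_scan(geno: GenotypeMatrix, expressions: list[ExpressionMatrix],
              phen: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Scan every locus against every transcript within each tissue.

    Model per pair: expression ~ genotype + age + sex; FDR is adjusted
    within tissue over all fitted pairs. Zero-variance transcripts and loci
    monomorphic among the tissue's genotyped samples are skipped.
    Returns the full pair table with a ``significant`` flag (FDR < 0.05).
    """
    frames = []
    for expr in expressions:
        shared = [s for s in expr.sample_ids if s in set(geno.sample_ids)]
        ph = phen[phen["sample_id"].isin(shared)]
        ph = complete_case(ph, ["age_years", "sex"])
        ids = [s for s in shared if s in set(ph["sample_id"])]
        ph = ph.set_index("sample_id").loc[ids].reset_index()
        C, _ = covariate_design(ph, ["sex", "age_years"])
        expr_cols = [expr.sample_ids.index(s) for s in ids]
        Y = expr.values[:, expr_cols].T  # n_samples x n_transcripts
        keep_t = np.ptp(Y, axis=0) > 0  # exact: a constant transcript is skipped
        Y = Y[:, keep_t]
        t_ids = [t for t, k in zip(expr.transcript_ids, keep_t) if k]
        G = geno.values[geno.sample_index(ids), :]
        n_cov = C.shape[1]

        recs = []
        for j, lid in enumerate(geno.locus_ids):
            g = G[:, j]
            called = g != MISSING
            n = int(called.sum())
            if n <= n_cov + 1:
                continue
            gv = g[called].astype(float)
            if gv.min() == gv.max():
                continue
            Cs = C[called]
            # residualize genotype and expression on the covariates
            Q, _ = np.linalg.qr(Cs)
            gr = gv - Q @ (Q.T @ gv)
            gg = float(gr @ gr)
            if gg <= 0:
                continue
            Ys = Y[called]
            Yr = Ys - Q @ (Q.T @ Ys)
            xy = gr @ Yr
            slope = xy / gg
            rss = np.einsum("ij,ij->j", Yr, Yr) - slope * xy
            dof = n - n_cov - 1
            sigma2 = np.maximum(rss, 0.0) / dof
            se = np.sqrt(sigma2 / gg)
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = np.where(se > 0, slope / se, np.inf)
            p = 2 * sps.t.sf(np.abs(tstat), dof)
            recs.append(pd.DataFrame({
                "locus_id": lid, "transcript_id": t_ids, "tissue": expr.tissue,
                "slope": slope, "se": se, "p_unadj": p, "n_used": n,
            }))
        if recs:
            tis = pd.concat(recs, ignore_index=True)
            tis["fdr"] = bh_fdr(tis["p_unadj"].to_numpy())
            frames.append(tis)
    if not frames:
        return pd.DataFrame(columns=["locus_id", "transcript_id", "tissue",
                                     "slope", "se", "p_unadj", "n_used", "fdr", "significant"])
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def significant_eqtl_loci(scan: pd.DataFrame) -> set[str]:
    """Loci significant for >= 1 transcript in >= 1 tissue (counted once)."""
    if scan.empty:
        return set()
    return set(scan.loc[scan["significant"], "locus_id"])


def rc_enrichment(eqtl_loci: set[str], tested_loci, rc_flags: dict[str, bool]):
    """Fisher's exact test of RC membership against eQTL status.

    ``tested_loci`` is the set of loci entering the scan; ``rc_flags`` maps
    locus id -> RC membership. Returns (proportion of RC loci that are
    eQTLs, proportion of all tested loci that are eQTLs, two-sided p,
    2x2 table). An empty eQTL set yields p = 1 and zero proportions.
    """
    tested = list(tested_loci)
    missing = [l for l in tested if l not in rc_flags]
    if missing:
        raise ValueError(f"rc_flags undefined for loci: {missing[:5]}")
    rc = np.array([rc_flags[l] for l in tested], dtype=bool)
    is_eqtl = np.array([l in eqtl_loci for l in tested], dtype=bool)
    table = np.array([
        [int((rc & is_eqtl).sum()), int((rc & ~is_eqtl).sum())],
        [int((~rc & is_eqtl).sum()), int((~rc & ~is_eqtl).sum())],
    ])
    n_rc, n_all = int(rc.sum()), len(tested)
    prop_rc = table[0, 0] / n_rc if n_rc else 0.0
    prop_all = int(is_eqtl.sum()) / n_all if n_all else 0.0
    if not is_eqtl.any():
        return 0.0, 0.0, 1.0, table
    return float(prop_rc), float(prop_all), fisher_exact_2x2(table), table
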
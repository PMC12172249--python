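#!/usr/bin/env python
"""Per-genome RC-L1 burden: disease model and >= k threshold scan.

Reads the QC'd burden matrix, computes each individual's Present-allele
count over the 89 retained RC loci, fits the linear burden-vs-status model
(the generator plants a 0.40-allele case-control shift), runs the logistic
threshold scan over k = 43..48 with Bonferroni over the six cut-points, and
fits the burden-onset and burden-survival models (both null by design).
Writes results/burden/*.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from l1burden import io as lio
from l1burden.burden import (
    burden_disease_model,
    burden_onset_and_survival,
    compute_burden,
    threshold_scan,
)
from l1burden.types import GenotypeMatrix

ROOT = Path(__file__).resolve().parents[1]


def main():
    argparse.ArgumentParser().parse_args()
    work = ROOT / "scratch" / "pipeline" / "qc"
    if not work.exists():
        raise SystemExit(f"missing {work}; run analysis/02_qc_filters.py first")
    geno = GenotypeMatrix.from_tsv(work / "genotypes_burden.tsv")
    phen = lio.read_phenotype_table(work / "phenotypes_cohort.tsv")

    profiles = compute_burden(geno)
    model = burden_disease_model(profiles, phen)
    scan = threshold_scan(profiles, phen)
    onset_res, surv_res = burden_onset_and_survival(profiles, phen)

    out = ROOT / "results" / "burden"
    out.mkdir(parents=True, exist_ok=True)
    scan.to_csv(out / "threshold_scan.tsv", sep="\t", index=False, float_format="%.5g")
    pd.DataFrame([model.to_dict(), onset_res.to_dict(), surv_res.to_dict()]).to_csv(
        out / "burden_models.tsv", sep="\t", index=False, float_format="%.5g")

    print(f"burden ~ status: beta = {model.effect:.3f} alleles "
          f"(SE {model.se:.3f}, p = {model.p_unadj:.3g}, n = {model.n_used})")
    print(f"burden ~ onset:  est = {onset_res.effect:.3f} y/allele (p = {onset_res.p_unadj:.2g})")
    print(f"burden ~ survival: HR = {surv_res.effect:.3f} (p = {surv_res.p_unadj:.2g})")
    print("\nthreshold scan (>= k Present alleles):")
    cols = ["threshold", "odds_ratio", "ci_low", "ci_high", "p_unadj", "p_bonferroni",
            "pct_controls_ge", "pct_cases_ge"]
    print(scan[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
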
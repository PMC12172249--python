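#!/usr/bin/env python
"""All-pairs eQTL scan in both motor-cortex tissues and RC enrichment.

Tests every (locus, transcript) pair with an additive linear model
(covariates age and sex), applies Benjamini-Hochberg FDR within tissue, and
asks whether retrotransposition-competent loci are enriched among eQTL loci
(Fisher's exact test on the RC x eQTL 2x2 table). Writes the significant
pairs and the enrichment summary under results/eqtl/.
"""

import argparse
from pathlib import Path

import pandas as pd

from l1burden import io as lio
from l1burden.eqtl import eqtl_scan, rc_enrichment, significant_eqtl_loci
from l1burden.simulate import TISSUES
from l1burden.types import GenotypeMatrix

ROOT = Path(__file__).resolve().parents[1]


def main():
    argparse.ArgumentParser().parse_args()
    work = ROOT / "scratch" / "pipeline" / "qc"
    fixture = ROOT / "scratch" / "pipeline" / "fixture"
    if not work.exists() or not fixture.exists():
        raise SystemExit("run analysis/01 and analysis/02 first")
    geno = GenotypeMatrix.from_tsv(work / "genotypes_qc.tsv")
    phen = lio.read_phenotype_table(work / "phenotypes_cohort.tsv")
    loci = lio.read_locus_table(work / "loci_qc.tsv")
    expressions = [lio.read_expression_matrix(fixture / f"expression_{t}.tsv", t)
                   for t in TISSUES]

    scan = eqtl_scan(geno, expressions, phen)
    sig_loci = significant_eqtl_loci(scan)
    sig_pairs = scan[scan["significant"]]
    tested = sorted(set(scan["locus_id"]))
    rc_flags = {l.locus_id: l.rc_flag for l in loci}
    prop_rc, prop_all, p, table = rc_enrichment(sig_loci, tested, rc_flags)

    out = ROOT / "results" / "eqtl"
    out.mkdir(parents=True, exist_ok=True)
    sig_pairs.to_csv(out / "significant_pairs.tsv", sep="\t", index=False,
                     float_format="%.5g")
    pd.DataFrame([{
        "n_tested_loci": len(tested),
        "n_eqtl_loci": len(sig_loci),
        "n_significant_pairs": len(sig_pairs),
        "n_transcripts": sig_pairs["transcript_id"].nunique(),
        "proportion_rc_eqtl": round(prop_rc, 4),
        "proportion_all_eqtl": round(prop_all, 4),
        "fisher_p": round(p, 4),
        "rc_eqtl": table[0, 0], "rc_not_eqtl": table[0, 1],
        "nonrc_eqtl": table[1, 0], "nonrc_not_eqtl": table[1, 1],
    }]).to_csv(out / "rc_enrichment.tsv", sep="\t", index=False)

    print(f"{len(sig_pairs)} significant pairs (FDR < 0.05): {len(sig_loci)} loci, "
          f"{sig_pairs['transcript_id'].nunique()} transcripts, of {len(tested)} tested loci")
    print(f"RC loci acting as eQTLs: {100 * prop_rc:.1f}% vs {100 * prop_all:.1f}% overall "
          f"(Fisher's exact p = {p:.2f})")


if __name__ == "__main__":
    main()
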
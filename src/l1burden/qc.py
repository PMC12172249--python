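"""Locus- and sample-level quality filters with a full accounting ledger.

Every filter returns what it kept plus a :class:`FilterLedger` recording,
step by step, how many items went in, how many were removed under which
criterion, and how many came out. Ledgers chain, so the pipeline can print
the complete locus accounting (e.g. the RC set shrinking 93 -> 89 after
removing sex-chromosome loci and one high-missingness locus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import GenotypeCounts, hwe_exact_test
from .types import GenotypeMatrix, MISSING


@dataclass
class LedgerStep:
    step: str
    n_in: int
    n_removed: int
    n_out: int
    criterion: str

    def __post_init__(self):
        if self.n_out != self.n_in - self.n_removed:
            raise ValueError(f"ledger step {self.step!r}: n_out != n_in - n_removed")


@dataclass
class FilterLedger:
    """Ordered filtering record; consecutive steps must chain (n_out -> n_in)."""

    unit: str = "loci"
    steps: list[LedgerStep] = field(default_factory=list)

    def add(self, step: str, n_in: int, n_removed: int, criterion: str) -> None:
        if not 0 <= n_removed <= n_in:
            raise ValueError(f"ledger step {step!r}: n_removed outside [0, n_in], n_out invalid")
        if self.steps and self.steps[-1].n_out != n_in:
            raise ValueError(
                f"ledger break at {step!r}: previous n_out {self.steps[-1].n_out} != n_in {n_in}"
            )
        self.steps.append(LedgerStep(step, n_in, n_removed, n_in - n_removed, criterion))

    def extend(self, other: "FilterLedger") -> "FilterLedger":
        for s in other.steps:
            self.add(s.step, s.n_in, s.n_removed, s.criterion)
        return self

    @property
    def n_out(self) -> int:
        return self.steps[-1].n_out if self.steps else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps],
                            columns=["step", "n_in", "n_removed", "n_out", "criterion"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __str__(self) -> str:
        return self.to_frame().to_string(index=False)


# ---------------------------------------------------------------------------
# Record-level caller-evidence filter (non-reference / MELT dialect only)
# ---------------------------------------------------------------------------

def filter_melt_records(loci, min_split_reads: int = 2, min_assess: int = 3):
    """Keep non-reference loci with >= 2 split reads, assessment score >= 3
    and a PASS caller filter; reference loci pass through untouched.

    Non-reference loci missing any evidence field fail, counted as a
    separate ledger step.
    """
    ledger = FilterLedger("loci")
    n_in = len(loci)
    no_evidence, failed, kept = [], [], []
    for rec in loci:
        if rec.source != "non_reference":
            kept.append(rec)
            continue
        if rec.split_reads is None or rec.assess_score is None or rec.caller_filter is None:
            no_evidence.append(rec)
        elif (rec.split_reads >= min_split_reads and rec.assess_score >= min_assess
              and rec.caller_filter == "PASS"):
            kept.append(rec)
        else:
            failed.append(rec)
    ledger.add("melt_evidence_missing", n_in, len(no_evidence),
               "non-reference locus lacking split-read/assessment/filter evidence")
    ledger.add("melt_quality", n_in - len(no_evidence), len(failed),
               f"split reads >= {min_split_reads} and assessment score >= {min_assess} and PASS")
    return kept, ledger


# ---------------------------------------------------------------------------
# Genotype-level filters
# ---------------------------------------------------------------------------

def _counts_from_column(col: np.ndarray) -> GenotypeCounts:
    return GenotypeCounts(
        n_hom_absent=int((col == 0).sum()),
        n_het=int((col == 1).sum()),
        n_hom_present=int((col == 2).sum()),
    )


def hwe_pvalues(geno: GenotypeMatrix, sample_ids) -> np.ndarray:
    """Exact HWE p per locus, computed on the given samples' non-missing calls.

    Loci with no genotyped individuals among those samples get p = 1 (no
    evidence against equilibrium).
    """
    sub = geno.values[geno.sample_index(sample_ids), :]
    p = np.ones(geno.n_loci)
    for j in range(geno.n_loci):
        counts = _counts_from_column(sub[:, j])
        if counts.n >= 1:
            p[j] = hwe_exact_test(counts)
    return p


def filter_hwe(geno: GenotypeMatrix, phen: pd.DataFrame, threshold: float = 1e-6):
    """Remove loci out of Hardy-Weinberg equilibrium in non-neurological
    controls (exact test p < threshold, strict)."""
    nnc = phen.loc[phen["diagnosis"] == "NNC", "sample_id"]
    nnc = [s for s in nnc if s in set(geno.sample_ids)]
    p = hwe_pvalues(geno, nnc)
    keep = p >= threshold
    ledger = FilterLedger("loci")
    ledger.add("hwe_controls", geno.n_loci, int((~keep).sum()),
               f"exact HWE p < {threshold:g} in NNCs (n={len(nnc)})")
    kept_ids = [lid for lid, k in zip(geno.locus_ids, keep) if k]
    return geno.subset(loci=kept_ids), ledger


def filter_maf(geno: GenotypeMatrix, min_maf: float = 0.01):
    """Keep loci with minor allele frequency strictly above ``min_maf``.

    Loci with no calls at all are removed first as degenerate.
    """
    ledger = FilterLedger("loci")
    called = geno.called_mask().sum(axis=0)
    degenerate = called == 0
    ledger.add("maf_degenerate", geno.n_loci, int(degenerate.sum()),
               "no non-missing genotypes")
    maf = geno.maf()
    keep = ~degenerate & (maf > min_maf)
    ledger.add("maf", int((~degenerate).sum()), int((~degenerate).sum() - keep.sum()),
               f"minor allele frequency > {min_maf:g} (strict)")
    kept_ids = [lid for lid, k in zip(geno.locus_ids, keep) if k]
    return geno.subset(loci=kept_ids), ledger


def filter_rc_for_burden(geno: GenotypeMatrix, loci, max_missing: float = 0.05):
    """Restrict to RC-flagged autosomal loci with missingness <= 5%.

    Sex-chromosome RC loci are removed so men and women can be compared on
    the same allele-count scale; loci with a missing-genotype fraction
    strictly above ``max_missing`` are removed.
    """
    by_id = {l.locus_id: l for l in loci}
    ledger = FilterLedger("loci")
    present = [lid for lid in geno.locus_ids if lid in by_id]
    rc_ids = [lid for lid in present if by_id[lid].rc_flag]
    ledger.add("rc_restrict", geno.n_loci, geno.n_loci - len(rc_ids),
               "member of the RC-L1 catalog")
    auto_ids = [lid for lid in rc_ids if by_id[lid].chrom not in ("X", "Y")]
    ledger.add("sex_chromosomes", len(rc_ids), len(rc_ids) - len(auto_ids),
               "located on chrX/chrY")
    sub = geno.subset(loci=auto_ids) if auto_ids else geno.subset(loci=[])
    miss = sub.missing_fraction()
    keep = miss <= max_missing
    ledger.add("high_missingness", len(auto_ids), int((~keep).sum()),
               f"missing genotype fraction > {max_missing:g} (strict)")
    kept_ids = [lid for lid, k in zip(sub.locus_ids, keep) if k]
    return sub.subset(loci=kept_ids), ledger


def restrict_complete_individuals(geno: GenotypeMatrix):
    """Keep only individuals genotyped at every retained burden locus."""
    complete = geno.called_mask().all(axis=1)
    ledger = FilterLedger("samples")
    ledger.add("complete_individuals", geno.n_samples, int((~complete).sum()),
               "missing genotype at >= 1 burden locus")
    kept = [s for s, c in zip(geno.sample_ids, complete) if c]
    return geno.subset(samples=kept), ledger


def select_analysis_cohort(phen: pd.DataFrame, min_european: float = 0.9):
    """European (>90%, strict) ALS / ALSND cases and NNC controls."""
    ledger = FilterLedger("samples")
    n_in = len(phen)
    euro = phen["european_fraction"] > min_european
    ledger.add("european", n_in, int((~euro).sum()),
               f"european_fraction > {min_european:g} (strict)")
    dx = phen["diagnosis"].isin(["ALS", "ALSND", "NNC"])
    keep = euro & dx
    ledger.add("diagnosis", int(euro.sum()), int(euro.sum() - keep.sum()),
               "diagnosis in {ALS, ALSND, NNC}")
    return list(phen.loc[keep, "sample_id"]), ledger
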
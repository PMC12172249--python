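"""Filtering ledger: caller evidence, HWE, MAF, RC/burden accounting."""

import numpy as np
import pandas as pd
import pytest

from l1burden.qc import (
    FilterLedger,
    filter_hwe,
    filter_maf,
    filter_melt_records,
    filter_rc_for_burden,
    restrict_complete_individuals,
    select_analysis_cohort,
)
from l1burden.stats import GenotypeCounts, hwe_exact_test
from l1burden.types import MISSING, GenotypeMatrix, LocusRecord


def _locus(lid, source="non_reference", chrom="1", pos=1, sr=5, score=4,
           filt="PASS", rc=False):
    rec = LocusRecord(locus_id=lid, chrom=chrom, pos=pos, source=source,
                      rc_flag=rc, caller_filter=filt)
    if source == "non_reference":
        rec.split_reads, rec.assess_score = sr, score
    return rec


# ---------------------------------------------------------------------------
# caller evidence
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("sr,score,filt,kept", [
    (1, 5, "PASS", False),   # too few split reads
    (2, 3, "PASS", True),    # inclusive boundaries
    (4, 2, "PASS", False),   # assessment score below cut
    (2, 3, "lq", False),     # non-PASS filter
    (10, 5, "PASS", True),
])
def test_melt_evidence_boundaries(sr, score, filt, kept):
    loci = [_locus("NRL1_1_1", sr=sr, score=score, filt=filt)]
    out, ledger = filter_melt_records(loci)
    assert (len(out) == 1) is kept
    assert ledger.n_out == len(out)


def test_melt_missing_evidence_counted_separately():
    bad = _locus("NRL1_1_1")
    bad.split_reads = None
    loci = [bad, _locus("NRL1_1_2", sr=1), _locus("RL1_1_3", source="reference")]
    out, ledger = filter_melt_records(loci)
    steps = {s.step: s for s in ledger.steps}
    assert steps["melt_evidence_missing"].n_removed == 1
    assert steps["melt_quality"].n_removed == 1
    # reference loci pass through untouched
    assert [l.locus_id for l in out] == ["RL1_1_3"]


# ---------------------------------------------------------------------------
# HWE filter
# ---------------------------------------------------------------------------

def _matrix(columns, sample_prefix="s"):
    vals = np.array(columns, dtype=np.int8).T
    return GenotypeMatrix([f"{sample_prefix}{i}" for i in range(vals.shape[0])],
                          [f"L{j}" for j in range(vals.shape[1])], vals)


def _phen(n, diagnosis="NNC"):
    return pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                         "diagnosis": diagnosis})


def test_hwe_monomorphic_kept():
    geno = _matrix([[0, 0, 0, 0, 0]])
    out, ledger = filter_hwe(geno, _phen(5))
    assert out.n_loci == 1 and ledger.steps[0].n_removed == 0


def test_hwe_extreme_het_deficit_removed():
    # 30 hom-absent + 30 hom-present, zero hets: enumeration p << 1e-6
    col = [0] * 30 + [2] * 30
    assert hwe_exact_test(GenotypeCounts(30, 0, 30)) < 1e-6
    out, _ = filter_hwe(_matrix([col]), _phen(60))
    assert out.n_loci == 0


def test_hwe_threshold_is_strict():
    col = [0] * 10 + [1] * 4 + [2] * 3
    p = hwe_exact_test(GenotypeCounts(10, 4, 3))
    geno = _matrix([col])
    kept_at_p, _ = filter_hwe(geno, _phen(17), threshold=p)
    assert kept_at_p.n_loci == 1          # p < threshold is strict: p == threshold kept
    removed, _ = filter_hwe(geno, _phen(17), threshold=p * 1.0001)
    assert removed.n_loci == 0


def test_hwe_uses_controls_only():
    # cases wildly out of HWE, controls in equilibrium -> kept
    col = [0, 1, 1, 0] + [0] * 10 + [2] * 10
    phen = pd.DataFrame({"sample_id": [f"s{i}" for i in range(24)],
                         "diagnosis": ["NNC"] * 4 + ["ALS"] * 20})
    out, _ = filter_hwe(_matrix([col]), phen)
    assert out.n_loci == 1


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------

def test_maf_common_insertion_kept():
    # IAF 0.77 -> MAF 0.23
    rng = np.random.default_rng(0)
    col = rng.binomial(2, 0.77, 200)
    out, _ = filter_maf(_matrix([col]))
    assert out.n_loci == 1


def test_maf_boundary_strict():
    # exactly MAF 0.01: 2 Present alleles in 100 diploids
    col = [1, 1] + [0] * 98
    out, _ = filter_maf(_matrix([col]))
    assert out.n_loci == 0
    col = [1, 1, 1] + [0] * 97  # MAF 0.015 > 0.01
    out, _ = filter_maf(_matrix([col]))
    assert out.n_loci == 1


def test_maf_all_missing_degenerate():
    out, ledger = filter_maf(_matrix([[MISSING] * 5]))
    assert out.n_loci == 0
    assert ledger.steps[0].step == "maf_degenerate" and ledger.steps[0].n_removed == 1


# ---------------------------------------------------------------------------
# RC burden accounting
# ---------------------------------------------------------------------------

def test_rc_burden_accounting_93_to_89():
    rng = np.random.default_rng(1)
    n = 400
    loci, cols = [], []
    for j in range(93):
        chrom = "X" if j < 3 else "1"
        loci.append(_locus(f"L{j}", chrom=chrom, pos=j + 1, rc=True))
        col = rng.binomial(2, 0.3, n).astype(np.int8)
        if j == 3:  # 6% missingness
            col[: int(0.06 * n)] = MISSING
        cols.append(col)
    loci.append(_locus("nonrc", pos=1000, rc=False))
    cols.append(rng.binomial(2, 0.3, n).astype(np.int8))
    geno = GenotypeMatrix([f"s{i}" for i in range(n)], [l.locus_id for l in loci],
                          np.array(cols).T)
    out, ledger = filter_rc_for_burden(geno, loci)
    frame = ledger.to_frame().set_index("step")
    assert frame.loc["rc_restrict", "n_out"] == 93
    assert frame.loc["sex_chromosomes", "n_removed"] == 3
    assert frame.loc["high_missingness", "n_removed"] == 1
    assert out.n_loci == 89


def test_missingness_boundary_inclusive():
    # exactly 5% missing is kept (strict > 5% removes)
    col = np.array([MISSING] * 5 + [1] * 95, dtype=np.int8)
    geno = GenotypeMatrix([f"s{i}" for i in range(100)], ["L0"], col[:, None])
    out, _ = filter_rc_for_burden(geno, [_locus("L0", rc=True)])
    assert out.n_loci == 1


def test_no_rc_loci_gives_empty_matrix():
    geno = _matrix([[0, 1, 2]])
    out, ledger = filter_rc_for_burden(geno, [_locus("L0", rc=False)])
    assert out.n_loci == 0 and ledger.n_out == 0


def test_complete_individuals():
    vals = np.zeros((10, 3), dtype=np.int8)
    vals[2, 1] = MISSING
    vals[7, 0] = MISSING
    geno = GenotypeMatrix([f"s{i}" for i in range(10)], ["a", "b", "c"], vals)
    out, ledger = restrict_complete_individuals(geno)
    assert out.n_samples == 8 and ledger.steps[0].n_removed == 2
    again, ledger2 = restrict_complete_individuals(out)
    assert again.n_samples == 8 and ledger2.steps[0].n_removed == 0


# ---------------------------------------------------------------------------
# cohort selection
# ---------------------------------------------------------------------------

def test_cohort_selection_boundaries():
    phen = pd.DataFrame({
        "sample_id": ["a", "b", "c", "d", "e"],
        "diagnosis": ["NNC", "ALS", "other_MND", "ALSND", "NNC"],
        "european_fraction": [0.95, 0.90, 0.99, 0.91, 0.89],
    })
    ids, ledger = select_analysis_cohort(phen)
    # 0.90 exactly is excluded (strict >); other_MND excluded by diagnosis
    assert ids == ["a", "d"]
    assert ledger.steps[0].n_removed == 2 and ledger.steps[1].n_removed == 1


# ---------------------------------------------------------------------------
# ledger mechanics and filter algebra
# ---------------------------------------------------------------------------

def test_ledger_conservation_and_chaining():
    led = FilterLedger()
    led.add("a", 100, 10, "x")
    led.add("b", 90, 5, "y")
    assert led.n_out == 85
    with pytest.raises(ValueError, match="ledger break"):
        led.add("c", 80, 1, "z")
    with pytest.raises(ValueError, match="n_removed"):
        FilterLedger().add("bad", 10, 20, "w")


def test_maf_and_hwe_filters_commute(small_cohort):
    geno, phen = small_cohort.geno, small_cohort.phen
    a1, _ = filter_hwe(geno, phen)
    a2, _ = filter_maf(a1)
    b1, _ = filter_maf(geno)
    b2, _ = filter_hwe(b1, phen)
    assert set(a2.locus_ids) & set(b2.locus_ids) == set(a2.locus_ids) == set(b2.locus_ids)


def test_filters_invariant_to_locus_order(small_cohort):
    geno, phen = small_cohort.geno, small_cohort.phen
    rng = np.random.default_rng(0)
    perm = list(rng.permutation(geno.locus_ids))
    out1, _ = filter_maf(geno)
    out2, _ = filter_maf(geno.subset(loci=perm))
    assert set(out1.locus_ids) == set(out2.locus_ids)
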
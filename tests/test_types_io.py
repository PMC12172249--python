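"""Domain types, VCF dialect coding, catalog handling and interval logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l1burden import io as lio
from l1burden.types import (
    MISSING,
    AssociationResult,
    GenotypeMatrix,
    LocusRecord,
    PhenotypeRecord,
    RcCatalog,
)

MELT_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##INFO=<ID=ASSESS,Number=1,Type=Integer,Description="score">
##INFO=<ID=SR,Number=1,Type=Integer,Description="split reads">
##FILTER=<ID=lq,Description="low quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\tD
1\t100\t.\tN\t<INS:ME:LINE1>\t.\tPASS\tASSESS=5;SR=4\tGT\t0/0\t0/1\t1/1\t./.
1\t200\tNRL1_1_200\tN\t<INS:ME:LINE1>\t.\tlq\tASSESS=2;SR=1\tGT\t0/.\t1/1\t0/0\t0/1
"""

DEL_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\tD
1\t100\t.\tN\t<DEL:ME:LINE1>\t.\tPASS\t.\tGT\t1/1\t0/1\t0/0\t./.
"""


def test_melt_dialect_coding(tmp_path):
    p = tmp_path / "m.vcf"
    p.write_text(MELT_VCF)
    loci, geno = lio.read_mei_vcf(p, dialect="melt")
    # GT 0/0, 0/1, 1/1, ./. -> Present counts 0, 1, 2, missing
    assert geno.values[:, 0].tolist() == [0, 1, 2, MISSING]
    # half-missing 0/. is missing
    assert geno.values[0, 1] == MISSING
    assert loci[0].locus_id == "NRL1_1_100"  # regenerated from coordinates
    assert loci[0].split_reads == 4 and loci[0].assess_score == 5
    assert loci[0].caller_filter == "PASS" and loci[1].caller_filter == "lq"


def test_deletion_dialect_complement_coding(tmp_path):
    p = tmp_path / "d.vcf"
    p.write_text(DEL_VCF)
    loci, geno = lio.read_mei_vcf(p, dialect="deletion_genotyping")
    # deletion of the reference element on both haplotypes -> 0 Present alleles
    assert geno.values[:, 0].tolist() == [0, 1, 2, MISSING]
    assert loci[0].source == "reference" and loci[0].locus_id == "RL1_1_100"


def test_unknown_dialect_rejected(tmp_path):
    with pytest.raises(ValueError, match="dialect"):
        lio.read_mei_vcf(tmp_path / "x.vcf", dialect="bogus")


def test_dialect_duality(tmp_path, small_cohort):
    """A cohort encoded melt-style and deletion-style (complemented GT)
    yields identical Present-allele matrices."""
    loci = [l for l in small_cohort.loci if l.source == "non_reference"][:40]
    ids = [l.locus_id for l in loci]
    sub = small_cohort.geno.subset(loci=ids)
    lio.write_mei_vcf(loci, sub, tmp_path / "as_melt.vcf", dialect="melt")
    lio.write_mei_vcf(loci, sub, tmp_path / "as_del.vcf", dialect="deletion_genotyping")
    _, g1 = lio.read_mei_vcf(tmp_path / "as_melt.vcf", dialect="melt")
    _, g2 = lio.read_mei_vcf(tmp_path / "as_del.vcf", dialect="deletion_genotyping")
    assert g1.locus_ids == g2.locus_ids
    assert np.array_equal(g1.values, g2.values)
    assert np.array_equal(g1.subset(loci=ids).values, sub.values)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(n_samples=st.integers(1, 8), n_loci=st.integers(1, 6), seed=st.integers(0, 2**31 - 1))
def test_genotype_tsv_round_trip(tmp_path_factory, n_samples, n_loci, seed):
    rng = np.random.default_rng(seed)
    vals = rng.choice([0, 1, 2, MISSING], size=(n_samples, n_loci)).astype(np.int8)
    gm = GenotypeMatrix([f"s{i}" for i in range(n_samples)],
                        [f"L{j}" for j in range(n_loci)], vals)
    p = tmp_path_factory.mktemp("tsv") / "g.tsv"
    gm.to_tsv(p)
    back = GenotypeMatrix.from_tsv(p)
    assert back.sample_ids == gm.sample_ids and back.locus_ids == gm.locus_ids
    assert np.array_equal(back.values, gm.values)


def test_iaf_bounds_and_fixed_locus():
    gm = GenotypeMatrix(["a", "b"], ["L1", "L2", "L3"],
                        np.array([[2, 0, MISSING], [2, 1, MISSING]], dtype=np.int8))
    iaf = gm.iaf()
    assert iaf[0] == 1.0                       # Present-fixed locus
    assert iaf[1] == pytest.approx(0.25)
    assert np.isnan(iaf[2])                    # no calls
    assert np.nanmax(iaf) <= 1.0 and np.nanmin(iaf) >= 0.0


def test_genotype_matrix_validation():
    with pytest.raises(ValueError, match="shape"):
        GenotypeMatrix(["a"], ["x", "y"], np.zeros((1, 1), dtype=np.int8))
    with pytest.raises(ValueError, match="0, 1, 2"):
        GenotypeMatrix(["a"], ["x"], np.array([[5]], dtype=np.int8))
    with pytest.raises(ValueError, match="duplicate"):
        GenotypeMatrix(["a", "a"], ["x"], np.zeros((2, 1), dtype=np.int8))


# ---------------------------------------------------------------------------
# RC catalog
# ---------------------------------------------------------------------------

def _write_catalog(path, rows):
    path.write_text("locus_id\tsource\n" + "".join(f"{k}\t{s}\n" for k, s in rows))


def test_catalog_counts(tmp_path):
    rows = [(f"RL1_1_{i}", "reference") for i in range(102)]
    rows += [(f"NRL1_2_{i}", "non_reference") for i in range(177)]
    p = tmp_path / "cat.tsv"
    _write_catalog(p, rows)
    cat = lio.read_rc_catalog(p)
    assert len(cat) == 279
    assert cat.n_reference == 102 and cat.n_non_reference == 177


def test_catalog_empty_and_duplicates(tmp_path):
    empty = tmp_path / "empty.tsv"
    empty.write_text("")
    assert len(lio.read_rc_catalog(empty)) == 0
    dup = tmp_path / "dup.tsv"
    _write_catalog(dup, [("RL1_1_5", "reference"), ("RL1_1_5", "reference")])
    with pytest.raises(ValueError, match="duplicate"):
        lio.read_rc_catalog(dup)


def _locus(lid, chrom="1", pos=100, source="non_reference"):
    return LocusRecord(locus_id=lid, chrom=chrom, pos=pos, source=source)


def test_annotate_rc_flag_counts():
    loci = [_locus(f"NRL1_1_{i}", pos=i + 1) for i in range(5)]
    cat = RcCatalog({"NRL1_1_1": "non_reference", "NRL1_1_3": "non_reference"})
    _, n = lio.annotate_rc(loci, cat)
    assert n == 2
    assert [l.rc_flag for l in loci] == [False, True, False, True, False]
    _, n0 = lio.annotate_rc(loci, RcCatalog())
    assert n0 == 0


def test_annotate_rc_matches_polymorphic_catalog_members():
    # a registry constructed to contain 106 catalog members is fully flagged
    loci = [_locus(f"NRL1_7_{i + 1}", pos=i + 1) for i in range(500)]
    members = {l.locus_id: "non_reference" for l in loci[:106]}
    extras = {f"RL1_9_{i + 1}": "reference" for i in range(279 - 106)}
    _, n = lio.annotate_rc(loci, RcCatalog({**members, **extras}))
    assert n == 106


# ---------------------------------------------------------------------------
# genomic context / gene intersection
# ---------------------------------------------------------------------------

FEATURES = [
    ("1", 0, 1000, "gene_body"),
    ("1", 100, 200, "exon"),
    ("1", 100, 150, "utr5"),
    ("1", 900, 1000, "utr3"),
]


def test_context_precedence():
    assert lio.classify_genomic_context(_locus("a", pos=120), FEATURES) == "exonic"
    assert lio.classify_genomic_context(_locus("b", pos=950), FEATURES) == "utr3"
    assert lio.classify_genomic_context(_locus("c", pos=500), FEATURES) == "intronic"
    assert lio.classify_genomic_context(_locus("d", pos=5000), FEATURES) == "intergenic"
    assert lio.classify_genomic_context(_locus("e", chrom="2", pos=120), FEATURES) == "intergenic"


def test_gene_intersection_pairs():
    genes = [("1", 0, 1000), ("1", 500, 2000), ("2", 0, 100)]
    names = ["G1", "G2", "G3"]
    hits = lio.intersect_with_gene_list([_locus("a", pos=600)], genes, names)
    assert sorted(hits) == [("a", "G1"), ("a", "G2")]  # overlapping genes both hit
    assert lio.intersect_with_gene_list([_locus("b", pos=5000)], genes, names) == []


# ---------------------------------------------------------------------------
# phenotype / association-result invariants
# ---------------------------------------------------------------------------

def test_phenotype_record_invariants():
    with pytest.raises(ValueError, match="survival"):
        PhenotypeRecord("s1", "ALS", "male", survival_months=0.0)
    with pytest.raises(ValueError, match="onset"):
        PhenotypeRecord("s1", "NNC", "male", age_at_onset_years=55.0)
    with pytest.raises(ValueError, match="diagnosis"):
        PhenotypeRecord("s1", "healthy", "male")


def test_phenotype_table_round_trip(tmp_path, small_cohort):
    p = tmp_path / "phen.tsv"
    lio.write_phenotype_table(small_cohort.phen, p, metadata={"seed": 11})
    back = lio.read_phenotype_table(p)
    a = small_cohort.phen.reset_index(drop=True)
    a = a.mask(a.isna())
    pd.testing.assert_frame_equal(back, a[back.columns], check_dtype=False)


def test_association_result_invariants():
    with pytest.raises(ValueError, match="confidence"):
        AssociationResult("t", 1.0, 0.1, 1.2, 1.5, 0.05, 0.05, 10, "linear")
    with pytest.raises(ValueError, match="adjusted"):
        AssociationResult("t", 1.0, 0.1, 0.8, 1.2, 0.05, 0.01, 10, "linear")
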
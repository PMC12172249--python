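"""Readers and writers for the formats the pipeline consumes and emits.

Two VCF dialects are supported for mobile-element-insertion genotypes:

``melt``
    Non-reference insertions called MELT-style: ALT allele 1 *is* the
    insertion, so the Present-allele count equals the ALT allele count.
    Call-quality evidence is read from configurable INFO keys
    (defaults ``ASSESS`` and ``SR``) plus the FILTER column.

``deletion_genotyping``
    Reference elements genotyped as deletions (Delly-style): ALT allele 1
    is the *deletion* of the element, so Present count = 2 - ALT count.

A genotype with any missing allele (``./.`` or half-calls like ``0/.``) is
treated as missing.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    MISSING,
    ExpressionMatrix,
    GenotypeMatrix,
    LocusRecord,
    RcCatalog,
    locus_id_for,
    normalize_chrom,
    validate_phenotypes,
)

DIALECTS = ("melt", "deletion_genotyping")


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def read_mei_vcf(path, dialect: str, assess_key: str = "ASSESS", sr_key: str = "SR"):
    """Read one MEI genotype VCF into (loci, GenotypeMatrix).

    Returns Present-allele counts regardless of dialect (see module
    docstring). Locus ids are taken from the ID column when set, otherwise
    regenerated from coordinates.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown VCF dialect {dialect!r}; expected one of {DIALECTS}")
    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # pragma: no cover - depends on htslib message
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    source = "non_reference" if dialect == "melt" else "reference"
    samples = list(vcf.samples)
    loci: list[LocusRecord] = []
    columns: list[np.ndarray] = []
    for lineno, var in enumerate(vcf, start=1):
        try:
            gts = var.genotype.array()
        except Exception as exc:
            raise ValueError(f"malformed VCF record in {path} (record {lineno}): {exc}") from exc
        alleles = gts[:, :2]
        missing = (alleles < 0).any(axis=1)
        alt = np.clip(alleles, 0, 1).sum(axis=1)
        present = alt if dialect == "melt" else 2 - alt
        present = np.where(missing, MISSING, present).astype(np.int8)
        lid = var.ID if var.ID not in (None, ".") else locus_id_for(var.CHROM, var.POS, source)
        rec = LocusRecord(
            locus_id=lid,
            chrom=normalize_chrom(var.CHROM),
            pos=var.POS,
            source=source,
            caller_filter=var.FILTER or "PASS",
        )
        if dialect == "melt":
            a = var.INFO.get(assess_key)
            s = var.INFO.get(sr_key)
            rec.assess_score = int(a) if a is not None else None
            rec.split_reads = int(s) if s is not None else None
        loci.append(rec)
        columns.append(present)
    ids = [l.locus_id for l in loci]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate locus ids in {path}")
    values = (
        np.column_stack(columns) if columns else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return loci, GenotypeMatrix(samples, ids, values)


_VCF_HEADER = """\
##fileformat=VCFv4.2
{meta}##INFO=<ID={assess},Number=1,Type=Integer,Description="Caller assessment score">
##INFO=<ID={sr},Number=1,Type=Integer,Description="Supporting split reads">
##FILTER=<ID=lq,Description="Low quality call">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""

_GT_BY_ALT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_mei_vcf(loci, geno: GenotypeMatrix, path, dialect: str,
                  assess_key: str = "ASSESS", sr_key: str = "SR",
                  metadata: dict | None = None) -> None:
    """Write loci + Present-allele genotypes as a VCF in the given dialect.

    Inverse of :func:`read_mei_vcf`: melt encodes Present count as the ALT
    count, deletion_genotyping encodes 2 - Present.
    ``metadata`` entries become ##key=value header lines.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown VCF dialect {dialect!r}")
    order = sorted(range(len(loci)), key=lambda i: (loci[i].chrom, loci[i].pos))
    meta = "".join(f"##{k}={v}\n" for k, v in (metadata or {}).items())
    contigs = "".join(
        f"##contig=<ID={c}>\n" for c in dict.fromkeys(loci[i].chrom for i in order)
    )
    alt_sym = "<INS:ME:LINE1>" if dialect == "melt" else "<DEL:ME:LINE1>"
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(meta=meta, assess=assess_key, sr=sr_key,
                                    contigs=contigs, samples="\t".join(geno.sample_ids)))
        col = geno.locus_index([loci[i].locus_id for i in order])
        for i, j in zip(order, col):
            rec = loci[i]
            present = geno.values[:, j]
            alt = np.where(present == MISSING, MISSING,
                           present if dialect == "melt" else 2 - present)
            gts = "\t".join(_GT_BY_ALT[int(a)] for a in alt)
            info = "."
            if dialect == "melt":
                parts = []
                if rec.assess_score is not None:
                    parts.append(f"{assess_key}={rec.assess_score}")
                if rec.split_reads is not None:
                    parts.append(f"{sr_key}={rec.split_reads}")
                info = ";".join(parts) or "."
            filt = rec.caller_filter or "PASS"
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.locus_id}\tN\t{alt_sym}\t.\t{filt}\t{info}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# RC catalog
# ---------------------------------------------------------------------------

def read_rc_catalog(path) -> RcCatalog:
    """Read the curated RC-L1 catalog (TSV with columns locus_id, source)."""
    entries: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return RcCatalog()
        for field in ("locus_id", "source"):
            if field not in reader.fieldnames:
                raise ValueError(f"RC catalog {path} lacks required column {field!r}")
        for row in reader:
            key = row["locus_id"].strip()
            src = row["source"].strip()
            if src not in ("reference", "non_reference"):
                raise ValueError(f"RC catalog {path}: unknown source {src!r} for {key}")
            if key in entries:
                raise ValueError(f"RC catalog {path}: duplicate entry {key!r}")
            entries[key] = src
    return RcCatalog(entries)


def write_rc_catalog(catalog: RcCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tsource\n")
        for key, src in catalog.entries.items():
            fh.write(f"{key}\t{src}\n")


def annotate_rc(loci, catalog: RcCatalog):
    """Set rc_flag on every locus whose id or coordinate key is in the catalog.

    Returns the same list (records mutated in place) and the number flagged.
    """
    n = 0
    for rec in loci:
        coord_key = f"{rec.chrom}_{rec.pos}"
        rec.rc_flag = rec.locus_id in catalog or coord_key in catalog
        n += rec.rc_flag
    return loci, n


# ---------------------------------------------------------------------------
# Genomic context
# ---------------------------------------------------------------------------

#: precedence when a position falls in several features
_CONTEXT_PRECEDENCE = ["exon", "utr5", "utr3", "intron", "gene_body"]
_CONTEXT_LABEL = {
    "exon": "exonic",
    "utr5": "utr5",
    "utr3": "utr3",
    "intron": "intronic",
    "gene_body": "intronic",  # inside a gene but no finer feature: intronic
}


def classify_genomic_context(locus: LocusRecord, feature_intervals) -> str:
    """Classify one insertion point against 0-based half-open feature intervals.

    ``feature_intervals`` is an iterable of (chrom, start, end, feature)
    with feature in {exon, utr5, utr3, intron, gene_body}. Precedence:
    exon > utr5 > utr3 > intron > intergenic.
    """
    pos0 = locus.pos - 1  # VCF 1-based -> 0-based point
    hits = set()
    for chrom, start, end, feature in feature_intervals:
        if normalize_chrom(chrom) == locus.chrom and start <= pos0 < end:
            if feature not in _CONTEXT_LABEL:
                raise ValueError(f"unknown feature label {feature!r}")
            hits.add(feature)
    for feature in _CONTEXT_PRECEDENCE:
        if feature in hits:
            return _CONTEXT_LABEL[feature]
    return "intergenic"


def intersect_with_gene_list(loci, gene_intervals, gene_names):
    """All (locus_id, gene_name) pairs where the insertion point falls in a gene.

    ``gene_intervals`` are (chrom, start, end) 0-based half-open, parallel to
    ``gene_names``. Overlapping genes each yield a pair.
    """
    if len(gene_intervals) != len(gene_names):
        raise ValueError("gene_intervals and gene_names must be parallel")
    pairs = []
    for rec in loci:
        pos0 = rec.pos - 1
        for (chrom, start, end), name in zip(gene_intervals, gene_names):
            if normalize_chrom(chrom) == rec.chrom and start <= pos0 < end:
                pairs.append((rec.locus_id, name))
    return pairs


# ---------------------------------------------------------------------------
# Phenotypes, expression, locus tables
# ---------------------------------------------------------------------------

def read_phenotype_table(path) -> pd.DataFrame:
    phen = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"sample_id": str, "seq_prep": str},
    )
    if "event_observed" in phen.columns:
        phen["event_observed"] = phen["event_observed"].map(
            {1: True, 0: False, "1": True, "0": False, True: True, False: False,
             "True": True, "False": False}
        )
    return validate_phenotypes(phen)


def write_phenotype_table(phen: pd.DataFrame, path, metadata: dict | None = None) -> None:
    phen = validate_phenotypes(phen)
    out = phen.copy()
    out["event_observed"] = out["event_observed"].map({True: 1, False: 0})
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        out.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_expression_matrix(path, tissue: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix(
        tissue=tissue,
        transcript_ids=[str(t) for t in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression_matrix(expr: ExpressionMatrix, path, metadata: dict | None = None) -> None:
    df = pd.DataFrame(expr.values, index=expr.transcript_ids, columns=expr.sample_ids)
    df.index.name = "transcript_id"
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t")


_LOCUS_COLUMNS = ["locus_id", "chrom", "pos", "source", "rc_flag",
                  "genomic_context", "split_reads", "assess_score", "caller_filter"]


def loci_to_frame(loci) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(l, c) for c in _LOCUS_COLUMNS} for l in loci],
                        columns=_LOCUS_COLUMNS)


def write_locus_table(loci, path) -> None:
    loci_to_frame(loci).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_locus_table(path) -> list[LocusRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], comment="#")
    out = []
    for row in df.itertuples(index=False):
        out.append(LocusRecord(
            locus_id=str(row.locus_id), chrom=str(row.chrom), pos=int(row.pos),
            source=str(row.source), rc_flag=bool(row.rc_flag),
            genomic_context=None if pd.isna(row.genomic_context) else str(row.genomic_context),
            split_reads=None if pd.isna(row.split_reads) else int(row.split_reads),
            assess_score=None if pd.isna(row.assess_score) else int(row.assess_score),
            caller_filter=None if pd.isna(row.caller_filter) else str(row.caller_filter),
        ))
    return out
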
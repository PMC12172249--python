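"""Core domain containers for the polymorphic-L1 analysis.

The counted allele is always the insertion-Present ("P") allele: a genotype
value is the number of haplotypes carrying the L1 insertion, regardless of
whether the element is present in the reference assembly (where its absence
is called as a deletion) or absent from it (where it is called as a novel
insertion).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing genotype call

SOURCES = ("reference", "non_reference")
GENOMIC_CONTEXTS = ("intergenic", "intronic", "exonic", "utr5", "utr3")
DIAGNOSES = ("NNC", "ALS", "ALSND", "other_MND", "other_neuro")

#: phenotype table columns, in canonical order
PHENOTYPE_COLUMNS = [
    "sample_id",
    "diagnosis",
    "sex",
    "age_years",
    "age_at_onset_years",
    "site_of_onset",
    "survival_months",
    "event_observed",
    "seq_prep",
    "european_fraction",
]


def locus_id_for(chrom: str, pos: int, source: str) -> str:
    """Canonical locus id: NRL1_<chrom>_<pos> for non-reference insertions,
    RL1_<chrom>_<pos> for reference elements. The chrom part never carries a
    "chr" prefix."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    prefix = "NRL1" if source == "non_reference" else "RL1"
    return f"{prefix}_{c}_{pos}"


def normalize_chrom(chrom: str, use_prefix: bool = False) -> str:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return f"chr{c}" if use_prefix else c


@dataclass
class LocusRecord:
    """One polymorphic L1 insertion locus.

    ``pos`` is the 1-based VCF position (insertion point for non-reference
    loci, reference-element start for reference loci). Evidence fields
    (``split_reads``, ``assess_score``) are only meaningful for
    non-reference loci called by a MELT-style caller.
    """

    locus_id: str
    chrom: str
    pos: int
    source: str
    rc_flag: bool = False
    genomic_context: str | None = None
    split_reads: int | None = None
    assess_score: int | None = None
    caller_filter: str | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown locus source {self.source!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.genomic_context is not None and self.genomic_context not in GENOMIC_CONTEXTS:
            raise ValueError(f"unknown genomic context {self.genomic_context!r}")


@dataclass
class RcCatalog:
    """Curated catalog of retrotransposition-competent (RC) L1s.

    ``entries`` maps a key (locus id, or ``<chrom>_<pos>`` coordinate key)
    to its source label.
    """

    entries: dict[str, str] = field(default_factory=dict)

    @property
    def n_reference(self) -> int:
        return sum(1 for s in self.entries.values() if s == "reference")

    @property
    def n_non_reference(self) -> int:
        return sum(1 for s in self.entries.values() if s == "non_reference")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self.entries


class GenotypeMatrix:
    """Samples x loci matrix of insertion-Present allele counts.

    Values are int8 in {0, 1, 2} with :data:`MISSING` (-1) for no-call.
    """

    def __init__(self, sample_ids: Sequence[str], locus_ids: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=np.int8)
        if values.shape != (len(sample_ids), len(locus_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(sample_ids)} samples x {len(locus_ids)} loci"
            )
        bad = ~np.isin(values, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values must be 0, 1, 2 or missing (-1)")
        self.sample_ids = list(sample_ids)
        self.locus_ids = list(locus_ids)
        self.values = values
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in ids], dtype=int)

    def locus_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.locus_ids)}
        return np.array([lookup[s] for s in ids], dtype=int)

    def subset(self, samples: Sequence[str] | None = None, loci: Sequence[str] | None = None) -> "GenotypeMatrix":
        v = self.values
        sids = self.sample_ids if samples is None else list(samples)
        lids = self.locus_ids if loci is None else list(loci)
        if samples is not None:
            v = v[self.sample_index(sids), :]
        if loci is not None:
            v = v[:, self.locus_index(lids)]
        return GenotypeMatrix(sids, lids, v.copy())

    # -- summaries -------------------------------------------------------
    def called_mask(self) -> np.ndarray:
        return self.values != MISSING

    def iaf(self) -> np.ndarray:
        """Per-locus insertion allele frequency over non-missing calls.

        Loci with no calls at all get NaN.
        """
        called = self.called_mask()
        n_called = called.sum(axis=0)
        alt = np.where(called, self.values, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        p = self.iaf()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        # direct ratio so an exactly-5% locus compares equal to 0.05
        return (self.values == MISSING).sum(axis=0) / self.n_samples

    # -- concatenation and I/O -------------------------------------------
    @staticmethod
    def concat_loci(parts: Sequence["GenotypeMatrix"]) -> "GenotypeMatrix":
        """Column-bind matrices sharing the same sample ordering."""
        first = parts[0]
        for p in parts[1:]:
            if p.sample_ids != first.sample_ids:
                raise ValueError("sample orderings differ between parts")
        lids = [l for p in parts for l in p.locus_ids]
        return GenotypeMatrix(first.sample_ids, lids, np.hstack([p.values for p in parts]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.astype(object), index=self.sample_ids, columns=self.locus_ids)
        return df.mask(df == MISSING, other=pd.NA)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", na_rep="NA")

    @staticmethod
    def from_tsv(path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id", comment="#")
        vals = df.to_numpy(dtype=float)
        vals = np.where(np.isnan(vals), MISSING, vals).astype(np.int8)
        return GenotypeMatrix([str(s) for s in df.index], [str(c) for c in df.columns], vals)


@dataclass
class PhenotypeRecord:
    """Per-individual phenotype and covariates.

    ``age_years`` is age at collection for controls and age at symptom onset
    for cases; ``event_observed`` False means censored at last follow-up.
    """

    sample_id: str
    diagnosis: str
    sex: str
    age_years: float | None = None
    age_at_onset_years: float | None = None
    site_of_onset: str | None = None
    survival_months: float | None = None
    event_observed: bool | None = None
    seq_prep: str = "prep1"
    european_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.survival_months is not None and not self.survival_months > 0:
            raise ValueError("survival_months must be > 0 when present")
        if not 0.0 <= self.european_fraction <= 1.0:
            raise ValueError("european_fraction must lie in [0, 1]")
        if self.age_at_onset_years is not None and self.diagnosis not in ("ALS", "ALSND"):
            raise ValueError("age_at_onset only applies to ALS/ALSND")


def validate_phenotypes(phen: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table against the record invariants.

    Returns the frame with columns in canonical order.
    """
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in phen.columns]
    if missing_cols:
        raise ValueError(f"phenotype table missing columns: {missing_cols}")
    if phen["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in phenotype table")
    bad_dx = set(phen["diagnosis"]) - set(DIAGNOSES)
    if bad_dx:
        raise ValueError(f"unknown diagnoses: {sorted(bad_dx)}")
    surv = phen["survival_months"].dropna()
    if (surv <= 0).any():
        raise ValueError("survival_months must be > 0 when present")
    ef = phen["european_fraction"]
    if ((ef < 0) | (ef > 1)).any():
        raise ValueError("european_fraction must lie in [0, 1]")
    onset = phen["age_at_onset_years"].notna() & ~phen["diagnosis"].isin(["ALS", "ALSND"])
    if onset.any():
        raise ValueError("age_at_onset_years present for non-ALS/ALSND samples")
    out = phen[PHENOTYPE_COLUMNS].copy()
    return out.mask(out.isna())  # normalize None vs NaN


@dataclass
class ExpressionMatrix:
    """Normalized expression, transcripts x samples, for one tissue."""

    tissue: str
    transcript_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.transcript_ids), len(self.sample_ids)):
            raise ValueError("expression values shape does not match id lists")
        if len(set(self.transcript_ids)) != len(self.transcript_ids):
            raise ValueError("duplicate transcript ids")


@dataclass
class AssociationResult:
    """One association test: effect with Wald 95% CI and p-values.

    ``scale`` records whether ``effect`` is a coefficient ("linear",
    "log-odds", "log-hazard") or exponentiated ("or", "hr").
    """

    test_id: str
    effect: float
    se: float
    ci_low: float
    ci_high: float
    p_unadj: float
    p_adj: float
    n_used: int
    model: str
    scale: str = "linear"
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if np.isfinite(self.effect) and not (self.ci_low <= self.effect <= self.ci_high):
            raise ValueError("effect must lie inside its confidence interval")
        if self.p_adj < self.p_unadj - 1e-12:
            raise ValueError("adjusted p cannot be smaller than unadjusted p")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["flags"] = ";".join(sorted(self.flags))
        return d
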
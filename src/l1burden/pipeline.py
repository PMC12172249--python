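"""End-to-end stage wiring: QC -> burden -> per-locus scans -> eQTL.

Each stage is a plain function over in-memory objects so the CLI, the
analysis drivers, the tests and the acceptance script all run the same
code. A :class:`RunManifest` records config hash, seed and output checksums
per stage so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assoc import casecontrol_scan, forest_table, onset_scan, survival_scan
from .burden import (
    DEFAULT_THRESHOLDS,
    burden_disease_model,
    burden_onset_and_survival,
    compute_burden,
    threshold_scan,
)
from .eqtl import eqtl_scan, rc_enrichment, significant_eqtl_loci
from .qc import (
    FilterLedger,
    filter_hwe,
    filter_maf,
    filter_melt_records,
    filter_rc_for_burden,
    restrict_complete_individuals,
    select_analysis_cohort,
)
from .types import GenotypeMatrix

log = logging.getLogger("l1burden")


@dataclass
class QcResult:
    """Everything downstream stages need, with the full filter accounting."""

    loci: list                      # loci surviving caller-evidence + HWE QC
    geno: GenotypeMatrix            # analysis-cohort genotypes at those loci
    phen: pd.DataFrame              # analysis-cohort phenotypes
    scan_geno: GenotypeMatrix       # MAF-filtered loci for per-locus scans
    burden_geno: GenotypeMatrix     # RC autosomal complete-case burden matrix
    locus_ledger: FilterLedger
    sample_ledger: FilterLedger
    scan_ledger: FilterLedger
    burden_locus_ledger: FilterLedger
    burden_sample_ledger: FilterLedger


def run_qc(loci, geno: GenotypeMatrix, phen: pd.DataFrame,
           maf_cohort: str = "analysis", min_maf: float = 0.01,
           hwe_threshold: float = 1e-6) -> QcResult:
    """Apply the full filtering ledger.

    Order: caller-evidence filter (non-reference loci) -> analysis-cohort
    selection (>90% European, ALS/ALSND vs NNC) -> exact HWE in controls ->
    branch into (a) the MAF > 0.01 scan set and (b) the RC autosomal
    low-missingness burden set with complete-case individuals.
    ``maf_cohort`` selects whether MAF is computed on the analysis cohort
    (default) or the full genotyped cohort.
    """
    loci_kept, locus_ledger = filter_melt_records(loci)
    geno = geno.subset(loci=[l.locus_id for l in loci_kept])

    cohort_ids, sample_ledger = select_analysis_cohort(phen)
    phen_cohort = phen[phen["sample_id"].isin(cohort_ids)].reset_index(drop=True)
    geno_cohort = geno.subset(samples=cohort_ids)

    geno_qc, hwe_ledger = filter_hwe(geno_cohort, phen_cohort, threshold=hwe_threshold)
    locus_ledger.extend(hwe_ledger)
    kept_ids = set(geno_qc.locus_ids)
    loci_qc = [l for l in loci_kept if l.locus_id in kept_ids]

    if maf_cohort == "analysis":
        scan_geno, scan_ledger = filter_maf(geno_qc, min_maf=min_maf)
    elif maf_cohort == "full":
        full_qc = geno.subset(loci=geno_qc.locus_ids)
        scan_full, scan_ledger = filter_maf(full_qc, min_maf=min_maf)
        scan_geno = geno_qc.subset(loci=scan_full.locus_ids)
    else:
        raise ValueError(f"maf_cohort must be 'analysis' or 'full', got {maf_cohort!r}")

    rc_geno, burden_locus_ledger = filter_rc_for_burden(geno_qc, loci_qc)
    burden_geno, burden_sample_ledger = restrict_complete_individuals(rc_geno)

    for name, ledger in [("locus QC", locus_ledger), ("cohort", sample_ledger),
                         ("scan loci", scan_ledger), ("burden loci", burden_locus_ledger),
                         ("burden individuals", burden_sample_ledger)]:
        log.info("filter ledger [%s]:\n%s", name, ledger)
    return QcResult(
        loci=loci_qc, geno=geno_qc, phen=phen_cohort, scan_geno=scan_geno,
        burden_geno=burden_geno, locus_ledger=locus_ledger, sample_ledger=sample_ledger,
        scan_ledger=scan_ledger, burden_locus_ledger=burden_locus_ledger,
        burden_sample_ledger=burden_sample_ledger,
    )


def run_burden(qc: QcResult, thresholds=DEFAULT_THRESHOLDS) -> dict:
    """Burden profiles, disease model, threshold scan, onset and survival models."""
    profiles = compute_burden(qc.burden_geno)
    model = burden_disease_model(profiles, qc.phen)
    scan = threshold_scan(profiles, qc.phen, thresholds=thresholds)
    onset_res, surv_res = burden_onset_and_survival(profiles, qc.phen)
    log.info("burden model: beta=%.3f p=%.3g (n=%d); Bonferroni family m=%d",
             model.effect, model.p_unadj, model.n_used, scan["p_unadj"].notna().sum())
    return {"profiles": profiles, "model": model, "threshold_scan": scan,
            "onset": onset_res, "survival": surv_res}


def run_assoc(qc: QcResult, firth: bool = True) -> dict:
    """Per-locus case-control, onset and survival scans over the MAF-filtered set."""
    cc = casecontrol_scan(qc.scan_geno, qc.phen, firth=firth)
    onset = onset_scan(qc.scan_geno, qc.phen)
    surv = survival_scan(qc.scan_geno, qc.phen)
    for name, t in [("case-control", cc), ("onset", onset), ("survival", surv)]:
        log.info("%s scan: m=%d loci fitted", name, t.attrs.get("bonferroni_m", -1))
    return {
        "casecontrol": cc, "onset": onset, "survival": surv,
        "casecontrol_forest": forest_table(cc, "odds_ratio"),
        "survival_forest": forest_table(surv, "hazard_ratio"),
    }


def run_eqtl(qc: QcResult, expressions, fdr_threshold: float = 0.05) -> dict:
    """All-pairs eQTL scan plus the RC enrichment test over tested loci."""
    scan = eqtl_scan(qc.geno, expressions, qc.phen, fdr_threshold=fdr_threshold)
    sig = significant_eqtl_loci(scan)
    tested = sorted(set(scan["locus_id"])) if not scan.empty else []
    rc_flags = {l.locus_id: l.rc_flag for l in qc.loci}
    prop_rc, prop_all, p, table = rc_enrichment(sig, tested, rc_flags)
    log.info("eQTL: %d significant loci of %d tested; RC %.1f%% vs overall %.1f%% (p=%.3g)",
             len(sig), len(tested), 100 * prop_rc, 100 * prop_all, p)
    return {"scan": scan, "significant_loci": sig, "proportion_rc": prop_rc,
            "proportion_all": prop_all, "enrichment_p": p, "table": table}


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str = ""
    seed: int | None = None
    version: str = __version__
    stages: list = field(default_factory=list)

    def add_stage(self, name: str, inputs: list, outputs: list) -> None:
        self.stages.append({
            "stage": name,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()},
            "outputs": {str(p): _sha256(Path(p)) for p in outputs if Path(p).is_file()},
        })

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @staticmethod
    def read(path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        m = RunManifest(config_hash=d.get("config_hash", ""), seed=d.get("seed"),
                        version=d.get("version", ""))
        m.stages = d.get("stages", [])
        return m
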
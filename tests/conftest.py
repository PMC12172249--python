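import pytest

from l1burden.pipeline import run_qc
from l1burden.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort: full structure (RC set, chrX/high-missingness loci,
    caller-evidence and HWE decoys, planted effects) at a fraction of the size."""
    return SimConfig(
        n_controls=80, n_cases=220, n_other_diagnosis=5, n_low_european=4,
        n_reference_loci=30, n_non_reference_loci=120, n_melt_fail=4, n_hwe_fail=2,
        n_rc_loci=20, n_rc_reference=6, n_rc_x=2, n_rc_high_missing=1, n_burden_common=2,
        n_expression_samples=60, n_transcripts=20, n_eqtl_loci=4, n_eqtl_rc=2,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the full default configuration (320 controls / 2,653
    cases, 2,803 QC-passing loci)."""
    return simulate_cohort(seed=7)


@pytest.fixture(scope="session")
def default_qc(default_cohort):
    c = default_cohort
    return run_qc(c.loci, c.geno, c.phen)
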
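import numpy as np
import pytest

from phenoharmon.phenodef import AssignmentTable, build_definition
from phenoharmon.simdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with noisy classifiers, reused by read-only tests."""
    cfg = SimConfig(
        n_cases_per_subtype=150,
        n_controls=400,
        n_snps=300,
        h2_liability=0.3,
        prevalence=0.10,
        target_kappa=0.6,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return AssignmentTable.from_cohort(small_cohort)


@pytest.fixture(scope="session")
def svs_definitions(small_table):
    return {
        kind: build_definition(small_table, "SVS", kind)
        for kind in ("CCSC", "CCSP", "TOAST", "intersect", "union", "symmetric_difference")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
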
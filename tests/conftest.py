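import numpy as np
import pytest

import rvburden as rv


@pytest.fixture(scope="session")
def small_cfg():
    """A desk-scale cohort with carrier rates high enough for non-trivial
    per-gene tables."""
    return rv.SimulationConfig(
        n_cases=60,
        n_controls=240,
        n_genes=120,
        baseline_carrier_rate=(0.02, 0.03, 0.04),
        enrichment_or=2.0,
        enrichment_loeuf_max=0.6,
        n_trios=30,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return rv.simulate_gene_panel(small_cfg)


@pytest.fixture(scope="session")
def small_cohort(small_cfg, small_panel):
    return rv.simulate_cohort(small_cfg, small_panel)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return rv.matrix_from_arrays(
        small_cohort.genes, small_cohort.samples, small_cohort.X_all, "flex_lof"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
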
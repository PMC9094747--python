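import numpy as np
import pandas as pd
import pytest

from myokinet import SimulationConfig, simulate_cohort
from myokinet.io_filter import log_cpm


@pytest.fixture(scope="session")
def default_cohort():
    """The default planted-truth cohort (100 male / 50 female, 3 target
    tissues, 2000 genes per tissue, 200 myokines) shared across tests."""
    cfg = SimulationConfig.default(seed=11)
    bundle, samples, truth = simulate_cohort(cfg)
    return cfg, bundle, samples, truth


@pytest.fixture(scope="session")
def default_cohort_logged(default_cohort):
    cfg, bundle, samples, truth = default_cohort
    logged = {t: log_cpm(m) for t, m in bundle.matrices.items()}
    return cfg, logged, samples, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A miniature cohort for fast structural tests."""
    edges = [
        dict(myokine="MYOK_0001", target_tissue="liver", target_gene="LIV_G0001",
             strength=0.5, sex_class="shared"),
        dict(myokine="MYOK_0002", target_tissue="liver", target_gene="LIV_G0002",
             strength=0.5, sex_class="male_only"),
        dict(myokine="MYOK_0003", target_tissue="pancreas", target_gene="PAN_G0001",
             strength=0.5, sex_class="female_only"),
    ]
    cfg = SimulationConfig(
        seed=4, n_male=30, n_female=20, genes_per_tissue=120, n_myokines=30,
        n_de_myokines=6, markers_per_cell_type=5, planted_edges=tuple(edges),
    )
    bundle, samples, truth = simulate_cohort(cfg)
    return cfg, bundle, samples, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
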
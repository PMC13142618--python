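import numpy as np
import pytest

from glioprog.synthetic import (
    CohortConfig,
    SpatialConfig,
    generate_cohort,
    generate_spatial_sample,
)


def small_config(seed: int = 0, **overrides) -> CohortConfig:
    """Cohort scaled for unit tests: default composition structure, small
    expression panel."""
    kwargs = dict(
        seed=seed,
        n_donors_per_group={"UPR": 3, "Reactive": 3, "Homeostatic": 3},
        n_cells_per_donor=300,
        n_genes=200,
        n_markers_per_subpop=5,
        n_markers_per_class=5,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_config(seed=42)
    matrix, annotations, truth = generate_cohort(cfg)
    return cfg, matrix, annotations, truth


@pytest.fixture(scope="session")
def spatial_sample():
    cfg = SpatialConfig(n_cells=3000, n_panel_genes=12, n_spatial_genes=3)
    return cfg, generate_spatial_sample(cfg, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
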
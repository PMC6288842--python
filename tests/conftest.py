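import logging

import pytest

from whitemap import (
    SimConfig,
    classify_segregation,
    pairwise_all,
    simulate_cross,
)

logging.getLogger("whitemap").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cross():
    """A 3-group cross with all three segregation types, no genotyping error."""
    cfg = SimConfig(n_groups=3, markers_per_group=40, mean_spacing_cM=2.5,
                    female_expansion=1.5, error_rate=0.0, missing_rate=0.05, seed=11)
    true_map, matrix, truth = simulate_cross(cfg)
    return cfg, true_map, matrix, truth


@pytest.fixture(scope="session")
def small_cross_estimates(small_cross):
    _, _, matrix, _ = small_cross
    seg = classify_segregation(matrix)
    return matrix, seg, pairwise_all(matrix, seg)
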
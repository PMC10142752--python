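import warnings

import numpy as np
import pytest

import gliaquant as gq
from gliaquant.config import (
    CONTROL_FRACTIONS,
    DISEASE_FRACTIONS,
    GroupSpec,
    ImageParams,
    SimulationConfig,
)


@pytest.fixture(scope="session")
def cohort():
    """Default two-region control/disease cohort, 10 cases per subgroup."""
    cfg = gq.default_cohort_config(n_cases=10, cells_per_case=600)
    cells, truth = gq.generate_cell_table(cfg, seed=3)
    return cfg, cells, truth


@pytest.fixture(scope="session")
def flagged(cohort):
    """Cohort cells with fitted thresholds and MOI^high flags."""
    _, cells, truth = cohort
    thresholds = gq.fit_thresholds(cells)
    return gq.classify_moi(cells, thresholds), thresholds, truth


@pytest.fixture(scope="session")
def small_image_cohort():
    """Small rendered cohort: 2 control + 2 disease motor-cortex cases."""
    ip = ImageParams(
        width_px=512,
        height_px=512,
        noise_sd=10.0,
        n_astrocytes=4,
        aggregate_count_per_case=8,
        bleedthrough_coefficient=0.0,
    )
    cfg = SimulationConfig(
        groups=[
            GroupSpec(
                "control", "motor_cortex", 2, dict(CONTROL_FRACTIONS), aggregates=False
            ),
            GroupSpec("disease", "motor_cortex", 2, dict(DISEASE_FRACTIONS)),
        ],
        cells_per_case=60,
        image_params=ip,
    )
    image_sets, truth = gq.generate_image_set(cfg, seed=7)
    return cfg, image_sets, truth


@pytest.fixture(scope="session")
def clustered(flagged):
    """Clustering run on a balanced 4x400 subsample of the cohort."""
    cells, _, truth = flagged
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = gq.run_clustering(
            cells, gq.EmbeddingConfig(n_per_group=400, perplexity=40, seed=0)
        )
    return result, truth


def brute_force_knn(points: np.ndarray, k: int) -> set[tuple[int, int]]:
    """Independent kNN oracle: full distance matrix, ties by index order,
    union-symmetrised edge set."""
    n = len(points)
    edges = set()
    for i in range(n):
        d = np.sqrt(((points - points[i]) ** 2).sum(axis=1))
        order = sorted((dj, j) for j, dj in enumerate(d) if j != i)
        for _, j in order[:k]:
            edges.add((min(i, j), max(i, j)))
    return edges
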
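import numpy as np
import pandas as pd
import pytest

from pcapam50 import (
    CentroidSet,
    ExpressionMatrix,
    PipelineConfig,
    SimConfig,
    make_centroids,
    run_pipeline,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def centroids():
    """Fixed 50-gene synthetic centroid panel (the fixture panel)."""
    return make_centroids(50, 1.0, seed=0)


@pytest.fixture(scope="session")
def cohort(centroids):
    """Default 300-sample cohort with 10% IHC-ER discordance."""
    return simulate_cohort(centroids, SimConfig(seed=11))


@pytest.fixture(scope="session")
def concordant_cohort(centroids):
    """Cohort with IHC ER identical to expression ER (no flips)."""
    return simulate_cohort(centroids, SimConfig(seed=11, er_discordance_rate=0.0))


@pytest.fixture(scope="session")
def small_cohort(centroids):
    """The packaged 60-sample smoke fixture."""
    return simulate_cohort(centroids, SimConfig(n_samples=60, seed=5))


@pytest.fixture(scope="session")
def pipeline_result(cohort, centroids):
    return run_pipeline(cohort.expression, cohort.clinical, centroids, PipelineConfig(seed=11))


@pytest.fixture
def toy_matrix():
    """3 genes x 2 samples, unique identifiers."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2"],
        )
    )


def toy_centroids_3g():
    """3-gene centroid set for hand-checkable classification examples."""
    profiles = pd.DataFrame(
        {
            "Basal": [3.0, 2.0, 1.0],
            "Her2": [1.0, 3.0, 2.0],
            "LumA": [1.0, 2.0, 3.0],
            "LumB": [2.0, 1.0, 3.0],
            "Normal": [2.0, 3.0, 1.0],
        },
        index=["g1", "g2", "g3"],
    )
    return CentroidSet(profiles)
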
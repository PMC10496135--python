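import numpy as np
import pytest

from seb3r import (
    ClusteringConfig,
    SimulationConfig,
    TrackingSession,
    default_archetypes,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_session():
    """3 frames x 6 hotspots with easily hand-checkable z values."""
    z = np.array(
        [
            [5.0, 4.0, 3.0, 2.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        ]
    )
    return TrackingSession(subject_id="156", session_label="OF", z=z, fps=25.0)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A compact planted cohort shared by the slower integration tests.

    3 subjects x 2 sessions x 600 frames, 5 archetypes all expressed,
    default noise; returns (mother folder, ground truth, configs).
    """
    root = tmp_path_factory.mktemp("cohort")
    archetypes = default_archetypes(5)
    config = SimulationConfig(
        n_subjects=3,
        n_sessions=2,
        frames_per_session=600,
        min_expressed=5,
        missing_prob=0.01,
        seed=7,
    )
    truth = simulate_cohort(archetypes, config, root, force=True)
    return root, truth, archetypes, config


@pytest.fixture
def cluster_config():
    return ClusteringConfig(seed=0)
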
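import numpy as np
import pytest

from matcher import CellFeatureMatrix, RunConfig, SimSpec, simulate_modality


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_config():
    """Config trimmed for unit-test speed (single restart)."""
    return RunConfig(seed=7, n_restarts=1, max_iter=400)


@pytest.fixture
def smooth_sim():
    """Small low-noise modality with smooth 1-D latent structure."""
    spec = SimSpec(n_cells=60, n_features=30, warp_family="identity",
                   noise_sigma=0.5, feature_range=16.0, seed=42,
                   modality_name="toy")
    return simulate_modality(spec)


@pytest.fixture
def tiny_matrix():
    values = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.5]]
    return CellFeatureMatrix(values, ["c1", "c2", "c3"], ["fA", "fB"], "demo")
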
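import numpy as np
import pytest

from klse.synthetic import RegionSpec, simulate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_subject():
    """3-region subject with distinct Gaussian intensity laws."""
    spec = [
        RegionSpec(region_id=1, mu=1.0, sigma=0.1, n_voxels=200),
        RegionSpec(region_id=2, mu=1.0, sigma=0.1, n_voxels=200),
        RegionSpec(region_id=3, mu=1.3, sigma=0.15, n_voxels=200),
    ]
    return simulate_subject(spec, jitter_sd=0.0, seed=7, subject_id="toy")


def random_weight_matrix(rng: np.random.Generator, n: int, density: float = 1.0) -> np.ndarray:
    """Random symmetric positive-weight matrix with zero diagonal."""
    W = rng.uniform(0.1, 1.0, size=(n, n))
    W = (W + W.T) / 2
    if density < 1.0:
        mask = rng.random((n, n)) < density
        mask = np.triu(mask, 1)
        mask = mask | mask.T
        W = W * mask
    np.fill_diagonal(W, 0.0)
    return W
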
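import numpy as np
import pytest

from msicomplete import PhantomSpec, SpectraMatrix, make_phantom


def lowrank_truth(m, n, r, seed):
    """Non-negative exactly rank-r matrix from uniform factors."""
    rng = np.random.default_rng(seed)
    A = rng.uniform(0.0, 1.0, (m, r))
    B = rng.uniform(0.0, 1.0, (n, r))
    return A @ B.T


@pytest.fixture
def small_matrix():
    return SpectraMatrix.from_dense(
        np.array([[1.0, 0.5], [2.0, 3.0]]),
        pixel_coords=np.array([[0, 0], [1, 0]]),
        mz_axis=np.array([100.0, 101.0]),
    )


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noiseless_phantom():
    return make_phantom(
        PhantomSpec(grid=(20, 20), n_bins=200, n_regions=3, n_peaks=12,
                    noise_sd=0.0, clip_density=1.0, seed=3)
    )
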
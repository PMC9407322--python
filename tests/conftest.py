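import numpy as np
import pytest

from jujubespec.dataset import SimConfig, generate_spectra


@pytest.fixture(scope="session")
def small_set():
    """Compact simulated spectra used across tests (40/60/20 x 50 bands)."""
    return generate_spectra(SimConfig(class_counts=(40, 60, 20), n_bands=50, seed=0))


@pytest.fixture(scope="session")
def paper_sized_set():
    """Simulated spectra at the study's class counts and band count."""
    return generate_spectra(SimConfig(seed=7))


@pytest.fixture
def blob_data():
    """Three well-separated Gaussian blobs (linearly separable)."""
    rng = np.random.default_rng(0)
    X = np.vstack([
        rng.normal(0.0, 0.3, (40, 4)),
        rng.normal(3.0, 0.3, (40, 4)),
        rng.normal(-3.0, 0.3, (40, 4)),
    ])
    y = np.array(["a"] * 40 + ["b"] * 40 + ["c"] * 40)
    return X, y


@pytest.fixture
def ortho_blob_data():
    """Three blobs with mutually orthogonal class means (PLS-DA separable)."""
    rng = np.random.default_rng(0)
    means = [np.array([4.0, 0, 0, 0]), np.array([0, 4.0, 0, 0]), np.array([0, 0, 4.0, 0])]
    X = np.vstack([rng.normal(m, 0.3, (40, 4)) for m in means])
    y = np.array(["a"] * 40 + ["b"] * 40 + ["c"] * 40)
    return X, y


def make_informative_data(seed, n=150, p=30, informative=(3, 11, 22), noise=0.3):
    """Classification data whose labels depend on 3 bands; the rest is noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    score = (
        X[:, informative[0]]
        + 0.8 * X[:, informative[1]]
        - 0.9 * X[:, informative[2]]
        + noise * rng.normal(size=n)
    )
    y = np.digitize(score, np.quantile(score, [1 / 3, 2 / 3]))
    return X, y
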
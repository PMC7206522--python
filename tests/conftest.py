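import numpy as np
import pytest
from scipy.signal import lfilter


def ar1(n: int, phi: float, rng: np.random.Generator, sd: float = 1.0) -> np.ndarray:
    """Fast AR(1) draw via linear filtering of white noise (stationary start)."""
    e = rng.standard_normal(n + 100) * sd
    y = lfilter([1.0], [1.0, -phi], e)
    return y[100:]


def independent_pair(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Two independent AR(1) series, stacked (n, 2) — a Granger null draw."""
    return np.column_stack([ar1(n, phi, rng), ar1(n, phi, rng)])


def coupled_pair(n: int, b: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """x autonomous AR(1); y_t = b·x_{t-1} + noise (no own memory)."""
    x = ar1(n + 1, phi, rng)
    y = b * x[:-1] + rng.standard_normal(n)
    return np.column_stack([x[1:], y])


def random_stable_fit(rng: np.random.Generator, p: int = 1, max_radius: float = 0.95):
    """Random stable coefficient matrices and a random SPD innovation covariance."""
    from idiovar.synthetic import spectral_radius

    while True:
        A = rng.uniform(-0.6, 0.6, size=(p, 2, 2)) / p
        if spectral_radius(A) < max_radius:
            break
    L = rng.uniform(-1.0, 1.0, size=(2, 2))
    sigma = L @ L.T + 0.5 * np.eye(2)
    return A, sigma


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)
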
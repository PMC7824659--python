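import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from moverstayer import SpatialKernel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def swap_kernel() -> SpatialKernel:
    """Two-zone kernel where every mover swaps zones."""
    return SpatialKernel([[0.0, 1.0], [1.0, 0.0]], zero_diagonal=True)


def power_iteration_stationary(p: np.ndarray, steps: int = 10_000) -> np.ndarray:
    """Independent stationary-vector oracle: brute-force lazy power iteration.

    Iterates the half-lazy chain (I + P)/2, which has the same stationary
    vectors as P but converges even for periodic kernels.
    """
    x = np.full(p.shape[0], 1.0 / p.shape[0])
    for _ in range(steps):
        x = 0.5 * (x + x @ p)
    return x / x.sum()


def random_stochastic_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Dense strictly positive row-stochastic matrix (primitive by construction)."""
    m = rng.random((n, n)) + 1e-3
    return m / m.sum(axis=1, keepdims=True)
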
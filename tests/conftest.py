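import numpy as np
import pytest

from gadpipe import ContactMatrix


def make_uniform_matrix(
    n: int = 60, value: float = 2.0, bin_size: int = 10_000, diag: float = 0.0
) -> ContactMatrix:
    """Matrix with every off-diagonal entry equal to ``value``."""
    v = np.full((n, n), float(value))
    np.fill_diagonal(v, diag)
    return ContactMatrix("chrS", bin_size, v)


@pytest.fixture
def uniform_matrix() -> ContactMatrix:
    return make_uniform_matrix()


@pytest.fixture
def random_symmetric_matrix() -> ContactMatrix:
    rng = np.random.default_rng(42)
    a = rng.uniform(0.5, 2.0, (50, 50))
    return ContactMatrix("chrS", 10_000, (a + a.T) / 2)
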
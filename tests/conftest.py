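import numpy as np
import pytest

from stripevol.simulate import default_fixture, simulate_bd_tree


@pytest.fixture(scope="session")
def fixture27():
    """The packaged study-scale synthetic dataset (27 tips, 8 codings)."""
    return default_fixture(0)


@pytest.fixture(scope="session")
def tree12():
    return simulate_bd_tree(0.3, 0.1, 12, seed=3)


@pytest.fixture(scope="session")
def tree20():
    return simulate_bd_tree(0.4, 0.1, 20, seed=42)


def random_q(rng, k, scale=0.5):
    """Random valid rate matrix with off-diagonals in [0, scale)."""
    Q = rng.uniform(0, scale, (k, k))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q
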
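import numpy as np
import pytest

from aberrant import CountMatrix, RealMatrix, SimulationConfig, simulate_counts


@pytest.fixture
def tiny_counts() -> CountMatrix:
    return CountMatrix(
        genes=["g1", "g2"],
        samples=["s1", "s2"],
        values=np.array([[2, 4], [8, 16]]),
    )


@pytest.fixture
def random_counts() -> CountMatrix:
    rng = np.random.default_rng(42)
    values = rng.integers(1, 200, size=(30, 8))
    return CountMatrix(
        genes=[f"g{j}" for j in range(30)],
        samples=[f"s{i}" for i in range(8)],
        values=values,
    )


@pytest.fixture(scope="session")
def sim_confounded():
    """Rank-3-confounded NB dataset reused across detection tests."""
    return simulate_counts(SimulationConfig(n_confounders=3, seed=1))


@pytest.fixture(scope="session")
def sim_null():
    """Confounder-free NB dataset."""
    return simulate_counts(SimulationConfig(n_confounders=0, seed=1))


def real_from(values: np.ndarray) -> RealMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return RealMatrix(
        genes=[f"g{j}" for j in range(values.shape[0])],
        samples=[f"s{i}" for i in range(values.shape[1])],
        values=values,
    )
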
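import numpy as np
import pandas as pd
import pytest

from slidr import MutationMatrix, ViabilityScreen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_screen():
    """4 genes × 3 cells with one missing entry."""
    vals = pd.DataFrame(
        [
            [-2.0, 0.5, 1.0],
            [0.0, -1.0, np.nan],
            [1.0, 0.0, -0.5],
            [3.0, 2.0, 0.0],
        ],
        index=["g1", "g2", "g3", "g4"],
        columns=["c1", "c2", "c3"],
    )
    return ViabilityScreen(values=vals)


@pytest.fixture
def random_screen(rng):
    """50 genes × 30 cells, fully observed."""
    vals = pd.DataFrame(
        rng.normal(size=(50, 30)),
        index=[f"g{i}" for i in range(50)],
        columns=[f"c{j}" for j in range(30)],
    )
    return ViabilityScreen(values=vals)


@pytest.fixture
def random_muts(rng):
    """10 drivers × 30 cells, each driver mutated in ≥2 cells."""
    m = np.zeros((10, 30), dtype=int)
    for i in range(10):
        k = int(rng.integers(2, 9))
        m[i, rng.choice(30, size=k, replace=False)] = 1
    return MutationMatrix(
        values=pd.DataFrame(
            m, index=[f"d{i}" for i in range(10)], columns=[f"c{j}" for j in range(30)]
        )
    )
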
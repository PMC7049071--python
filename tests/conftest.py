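import numpy as np
import pytest

from jsdbalance import BalanceTable, ProbabilityVector, glucose_example

#: Published outpatient counts: glucose level (rows) x treatment group (columns).
GLUCOSE_COUNTS = np.array(
    [
        [7191, 3637, 64265],
        [1025, 835, 7298],
        [1715, 685, 6932],
    ]
)
GLUCOSE_LEVELS = ("<109", "109-125", ">125")
GLUCOSE_GROUPS = ("Disadvantaged", "Elderly", "Reference")


@pytest.fixture
def glucose_table() -> BalanceTable:
    return BalanceTable(GLUCOSE_LEVELS, GLUCOSE_GROUPS, GLUCOSE_COUNTS)


@pytest.fixture
def packaged_glucose_table() -> BalanceTable:
    return glucose_example()


def random_balance_table(rng: np.random.Generator) -> BalanceTable:
    """A random contingency table with every column total positive."""
    m = rng.integers(2, 7)
    n = rng.integers(2, 5)
    counts = rng.integers(0, 50, size=(m, n))
    counts[:2, :] += 1  # at least two non-empty levels, positive column totals
    levels = tuple(f"c{i}" for i in range(m))
    groups = tuple(f"g{k}" for k in range(n))
    return BalanceTable(levels, groups, counts)


def random_distribution(rng: np.random.Generator, m: int) -> ProbabilityVector:
    probs = rng.dirichlet(np.ones(m))
    return ProbabilityVector(tuple(f"x{i}" for i in range(m)), probs)
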
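"""Shared fixtures: tiny hand-built networks and random discrete datasets."""

import numpy as np
import pytest

from dcmi import BayesianNetwork, DiscreteDataset


@pytest.fixture(scope="session")
def chain_bn() -> BayesianNetwork:
    """A -> B -> C with strong, noisy-copy conditionals."""
    return BayesianNetwork(
        ["A", "B", "C"],
        [2, 2, 2],
        {"B": ["A"], "C": ["B"]},
        {
            "A": [[0.5, 0.5]],
            "B": [[0.9, 0.1], [0.1, 0.9]],
            "C": [[0.8, 0.2], [0.2, 0.8]],
        },
    )


@pytest.fixture(scope="session")
def collider_bn() -> BayesianNetwork:
    """A -> C <- B: B is a spouse of A through the shared child C."""
    return BayesianNetwork(
        ["A", "B", "C"],
        [2, 2, 2],
        {"C": ["A", "B"]},
        {
            "A": [[0.5, 0.5]],
            "B": [[0.6, 0.4]],
            "C": [[0.9, 0.1], [0.3, 0.7], [0.2, 0.8], [0.05, 0.95]],
        },
    )


@pytest.fixture(scope="session")
def strong5_bn() -> BayesianNetwork:
    """Five nodes with strong dependences: A -> C <- B, C -> D -> E.

    Built for finite-sample recovery: every edge is a high-fidelity noisy
    copy / noisy-XOR, so blankets are recoverable from moderate samples.
    """
    xor = [
        [0.9, 0.1],  # A=0, B=0
        [0.1, 0.9],  # A=0, B=1
        [0.1, 0.9],  # A=1, B=0
        [0.9, 0.1],  # A=1, B=1
    ]
    copy85 = [[0.85, 0.15], [0.15, 0.85]]
    return BayesianNetwork(
        ["A", "B", "C", "D", "E"],
        [2, 2, 2, 2, 2],
        {"C": ["A", "B"], "D": ["C"], "E": ["D"]},
        {
            "A": [[0.6, 0.4]],
            "B": [[0.4, 0.6]],
            "C": xor,
            "D": copy85,
            "E": copy85,
        },
    )


@pytest.fixture(scope="session")
def random_ds() -> DiscreteDataset:
    """500 rows x 5 features with mild pairwise dependence."""
    rng = np.random.default_rng(7)
    base = rng.integers(0, 3, size=(500, 5))
    base[:, 1] = np.where(rng.random(500) < 0.6, base[:, 0], base[:, 1])
    base[:, 3] = np.where(rng.random(500) < 0.5, base[:, 2] % 2, base[:, 3])
    return DiscreteDataset(base)


def brute_force_counts(values: np.ndarray, feats: tuple[int, ...]) -> dict:
    """Independent per-row scan oracle for joint counts."""
    out: dict[tuple[int, ...], int] = {}
    for row in values:
        key = tuple(int(row[f]) for f in feats)
        out[key] = out.get(key, 0) + 1
    return out
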
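"""Decomposed conditional mutual information (dcMI): G from cached entropies.

The G statistic is an exact rescaling of conditional mutual information,
``G(X,Y|Z) = 2N * I(X;Y|Z)``, and CMI decomposes into joint entropies:

    I(X;Y|Z) = H(X,Z) + H(Y,Z) - H(X,Y,Z) - H(Z)

Joint entropy does not depend on the order of its arguments, so every term
is addressed by the *set* of feature indices it covers.  The Joint Entropy
Table (JHT) caches these terms: a G-test needs at most four lookups (three
when Z is empty, since H(∅) = 0), and permuted tests over overlapping
feature sets reuse terms computed earlier.  No approximation is involved —
the decomposed value equals the canonical statistic up to floating-point
rounding.

Degrees of freedom still require the pattern of zero cells in the joint
PMF, which only exists while a term is being computed from data.  The DoF
cache is therefore filled *at term-computation time*: when the PMF of a
feature set S is built on a JHT miss, DoF entries for every unordered pair
{a, b} ⊆ S conditioned on S \\ {a, b} are stored at once — the only
opportunity, because the dataset is not consulted again for S.
"""

from __future__ import annotations

import itertools
import json
import math
from pathlib import Path
from typing import Iterable

from .citest import (
    CITestConfig,
    GTestResult,
    degrees_of_freedom,
    g_statistic_from_counts,
    p_value,
)
from .dataset import ContingencyTable, DiscreteDataset, count_joint

__all__ = [
    "JointEntropyTable",
    "DoFCache",
    "joint_entropy",
    "cmi_decomposed",
    "get_or_compute_term",
    "g_test_dcmi",
    "hit_rate",
    "DcmiBackend",
    "exhaustive_term_statistics",
    "reuse_factor_formula",
]

_NEG_TOL = 1e-9


def joint_entropy(counts: ContingencyTable) -> float:
    """H of the empirical joint PMF, in nats: −Σ (c/N)·ln(c/N) over nonzero cells."""
    n = counts.total
    if n < 1 or not counts.counts:
        raise ValueError("empty contingency table has no entropy")
    h = 0.0
    for c in counts.counts.values():
        p = c / n
        h -= p * math.log(p)
    return max(h, 0.0)


def cmi_decomposed(h_xz: float, h_yz: float, h_xyz: float, h_z: float) -> float:
    """I(X;Y|Z) from its four joint-entropy terms, clamped at 0.

    Floating-point cancellation can push the sum a hair below zero; CMI is
    non-negative, so values above −1e-9 are clamped and anything lower is a
    genuine error.
    """
    v = h_xz + h_yz - h_xyz - h_z
    if v < -_NEG_TOL:
        raise AssertionError(f"CMI decomposition produced {v} < -{_NEG_TOL}")
    return max(v, 0.0)


class JointEntropyTable:
    """Associative cache of joint entropies keyed by canonical feature sets.

    Keys are sorted index tuples, so {i, j} and {j, i} address one entry.
    ``hits``/``misses`` count term lookups made through
    :func:`get_or_compute_term`.
    """

    def __init__(self) -> None:
        self.entries: dict[tuple[int, ...], float] = {}
        self.hits = 0
        self.misses = 0

    def __len__(self) -> int:
        return len(self.entries)

    # serialization: JHTs may be shared between runs on the same dataset,
    # including across processes
    def to_json(self) -> str:
        return json.dumps(
            {
                "entries": [[list(k), v] for k, v in self.entries.items()],
                "hits": self.hits,
                "misses": self.misses,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "JointEntropyTable":
        data = json.loads(text)
        jht = cls()
        jht.entries = {tuple(k): float(v) for k, v in data["entries"]}
        jht.hits = int(data["hits"])
        jht.misses = int(data["misses"])
        return jht


class DoFCache:
    """Degrees of freedom for pair-given-rest permutations of cached sets.

    Keyed by ``((a, b), rest)`` with ``a < b`` and ``rest`` the sorted tuple
    of the remaining conditioning indices.  When the joint PMF of a set S is
    built, entries for all C(|S|, 2) pairs are stored simultaneously.
    """

    def __init__(self) -> None:
        self.entries: dict[tuple[tuple[int, int], tuple[int, ...]], int] = {}

    def __len__(self) -> int:
        return len(self.entries)

    @staticmethod
    def key(x: int, y: int, z: Iterable[int]) -> tuple[tuple[int, int], tuple[int, ...]]:
        a, b = sorted((x, y))
        return (a, b), tuple(sorted(z))

    def get(self, x: int, y: int, z: Iterable[int]) -> int:
        return self.entries[self.key(x, y, z)]

    def put(self, x: int, y: int, z: Iterable[int], dof: int) -> None:
        self.entries[self.key(x, y, z)] = int(dof)

    def __contains__(self, key) -> bool:
        return key in self.entries

    def to_json(self) -> str:
        return json.dumps(
            {"entries": [[list(p), list(r), d]
                         for (p, r), d in self.entries.items()]}
        )

    @classmethod
    def from_json(cls, text: str) -> "DoFCache":
        data = json.loads(text)
        cache = cls()
        cache.entries = {
            ((int(p[0]), int(p[1])), tuple(r)): int(d)
            for p, r, d in data["entries"]
        }
        return cache


def get_or_compute_term(
    jht: JointEntropyTable,
    ds: DiscreteDataset,
    s: Iterable[int],
    dof_cache: DoFCache | None = None,
) -> float:
    """Look up H(S) in the JHT, computing (and caching) it on a miss.

    The empty set returns 0 without touching the cache (H of nothing is 0).
    On a miss the joint PMF of S is built from the dataset exactly once;
    while it exists, the DoF cache is filled for every pair-given-rest
    permutation of S (|S| >= 2).
    """
    key = tuple(sorted(s))
    if not key:
        return 0.0
    if key in jht.entries:
        jht.hits += 1
        return jht.entries[key]
    joint = count_joint(ds, key)
    h = joint_entropy(joint)
    jht.entries[key] = h
    jht.misses += 1
    if dof_cache is not None and len(key) >= 2:
        for a, b in itertools.combinations(key, 2):
            rest = tuple(f for f in key if f != a and f != b)
            dof_cache.put(a, b, rest, degrees_of_freedom(joint, a, b, rest))
    return h


def g_test_dcmi(
    ds: DiscreteDataset,
    x: int,
    y: int,
    z: Iterable[int],
    jht: JointEntropyTable,
    dof_cache: DoFCache,
    cfg: CITestConfig | None = None,
) -> GTestResult:
    """The full G-test through the entropy decomposition.

    At most four term lookups (three when Z is empty); the DoF is read from
    the cache, which the {x, y} ∪ z term fill is guaranteed to have
    populated.  Equal to the canonical test up to floating-point rounding in
    G and exactly in DoF and verdict.
    """
    if cfg is None:
        cfg = CITestConfig(backend="dcmi")
    zs = frozenset(int(f) for f in z)
    if x == y or x in zs or y in zs:
        raise ValueError("require x != y and x, y not in z")
    h_xz = get_or_compute_term(jht, ds, {x, *zs}, dof_cache)
    h_yz = get_or_compute_term(jht, ds, {y, *zs}, dof_cache)
    h_xyz = get_or_compute_term(jht, ds, {x, y, *zs}, dof_cache)
    h_z = get_or_compute_term(jht, ds, zs, dof_cache)
    g = 2.0 * ds.N * cmi_decomposed(h_xz, h_yz, h_xyz, h_z)
    dof = dof_cache.get(x, y, zs)
    if dof < 1:
        return GTestResult(x, y, zs, g, dof, 1.0, True)
    p = p_value(g, dof)
    independent = p >= cfg.alpha
    if cfg.min_samples_factor > 0:
        cells = 1
        for f in (x, y, *zs):
            cells *= ds.arities[f]
        if ds.N < cfg.min_samples_factor * cells:
            independent = True
    return GTestResult(x, y, zs, g, dof, p, independent)


def hit_rate(jht: JointEntropyTable) -> float:
    """Fraction of term lookups answered from the cache."""
    total = jht.hits + jht.misses
    if total < 1:
        raise RuntimeError("no JHT lookups performed yet")
    return jht.hits / total


class DcmiBackend:
    """Counting backend driven entirely by the JHT and DoF cache.

    Satisfies the same black-box API as direct counting and the AD-tree
    backends, so consumers cannot tell the difference — except that the
    dataset is only touched on cache misses.  Caches may be shared across
    runs (and serialized) to amortize term computation.
    """

    name = "dcmi"

    def __init__(
        self,
        ds: DiscreteDataset,
        jht: JointEntropyTable | None = None,
        dof_cache: DoFCache | None = None,
    ):
        self.ds = ds
        self.jht = jht if jht is not None else JointEntropyTable()
        self.dof_cache = dof_cache if dof_cache is not None else DoFCache()
        self.ci_tests = 0

    @property
    def N(self) -> int:
        return self.ds.N

    @property
    def arities(self) -> list[int]:
        return self.ds.arities

    @property
    def M(self) -> int:
        return self.ds.M

    def test(self, x: int, y: int, z: frozenset[int]) -> tuple[float, int]:
        h_xz = get_or_compute_term(self.jht, self.ds, {x, *z}, self.dof_cache)
        h_yz = get_or_compute_term(self.jht, self.ds, {y, *z}, self.dof_cache)
        h_xyz = get_or_compute_term(self.jht, self.ds, {x, y, *z}, self.dof_cache)
        h_z = get_or_compute_term(self.jht, self.ds, z, self.dof_cache)
        g = 2.0 * self.ds.N * cmi_decomposed(h_xz, h_yz, h_xyz, h_z)
        return g, self.dof_cache.get(x, y, z)


# ---------------------------------------------------------------------------
# reuse-factor enumeration
# ---------------------------------------------------------------------------

def exhaustive_term_statistics(m: int) -> dict[str, float]:
    """Enumerate the combinatorically exhaustive G-test family over m features.

    Every unordered pair {x, y} is tested given every conditioning subset of
    the remaining m − 2 features.  The canonical backend builds one
    probability distribution per term position (4 per test); with caching,
    only the distinct term sets — the non-empty subsets of the m features —
    are ever built.  Returns the counts and their ratio, which approaches
    m(m−1)/2 as m grows.
    """
    if m < 2:
        raise ValueError("need at least two features")
    feats = range(m)
    tests = 0
    distinct: set[frozenset[int]] = set()
    lookups = 0
    for x, y in itertools.combinations(feats, 2):
        rest = [f for f in feats if f != x and f != y]
        for k in range(len(rest) + 1):
            for zc in itertools.combinations(rest, k):
                z = frozenset(zc)
                tests += 1
                lookups += 4
                for term in (z | {x}, z | {y}, z | {x, y}, z):
                    if term:
                        distinct.add(frozenset(term))
    return {
        "m": m,
        "tests": tests,
        "canonical_distributions": lookups,
        "distinct_terms": len(distinct),
        "ratio": lookups / len(distinct),
    }


def reuse_factor_formula(m: int) -> float:
    """Closed form of the exhaustive reuse ratio: m(m−1)·2^(m−1) / (2^m − 1)."""
    return m * (m - 1) * 2 ** (m - 1) / (2**m - 1)
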
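"""The G-test of (conditional) independence on multinomial data.

The G statistic for features X, Y given a conditioning set Z is the
log-likelihood-ratio statistic

    G(X,Y|Z) = 2N * sum_{x,y,z} P(x,y,z) * ln[ P(x,y,z) P(z) / (P(x,z) P(y,z)) ]

in nats (natural log throughout), summed over cells with positive joint
count.  Under the independence null it is asymptotically chi-squared with a
number of degrees of freedom computed per observed Z-stratum:

    DoF = sum_c  max(r_x(c) - 1, 0) * max(r_y(c) - 1, 0)

where ``r_x(c)`` counts X-levels with positive support in stratum ``c``.
Levels with zero observed support are excluded, which is why contingency
tables carry implicit zeros.  This zero-eliminating per-stratum rule is a
reconstruction in the spirit of Spirtes et al.'s PC-style tests; the one
rule is shared by every counting backend so all backends return identical
results.

A test whose DoF sums to zero (e.g. a constant feature) carries no
information: it returns p = 1 and an "independent" verdict rather than
consulting a chi-squared with zero degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Protocol

from scipy.stats import chi2

from .dataset import ContingencyTable, DiscreteDataset, count_joint

__all__ = [
    "GTestResult",
    "CITestConfig",
    "g_statistic_from_counts",
    "degrees_of_freedom",
    "p_value",
    "ci_test",
    "DirectCountBackend",
]

BACKEND_NAMES = ("default", "static-adtree", "dynamic-adtree", "dcmi")


@dataclass(frozen=True)
class CITestConfig:
    """Significance and backend selection for CI tests.

    ``min_samples_factor`` enables a sample-size reliability heuristic: when
    positive, a test over features whose potential cell count ``q`` satisfies
    ``N < min_samples_factor * q`` is declared unreliable and answered
    "independent" without consulting the statistic.  Off (0) by default so
    verdicts are driven by the G-test alone.
    """

    alpha: float = 0.05
    min_samples_factor: float = 0.0
    backend: str = "default"
    spouse_conditioning: str = "sepset_union_x"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_samples_factor < 0:
            raise ValueError("min_samples_factor must be >= 0")
        if self.backend not in BACKEND_NAMES:
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.spouse_conditioning not in (
            "sepset_union_x", "pc_union_x", "pc_only"
        ):
            raise ValueError(
                "spouse_conditioning must be sepset_union_x, pc_union_x "
                "or pc_only"
            )


@dataclass(frozen=True)
class GTestResult:
    """Outcome of one G-test: statistic, DoF, p-value and verdict."""

    x: int
    y: int
    z: frozenset[int]
    g: float
    dof: int
    p_value: float
    independent: bool

    def to_record(self) -> dict:
        return {
            "x": self.x,
            "y": self.y,
            "z": sorted(self.z),
            "g": self.g,
            "dof": self.dof,
            "p": self.p_value,
            "independent": self.independent,
        }


def _positions(
    joint: ContingencyTable, x: int, y: int, z: Iterable[int]
) -> tuple[int, int, list[int]]:
    zs = sorted(z)
    if x == y or x in zs or y in zs:
        raise ValueError("require x != y and x, y not in z")
    if set(joint.features) != {x, y, *zs}:
        raise ValueError(
            f"joint table over {joint.features} does not match "
            f"{{ {x}, {y} }} | {zs}"
        )
    feats = joint.features
    return feats.index(x), feats.index(y), [feats.index(f) for f in zs]


def g_statistic_from_counts(
    joint: ContingencyTable, x: int, y: int, z: Iterable[int], n: int | None = None
) -> float:
    """G(X,Y|Z) in nats from a sparse joint table over {x, y} ∪ z.

    Cells with zero joint count contribute nothing; with counts ``c`` the
    probability form reduces to ``2 * sum c_xyz * ln(c_xyz * c_z / (c_xz * c_yz))``
    (the sample size cancels), so only the marginal count maps are needed.
    """
    px, py, pz = _positions(joint, x, y, z)
    if n is None:
        n = joint.total
    elif n != joint.total:
        raise ValueError("n must equal joint.total")
    c_z: dict[tuple[int, ...], int] = {}
    c_xz: dict[tuple, int] = {}
    c_yz: dict[tuple, int] = {}
    cells: list[tuple[int, int, tuple[int, ...], int]] = []
    for key, c in joint.counts.items():
        zk = tuple(key[p] for p in pz)
        xv, yv = key[px], key[py]
        c_z[zk] = c_z.get(zk, 0) + c
        c_xz[(xv, zk)] = c_xz.get((xv, zk), 0) + c
        c_yz[(yv, zk)] = c_yz.get((yv, zk), 0) + c
        cells.append((xv, yv, zk, c))
    g = 0.0
    for xv, yv, zk, c in cells:
        g += c * math.log(c * c_z[zk] / (c_xz[(xv, zk)] * c_yz[(yv, zk)]))
    g *= 2.0
    if g < -1e-9:
        raise AssertionError(f"G statistic came out negative: {g}")
    return max(g, 0.0)


def degrees_of_freedom(
    joint: ContingencyTable, x: int, y: int, z: Iterable[int]
) -> int:
    """Per-stratum zero-eliminating DoF; may legitimately be 0."""
    px, py, pz = _positions(joint, x, y, z)
    x_levels: dict[tuple[int, ...], set[int]] = {}
    y_levels: dict[tuple[int, ...], set[int]] = {}
    for key in joint.counts:
        zk = tuple(key[p] for p in pz)
        x_levels.setdefault(zk, set()).add(key[px])
        y_levels.setdefault(zk, set()).add(key[py])
    dof = 0
    for zk, xs in x_levels.items():
        dof += max(len(xs) - 1, 0) * max(len(y_levels[zk]) - 1, 0)
    return dof


def p_value(g: float, dof: int) -> float:
    """Upper-tail chi-squared probability of the observed statistic."""
    if g < 0:
        raise ValueError("g must be non-negative")
    if dof < 1:
        raise ValueError("dof must be >= 1 (dof 0 is handled by the caller)")
    return float(chi2.sf(g, dof))


class CountingBackend(Protocol):
    """What a G-test counting backend must expose.

    ``test`` returns the pair (G, DoF); arities and N support the
    reliability rule; ``ci_tests`` counts completed tests.
    """

    ci_tests: int
    N: int
    arities: list[int]

    def test(self, x: int, y: int, z: frozenset[int]) -> tuple[float, int]: ...


class DirectCountBackend:
    """The unoptimized backend: scans the dataset for every test."""

    name = "default"

    def __init__(self, ds: DiscreteDataset):
        self.ds = ds
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
        feats = tuple(sorted({x, y, *z}))
        joint = count_joint(self.ds, feats)
        return (
            g_statistic_from_counts(joint, x, y, z),
            degrees_of_freedom(joint, x, y, z),
        )


def ci_test(
    backend: CountingBackend,
    x: int,
    y: int,
    z: Iterable[int],
    cfg: CITestConfig | None = None,
) -> GTestResult:
    """Black-box CI test over feature indices, through any counting backend.

    Increments the backend's test counter.  Verdict: independent iff
    p >= alpha (reject the null strictly below alpha), except for the
    zero-DoF and reliability special cases described in the module docstring.
    """
    if cfg is None:
        cfg = CITestConfig()
    z = frozenset(int(f) for f in z)
    if x == y or x in z or y in z:
        raise ValueError("require x != y and x, y not in z")
    g, dof = backend.test(x, y, z)
    if dof < 1:
        result = GTestResult(x, y, z, g, dof, 1.0, True)
    else:
        p = p_value(g, dof)
        independent = p >= cfg.alpha
        if cfg.min_samples_factor > 0:
            cells = 1
            for f in (x, y, *z):
                cells *= backend.arities[f]
            if backend.N < cfg.min_samples_factor * cells:
                independent = True
        result = GTestResult(x, y, z, g, dof, p, independent)
    backend.ci_tests += 1
    return result
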
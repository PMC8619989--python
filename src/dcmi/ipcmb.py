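"""IPC-MB: iterative parent-child Markov blanket discovery.

The algorithm splits blanket discovery for a target T into (1) finding the
parents and children PC(T) and (2) finding the spouses SP(T), with
MB(T) = PC(T) ∪ SP(T).  Parent-child recognition removes candidates as soon
as *some* conditioning set separates them from the target, scanning
conditioning sets of size 0 first, then 1, 2, ... so that cheap
unconditional tests prune the pool before expensive high-order tests run.
A symmetry pass (X stays only if T also survives recognition from X's side)
eliminates the asymmetric false positives inherited from PC-style
recognition.  Spouses are the members of PC(X), X ∈ PC(T), that remain
dependent on T given PC(T) with the collider at X opened.

All data access goes through a CI-tester interface answering
"independent(x, y | z)?" for feature indices — IPC-MB never touches samples
directly, so any counting backend (or the d-separation oracle of a known
network, used for validation) can stand behind it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Protocol

from .bayesnet import BayesianNetwork, d_separated
from .citest import CITestConfig, CountingBackend, ci_test

__all__ = [
    "MBResult",
    "GTestTester",
    "DSeparationTester",
    "recognize_pc",
    "find_pc",
    "find_spouses",
    "find_mb",
]


@dataclass
class MBResult:
    """Discovered blanket of one target plus the test-count accounting."""

    target: int
    pc: frozenset[int]
    sp: frozenset[int]
    ci_tests_performed: int
    sepsets: dict[int, tuple[int, ...]] = field(default_factory=dict)

    @property
    def mb(self) -> frozenset[int]:
        return self.pc | self.sp

    def to_record(self) -> dict:
        return {
            "target": self.target,
            "pc": sorted(self.pc),
            "sp": sorted(self.sp),
            "mb": sorted(self.mb),
            "ci_tests": self.ci_tests_performed,
            "sepsets": {str(k): list(v) for k, v in self.sepsets.items()},
        }


class CITester(Protocol):
    """Black-box conditional-independence oracle over feature indices."""

    m: int
    tests_performed: int

    def independent(self, x: int, y: int, z: frozenset[int]) -> bool: ...


class GTestTester:
    """CI tester backed by a G-test counting backend.

    Keeps the full decision trace (x, y, sorted z, verdict) so that
    different backends can be compared test by test.
    """

    def __init__(self, backend: CountingBackend, cfg: CITestConfig | None = None):
        self.backend = backend
        self.cfg = cfg if cfg is not None else CITestConfig()
        self.trace: list[tuple[int, int, tuple[int, ...], bool]] = []

    @property
    def m(self) -> int:
        return self.backend.M

    @property
    def tests_performed(self) -> int:
        return self.backend.ci_tests

    def independent(self, x: int, y: int, z: frozenset[int]) -> bool:
        res = ci_test(self.backend, x, y, z, self.cfg)
        self.trace.append((x, y, tuple(sorted(z)), res.independent))
        return res.independent


class DSeparationTester:
    """Exact CI oracle from a known network's DAG (validation tester)."""

    def __init__(self, bn: BayesianNetwork):
        self.bn = bn
        self.tests_performed = 0

    @property
    def m(self) -> int:
        return len(self.bn)

    def independent(self, x: int, y: int, z: frozenset[int]) -> bool:
        self.tests_performed += 1
        names = self.bn.names
        return d_separated(self.bn, names[x], names[y], [names[f] for f in z])


def recognize_pc(
    target: int, candidates: Iterable[int], tester: CITester
) -> tuple[set[int], dict[int, tuple[int, ...]]]:
    """One-sided parent-child recognition.

    Sweeps conditioning-set sizes k = 0, 1, 2, ...; within a sweep each
    remaining candidate X is tested against every size-k subset of the other
    remaining candidates (lexicographic order over sorted indices) and is
    removed the moment a separating set is found.  Removed candidates leave
    the subset pools immediately.  Stops once k exceeds the pool size minus
    one.  Returns the survivors and the separating sets of the removed.
    """
    remaining = set(int(c) for c in candidates)
    if target in remaining:
        raise ValueError("target must not be among the candidates")
    sepsets: dict[int, tuple[int, ...]] = {}
    k = 0
    while k <= len(remaining) - 1:
        for x in sorted(remaining):
            pool = sorted(remaining - {x})
            for s in itertools.combinations(pool, k):
                if tester.independent(target, x, frozenset(s)):
                    remaining.discard(x)
                    sepsets[x] = s
                    break
        k += 1
    return remaining, sepsets


def find_pc(
    target: int,
    tester: CITester,
    _memo: dict[int, tuple[set[int], dict[int, tuple[int, ...]]]] | None = None,
) -> set[int]:
    """PC(T): one-sided recognition plus the symmetry correction.

    A survivor X is kept only if T in turn survives recognition from X's
    side over the full feature set minus X (conservative pool).  The memo,
    when provided, shares recognition results within one blanket run.
    """
    memo = _memo if _memo is not None else {}

    def recog(t: int) -> tuple[set[int], dict[int, tuple[int, ...]]]:
        if t not in memo:
            memo[t] = recognize_pc(
                t, [f for f in range(tester.m) if f != t], tester
            )
        return memo[t]

    cand, _ = recog(target)
    return {x for x in cand if target in recog(x)[0]}


def find_spouses(
    target: int,
    pc: Iterable[int],
    tester: CITester,
    spouse_conditioning: str = "sepset_union_x",
    _memo=None,
) -> set[int]:
    """SP(T): parents-of-children detected through opened colliders.

    For each X ∈ PC(T) and each Y ∈ PC(X) outside PC(T) ∪ {T}: Y is a
    spouse iff T and Y remain dependent given sepset(T, Y) ∪ {X} — the set
    that separated Y from T during recognition, augmented with X to open a
    potential collider at X.  Conditioning on PC(T) instead (the
    "pc_union_x" / "pc_only" variants) admits false positives: it opens
    colliders at *every* child of T, activating paths to non-spouse
    ancestors of those children.  The default is the conditioning set under
    which the d-separation oracle suite recovers blankets exactly.
    """
    pc = set(pc)
    memo = _memo if _memo is not None else {}
    spouses: set[int] = set()
    for x in sorted(pc):
        pc_x = find_pc(x, tester, _memo=memo)
        for y in sorted(pc_x):
            if y == target or y in pc or y in spouses:
                continue
            if spouse_conditioning == "sepset_union_x":
                # the separator was recorded either during the target's
                # recognition or, for symmetry-dropped candidates, during
                # y's own recognition (computed by find_pc(x)'s symmetry pass)
                sep = memo.get(target, (set(), {}))[1].get(y)
                if sep is None:
                    sep = memo.get(y, (set(), {}))[1].get(target, ())
                cond = set(sep) | {x}
            elif spouse_conditioning == "pc_union_x":
                cond = pc | {x}
            else:  # pc_only
                cond = set(pc)
            cond.discard(y)
            if not tester.independent(target, y, frozenset(cond)):
                spouses.add(y)
    return spouses


def find_mb(
    target: int,
    tester: CITester,
    spouse_conditioning: str = "sepset_union_x",
) -> MBResult:
    """Full blanket of one target through the black-box tester."""
    if not 0 <= target < tester.m:
        raise IndexError(f"target {target} out of range")
    start = tester.tests_performed
    memo: dict = {}
    pc = find_pc(target, tester, _memo=memo)
    sp = find_spouses(
        target, pc, tester, spouse_conditioning=spouse_conditioning, _memo=memo
    )
    _, sepsets = memo[target]
    return MBResult(
        target=target,
        pc=frozenset(pc),
        sp=frozenset(sp),
        ci_tests_performed=tester.tests_performed - start,
        sepsets=dict(sepsets),
    )
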
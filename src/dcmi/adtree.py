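"""AD-trees: cached sample counts with MCV elision and Leaf-List nodes.

An AD-tree interleaves two node kinds: AD-nodes hold the sample count of a
partial value assignment, and Vary-nodes fan an AD-node out over the values
of one feature.  The root AD-node holds N; children of a Vary-node for
feature f are AD-nodes for each value of f — except that

* zero-count AD-nodes are never created (queries on missing branches
  return 0),
* the most common value (MCV) of each Vary-node is elided: its subtree is
  absent and its counts are reconstructed at query time as the parent
  count minus the non-elided siblings, and
* AD-nodes whose count falls below the Leaf-List threshold (a percentage
  of N) store raw row indices instead of a subtree and are counted by
  scanning those rows.

Trees expand only along a fixed feature ordering, so queries are re-sorted
to that ordering internally.  A *static* tree is fully expanded at build
time; a *dynamic* tree starts as a bare root and expands on demand as it is
queried.  Both answer every query exactly as a direct row scan would.
"""

from __future__ import annotations

import json
import math
from typing import Iterable, Mapping

import numpy as np

from .citest import degrees_of_freedom, g_statistic_from_counts
from .dataset import ContingencyTable, DiscreteDataset

__all__ = ["ADTree", "ADTreeBackend", "ADTreeBudgetError", "expand_dynamic"]


class ADTreeBudgetError(RuntimeError):
    """Raised when a static build exceeds the configured node budget."""


class _VaryNode:
    __slots__ = ("feature", "mcv", "children")

    def __init__(self, feature: int, mcv: int):
        self.feature = feature
        self.mcv = mcv
        self.children: dict[int, "_ADNode"] = {}


class _ADNode:
    __slots__ = ("count", "rows", "vary", "leaf")

    def __init__(self, count: int, rows: np.ndarray | None, leaf: bool):
        self.count = count
        self.rows = rows
        self.vary: dict[int, _VaryNode] = {}
        self.leaf = leaf


class ADTree:
    """Sample-count cache over a fixed feature ordering.

    Parameters
    ----------
    ds:
        Source dataset.  Retained in all modes: dynamic expansion and
        Leaf-List resolution both need the raw rows.
    mode:
        ``"static"`` (fully built up front) or ``"dynamic"`` (expanded by
        queries).
    llt_percent:
        Leaf-List threshold as a percentage of N; the absolute threshold is
        ``ceil(llt_percent/100 * N)`` and a node becomes a Leaf-List when
        its count is strictly below it, so 0 disables Leaf-Lists.
    node_budget:
        Optional cap on created AD-nodes; static builds that exceed it
        abort with :class:`ADTreeBudgetError` (mirrors aborting infeasible
        static builds on large data).
    """

    def __init__(
        self,
        ds: DiscreteDataset,
        mode: str = "dynamic",
        ordering: Iterable[int] | None = None,
        llt_percent: float = 0.0,
        node_budget: int | None = None,
    ):
        if mode not in ("static", "dynamic"):
            raise ValueError("mode must be 'static' or 'dynamic'")
        if not 0.0 <= llt_percent <= 100.0:
            raise ValueError("llt_percent must be in [0, 100]")
        self.ds = ds
        self.mode = mode
        self.ordering: list[int] = (
            list(range(ds.M)) if ordering is None else [int(f) for f in ordering]
        )
        if sorted(self.ordering) != list(range(ds.M)):
            raise ValueError("ordering must be a permutation of all features")
        self._pos = {f: i for i, f in enumerate(self.ordering)}
        self.llt_percent = float(llt_percent)
        self.llt_absolute = math.ceil(llt_percent / 100.0 * ds.N)
        self.node_budget = node_budget
        self._n_adnodes = 1
        self.root = _ADNode(
            ds.N, np.arange(ds.N), leaf=ds.N < self.llt_absolute
        )
        if mode == "static":
            self._expand_all(self.root, 0)
            self._strip_rows(self.root)

    # -- construction ------------------------------------------------------

    def _make_child(self, count: int, rows: np.ndarray) -> _ADNode:
        self._n_adnodes += 1
        if self.node_budget is not None and self._n_adnodes > self.node_budget:
            raise ADTreeBudgetError(
                f"AD-tree exceeded node budget of {self.node_budget}"
            )
        leaf = count < self.llt_absolute
        return _ADNode(count, rows, leaf)

    def _ensure_vary(self, node: _ADNode, f: int) -> _VaryNode:
        if f in node.vary:
            return node.vary[f]
        if node.leaf:
            raise RuntimeError("Leaf-List nodes are never expanded")
        if node.rows is None:
            # only possible on a stripped static tree, which is complete
            raise RuntimeError(
                "static AD-tree is missing an expected Vary-node"
            )
        col = self.ds.values[node.rows, f]
        counts = np.bincount(col, minlength=self.ds.arities[f])
        mcv = int(np.argmax(counts))  # ties: smallest value index
        vary = _VaryNode(f, mcv)
        for v in np.nonzero(counts)[0]:
            v = int(v)
            if v == mcv:
                continue  # MCV elision: slot reconstructed at query time
            vary.children[v] = self._make_child(
                int(counts[v]), node.rows[col == v]
            )
        node.vary[f] = vary
        return vary

    def _expand_all(self, node: _ADNode, start_pos: int) -> None:
        if node.leaf:
            return
        for pos in range(start_pos, self.ds.M):
            vary = self._ensure_vary(node, self.ordering[pos])
            for child in vary.children.values():
                self._expand_all(child, pos + 1)

    def _strip_rows(self, node: _ADNode) -> None:
        # static trees keep row indices only inside Leaf-Lists
        if not node.leaf:
            node.rows = None
        for vary in node.vary.values():
            for child in vary.children.values():
                self._strip_rows(child)

    # -- queries -----------------------------------------------------------

    def _sorted_items(self, q: Mapping[int, int]) -> list[tuple[int, int]]:
        items = []
        for f, v in q.items():
            if not 0 <= f < self.ds.M:
                raise IndexError(f"feature index {f} out of range")
            if not 0 <= v < self.ds.arities[f]:
                raise ValueError(f"value {v} outside arity of feature {f}")
            items.append((int(f), int(v)))
        items.sort(key=lambda fv: self._pos[fv[0]])
        return items

    def query_count(self, q: Mapping[int, int]) -> int:
        """Number of samples matching the assignment; exact, may expand."""
        return self._query(self.root, self._sorted_items(q))

    def _scan_leaf(self, node: _ADNode, items: list[tuple[int, int]]) -> int:
        rows = node.rows
        mask = np.ones(rows.shape[0], dtype=bool)
        for f, v in items:
            mask &= self.ds.values[rows, f] == v
        return int(mask.sum())

    def _query(self, node: _ADNode, items: list[tuple[int, int]]) -> int:
        if not items:
            return node.count
        if node.leaf:
            return self._scan_leaf(node, items)
        (f, v), rest = items[0], items[1:]
        vary = self._ensure_vary(node, f)
        if v == vary.mcv:
            total = self._query(node, rest)
            for child in vary.children.values():
                total -= self._query(child, rest)
            return total
        child = vary.children.get(v)
        return 0 if child is None else self._query(child, rest)

    def contingency(self, features: Iterable[int]) -> ContingencyTable:
        """Joint table over the features, identical to a direct count.

        Accepts features in any order; keys are returned in ascending
        feature-index order (the direct-count convention), while the
        internal descent follows the tree's ordering.
        """
        feats = sorted(set(int(f) for f in features))
        if not feats:
            raise ValueError("feature set must be non-empty")
        for f in feats:
            if not 0 <= f < self.ds.M:
                raise IndexError(f"feature index {f} out of range")
        tree_order = sorted(feats, key=lambda f: self._pos[f])
        raw = self._tbl(self.root, tree_order)
        perm = [tree_order.index(f) for f in feats]
        counts = {
            tuple(key[p] for p in perm): c for key, c in raw.items() if c > 0
        }
        return ContingencyTable(tuple(feats), counts, self.ds.N)

    def _tbl(
        self, node: _ADNode, feats: list[int]
    ) -> dict[tuple[int, ...], int]:
        if not feats:
            return {(): node.count}
        if node.leaf:
            rows = node.rows
            sub = self.ds.values[rows][:, feats]
            uniq, cnt = np.unique(sub, axis=0, return_counts=True)
            return {
                tuple(int(v) for v in key): int(c) for key, c in zip(uniq, cnt)
            }
        f, rest = feats[0], feats[1:]
        vary = self._ensure_vary(node, f)
        out: dict[tuple[int, ...], int] = {}
        remainder = dict(self._tbl(node, rest))
        for v, child in vary.children.items():
            for key, c in self._tbl(child, rest).items():
                out[(v, *key)] = c
                remainder[key] = remainder.get(key, 0) - c
        mcv = vary.mcv
        for key, c in remainder.items():
            if c < 0:
                raise AssertionError("MCV reconstruction went negative")
            if c > 0:
                out[(mcv, *key)] = c
        return out

    # -- introspection / serialization ------------------------------------

    def node_counts(self) -> dict[str, int]:
        """Structure size as entry counts (memory proxy)."""
        ad = vary = leaves = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            ad += 1
            if node.leaf:
                leaves += 1
            for vn in node.vary.values():
                vary += 1
                stack.extend(vn.children.values())
        return {"ad_nodes": ad, "vary_nodes": vary, "leaf_lists": leaves}

    def to_json(self) -> str:
        """Serialize a static tree (structure + ordering + threshold)."""
        if self.mode != "static":
            raise RuntimeError(
                "dynamic trees are in-memory only (they need the dataset)"
            )

        def enc(node: _ADNode) -> dict:
            d: dict = {"c": node.count}
            if node.leaf:
                d["rows"] = node.rows.tolist()
            if node.vary:
                d["vary"] = {
                    str(f): {
                        "mcv": vn.mcv,
                        "ch": {str(v): enc(ch) for v, ch in vn.children.items()},
                    }
                    for f, vn in node.vary.items()
                }
            return d

        return json.dumps(
            {
                "ordering": self.ordering,
                "llt_percent": self.llt_percent,
                "root": enc(self.root),
            }
        )

    @classmethod
    def from_json(cls, text: str, ds: DiscreteDataset) -> "ADTree":
        data = json.loads(text)
        tree = cls.__new__(cls)
        tree.ds = ds
        tree.mode = "static"
        tree.ordering = [int(f) for f in data["ordering"]]
        tree._pos = {f: i for i, f in enumerate(tree.ordering)}
        tree.llt_percent = float(data["llt_percent"])
        tree.llt_absolute = math.ceil(tree.llt_percent / 100.0 * ds.N)
        tree.node_budget = None

        def dec(d: dict) -> _ADNode:
            leaf = "rows" in d
            node = _ADNode(
                int(d["c"]),
                np.asarray(d["rows"], dtype=np.int64) if leaf else None,
                leaf,
            )
            for f, vn in d.get("vary", {}).items():
                vary = _VaryNode(int(f), int(vn["mcv"]))
                vary.children = {int(v): dec(ch) for v, ch in vn["ch"].items()}
                node.vary[int(f)] = vary
            return node

        tree.root = dec(data["root"])
        tree._n_adnodes = tree.node_counts()["ad_nodes"]
        return tree


def expand_dynamic(tree: ADTree, q: Mapping[int, int]) -> ADTree:
    """Expand a dynamic tree along the branches a query needs.

    Idempotent: re-issuing a query expands nothing further.  Static trees
    are complete by construction and reject expansion requests.
    """
    if tree.mode != "dynamic":
        raise ValueError("expand_dynamic requires a dynamic tree")
    tree.query_count(q)
    return tree


class ADTreeBackend:
    """G-test backend that assembles contingency tables from an AD-tree."""

    def __init__(self, tree: ADTree):
        self.tree = tree
        self.ci_tests = 0

    @property
    def name(self) -> str:
        return f"{self.tree.mode}-adtree"

    @property
    def N(self) -> int:
        return self.tree.ds.N

    @property
    def arities(self) -> list[int]:
        return self.tree.ds.arities

    @property
    def M(self) -> int:
        return self.tree.ds.M

    def test(self, x: int, y: int, z: frozenset[int]) -> tuple[float, int]:
        joint = self.tree.contingency({x, y, *z})
        return (
            g_statistic_from_counts(joint, x, y, z),
            degrees_of_freedom(joint, x, y, z),
        )
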
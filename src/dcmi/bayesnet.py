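"""Discrete Bayesian networks: BIF I/O, d-separation, ancestral sampling.

This module is the data source and the validation oracle for everything
downstream.  Networks synthesize datasets by ancestral sampling in
topological order, and d-separation over the DAG provides the exact
conditional-independence oracle against which the statistical machinery and
the blanket-discovery algorithm are validated.

The BIF reader accepts the dialect emitted by the bnlearn repository
(network / variable / probability blocks of BIF 0.15; ``property`` lines are
ignored).  It is a small hand-written tokenizer plus recursive-descent
parser — the grammar is tiny and regular.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .dataset import DiscreteDataset

__all__ = [
    "BIFParseError",
    "BayesianNetwork",
    "MarkovBlanketTruth",
    "parse_bif",
    "emit_bif",
    "d_separated",
    "true_markov_blanket",
    "sample",
    "random_network",
]


class BIFParseError(ValueError):
    """Syntax or validation failure while reading a BIF document."""


@dataclass(frozen=True)
class MarkovBlanketTruth:
    """Graph-defined Markov blanket of a target node.

    ``spouses`` are the other parents of the target's children; the blanket
    is the union of parents, children and spouses, never containing the
    target itself.
    """

    target: str
    parents: frozenset[str]
    children: frozenset[str]
    spouses: frozenset[str]

    @property
    def blanket(self) -> frozenset[str]:
        return self.parents | self.children | self.spouses


class BayesianNetwork:
    """DAG over named discrete nodes with one CPT per node.

    The CPT of a node with arity ``r`` and parents ``p1..pk`` is an array of
    shape ``(prod(parent arities), r)``; rows are indexed by the
    lexicographic (row-major) order of parent value tuples, in declared
    parent order.  Each row is a probability vector.
    """

    def __init__(
        self,
        names: Sequence[str],
        arities: Sequence[int],
        parents: dict[str, Sequence[str]],
        cpts: dict[str, np.ndarray],
        value_names: dict[str, Sequence[str]] | None = None,
        name: str = "network",
    ) -> None:
        self.name = name
        self.names: list[str] = list(names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate node names")
        self.arities: dict[str, int] = {
            n: int(a) for n, a in zip(self.names, arities)
        }
        self.parents: dict[str, tuple[str, ...]] = {
            n: tuple(parents.get(n, ())) for n in self.names
        }
        self.value_names: dict[str, list[str]] = {
            n: [str(v) for v in (value_names or {}).get(n, range(self.arities[n]))]
            for n in self.names
        }
        self.cpts: dict[str, np.ndarray] = {}
        for n in self.names:
            tab = np.asarray(cpts[n], dtype=float)
            n_cfg = int(np.prod([self.arities[p] for p in self.parents[n]])) or 1
            if tab.shape != (n_cfg, self.arities[n]):
                raise ValueError(
                    f"CPT of {n}: expected shape {(n_cfg, self.arities[n])}, "
                    f"got {tab.shape}"
                )
            if (tab < 0).any():
                raise ValueError(f"CPT of {n} has negative entries")
            if not np.allclose(tab.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(f"CPT rows of {n} do not sum to 1")
            self.cpts[n] = tab
        self.children: dict[str, tuple[str, ...]] = {n: () for n in self.names}
        kids: dict[str, list[str]] = {n: [] for n in self.names}
        for n in self.names:
            for p in self.parents[n]:
                if p not in self.arities:
                    raise ValueError(f"unknown parent {p!r} of node {n!r}")
                kids[p].append(n)
        self.children = {n: tuple(kids[n]) for n in self.names}
        self._topo = self._topological_order()

    # -- graph structure ---------------------------------------------------

    def _topological_order(self) -> list[str]:
        indeg = {n: len(self.parents[n]) for n in self.names}
        queue = [n for n in self.names if indeg[n] == 0]
        order: list[str] = []
        while queue:
            n = queue.pop(0)
            order.append(n)
            for c in self.children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(self.names):
            raise ValueError("parent graph contains a cycle")
        return order

    @property
    def topological_order(self) -> list[str]:
        return list(self._topo)

    def node_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(name) from None

    def __len__(self) -> int:
        return len(self.names)

    def edges(self) -> list[tuple[str, str]]:
        return [(p, n) for n in self.names for p in self.parents[n]]


# ---------------------------------------------------------------------------
# BIF parsing / emission
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[A-Za-z0-9_.+\-]+|[{}()\[\]|,;]")


def _tokenize(text: str) -> list[tuple[str, int]]:
    # strip // and /* */ comments, then emit (token, line) pairs
    text = re.sub(r"/\*.*?\*/", lambda m: re.sub(r"[^\n]", " ", m.group()), text,
                  flags=re.S)
    tokens: list[tuple[str, int]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("//")[0]
        for m in _TOKEN_RE.finditer(line):
            tokens.append((m.group(), lineno))
    return tokens


class _TokenStream:
    def __init__(self, tokens: list[tuple[str, int]]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    @property
    def line(self) -> int:
        i = min(self.pos, len(self.tokens) - 1)
        return self.tokens[i][1] if self.tokens else 0

    def next(self) -> str:
        if self.pos >= len(self.tokens):
            raise BIFParseError("unexpected end of input")
        tok, _ = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, tok: str) -> None:
        got = self.next()
        if got != tok:
            raise BIFParseError(f"line {self.line}: expected {tok!r}, got {got!r}")

    def skip_block(self) -> None:
        # consume a balanced { ... } block (used for property payloads)
        self.expect("{")
        depth = 1
        while depth:
            t = self.next()
            if t == "{":
                depth += 1
            elif t == "}":
                depth -= 1


def parse_bif(text: str) -> BayesianNetwork:
    """Parse a BIF 0.15 document (bnlearn-emitted subset) into a network.

    ``property`` lines are ignored.  CPT rows are normalized to the
    lexicographic parent-configuration order regardless of the order of the
    ``( value, ... )`` entries in the document.
    """
    ts = _TokenStream(_tokenize(text))
    net_name = "network"
    names: list[str] = []
    arities: list[int] = []
    value_names: dict[str, list[str]] = {}
    parents: dict[str, tuple[str, ...]] = {}
    raw_rows: dict[str, dict[tuple[str, ...], list[float]]] = {}
    tables: dict[str, list[float]] = {}

    while ts.peek() is not None:
        kw = ts.next()
        if kw == "network":
            net_name = ts.next()
            ts.skip_block()
        elif kw == "variable":
            var = ts.next()
            ts.expect("{")
            while ts.peek() != "}":
                inner = ts.next()
                if inner == "type":
                    ts.expect("discrete")
                    ts.expect("[")
                    k = int(ts.next())
                    ts.expect("]")
                    ts.expect("{")
                    vals: list[str] = []
                    while ts.peek() != "}":
                        t = ts.next()
                        if t != ",":
                            vals.append(t)
                    ts.expect("}")
                    ts.expect(";")
                    if len(vals) != k:
                        raise BIFParseError(
                            f"line {ts.line}: variable {var!r} declares {k} "
                            f"values but lists {len(vals)}"
                        )
                    names.append(var)
                    arities.append(k)
                    value_names[var] = vals
                elif inner == "property":
                    while ts.next() != ";":
                        pass
                else:
                    raise BIFParseError(
                        f"line {ts.line}: unexpected token {inner!r} in "
                        f"variable block"
                    )
            ts.expect("}")
        elif kw == "probability":
            ts.expect("(")
            child = ts.next()
            pars: list[str] = []
            t = ts.next()
            if t == "|":
                while True:
                    pars.append(ts.next())
                    t = ts.next()
                    if t == ")":
                        break
                    if t != ",":
                        raise BIFParseError(
                            f"line {ts.line}: expected ',' or ')', got {t!r}"
                        )
            elif t != ")":
                raise BIFParseError(f"line {ts.line}: expected '|' or ')'")
            parents[child] = tuple(pars)
            ts.expect("{")
            rows: dict[tuple[str, ...], list[float]] = {}
            while ts.peek() != "}":
                t = ts.next()
                if t == "table":
                    probs: list[float] = []
                    while ts.peek() != ";":
                        tok = ts.next()
                        if tok != ",":
                            probs.append(float(tok))
                    ts.expect(";")
                    tables[child] = probs
                elif t == "(":
                    cfg: list[str] = []
                    while ts.peek() != ")":
                        tok = ts.next()
                        if tok != ",":
                            cfg.append(tok)
                    ts.expect(")")
                    probs = []
                    while ts.peek() != ";":
                        tok = ts.next()
                        if tok != ",":
                            probs.append(float(tok))
                    ts.expect(";")
                    rows[tuple(cfg)] = probs
                elif t == "property":
                    while ts.next() != ";":
                        pass
                else:
                    raise BIFParseError(
                        f"line {ts.line}: unexpected token {t!r} in "
                        f"probability block"
                    )
            ts.expect("}")
            if rows:
                raw_rows[child] = rows
        else:
            raise BIFParseError(f"line {ts.line}: unexpected keyword {kw!r}")

    if not names:
        raise BIFParseError("no variable blocks found")
    arity_of = dict(zip(names, arities))
    cpts: dict[str, np.ndarray] = {}
    for var in names:
        pars = parents.get(var, ())
        parents.setdefault(var, ())
        r = arity_of[var]
        if not pars:
            probs = tables.get(var)
            if probs is None and var in raw_rows and () in raw_rows[var]:
                probs = raw_rows[var][()]
            if probs is None:
                raise BIFParseError(f"no probability table for root {var!r}")
            cpts[var] = np.asarray([probs], dtype=float)
        else:
            rows = raw_rows.get(var)
            if rows is None:
                raise BIFParseError(f"no probability rows for {var!r}")
            cfgs = list(itertools.product(*(value_names[p] for p in pars)))
            tab = np.empty((len(cfgs), r), dtype=float)
            for i, cfg in enumerate(cfgs):
                if cfg not in rows:
                    raise BIFParseError(
                        f"{var!r}: missing CPT row for parent configuration "
                        f"{cfg}"
                    )
                row = rows[cfg]
                if len(row) != r:
                    raise BIFParseError(
                        f"{var!r}: CPT row for {cfg} has {len(row)} entries, "
                        f"expected {r}"
                    )
                tab[i] = row
            cpts[var] = tab
    for var in names:
        bad = np.abs(cpts[var].sum(axis=1) - 1.0) > 1e-6
        if bad.any():
            raise BIFParseError(f"CPT rows of {var!r} do not sum to 1")
    try:
        return BayesianNetwork(names, [arity_of[n] for n in names], parents,
                               cpts, value_names, name=net_name)
    except ValueError as exc:
        raise BIFParseError(str(exc)) from exc


def emit_bif(bn: BayesianNetwork) -> str:
    """Serialize a network back to BIF text (round-trips through parse_bif)."""
    out: list[str] = [f"network {bn.name} {{", "}"]
    for n in bn.names:
        vals = ", ".join(bn.value_names[n])
        out.append(
            f"variable {n} {{\n  type discrete [ {bn.arities[n]} ] "
            f"{{ {vals} }};\n}}"
        )
    for n in bn.names:
        pars = bn.parents[n]
        tab = bn.cpts[n]
        if not pars:
            probs = ", ".join(repr(float(p)) for p in tab[0])
            out.append(f"probability ( {n} ) {{\n  table {probs};\n}}")
        else:
            head = ", ".join(pars)
            lines = [f"probability ( {n} | {head} ) {{"]
            cfgs = itertools.product(*(bn.value_names[p] for p in pars))
            for i, cfg in enumerate(cfgs):
                probs = ", ".join(repr(float(p)) for p in tab[i])
                lines.append(f"  ({', '.join(cfg)}) {probs};")
            lines.append("}")
            out.append("\n".join(lines))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# d-separation and Markov blankets
# ---------------------------------------------------------------------------

def d_separated(bn: BayesianNetwork, x: str, y: str, z: Iterable[str]) -> bool:
    """Exact d-separation of ``x`` and ``y`` given set ``z``.

    Implemented as Bayes-ball reachability: a breadth-first search over
    (node, arrival-direction) states where chains and forks are blocked by
    conditioning and colliders are activated by conditioned descendants.
    """
    z = set(z)
    if x == y:
        raise ValueError("x and y must differ")
    if x in z or y in z:
        raise ValueError("x and y must not be in the conditioning set")
    for node in (x, y, *z):
        if node not in bn.arities:
            raise KeyError(node)
    # ancestors of z (inclusive) activate colliders
    anc = set(z)
    stack = list(z)
    while stack:
        n = stack.pop()
        for p in bn.parents[n]:
            if p not in anc:
                anc.add(p)
                stack.append(p)
    # states: (node, came_from_child?) — True means we arrived via an edge
    # pointing at the node's child, i.e. we are moving "up" the graph
    visited: set[tuple[str, bool]] = set()
    stack2: list[tuple[str, bool]] = [(x, True)]
    while stack2:
        node, up = stack2.pop()
        if (node, up) in visited:
            continue
        visited.add((node, up))
        if node == y:
            return False
        if up and node not in z:
            for p in bn.parents[node]:
                stack2.append((p, True))
            for c in bn.children[node]:
                stack2.append((c, False))
        elif not up:
            if node not in z:
                for c in bn.children[node]:
                    stack2.append((c, False))
            if node in anc:
                for p in bn.parents[node]:
                    stack2.append((p, True))
    return True


def true_markov_blanket(bn: BayesianNetwork, target: str) -> MarkovBlanketTruth:
    """Parents, children, and spouses of ``target`` read off the DAG."""
    if target not in bn.arities:
        raise KeyError(target)
    parents = frozenset(bn.parents[target])
    children = frozenset(bn.children[target])
    spouses = frozenset(
        p
        for c in children
        for p in bn.parents[c]
        if p != target and p not in parents and p not in children
    )
    return MarkovBlanketTruth(target, parents, children, spouses)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample(bn: BayesianNetwork, n: int, seed: int) -> DiscreteDataset:
    """Ancestral sampling: ``n`` full sample vectors, one column per node.

    Nodes are visited in topological order; each node draws from its CPT row
    selected by the already-sampled parent values.  Deterministic given
    ``seed``; column order is the network's declaration order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for node in bn.topological_order:
        pars = bn.parents[node]
        tab = bn.cpts[node]
        if pars:
            cfg = np.zeros(n, dtype=np.int64)
            for p in pars:
                cfg = cfg * bn.arities[p] + cols[p]
        else:
            cfg = np.zeros(n, dtype=np.int64)
        cum = np.cumsum(tab, axis=1)
        u = rng.random(n)
        cols[node] = (u[:, None] > cum[cfg]).sum(axis=1).astype(np.int64)
        np.minimum(cols[node], bn.arities[node] - 1, out=cols[node])
    values = np.column_stack([cols[name] for name in bn.names])
    return DiscreteDataset(values,
                           arities=[bn.arities[name] for name in bn.names],
                           feature_names=list(bn.names))


def random_network(
    m: int,
    max_parents: int = 3,
    arity_range: tuple[int, int] = (2, 3),
    seed: int = 0,
    dirichlet_alpha: float = 0.5,
) -> BayesianNetwork:
    """Random DAG fixture with Dirichlet-sampled CPT rows.

    A random topological order is drawn, each node receives up to
    ``max_parents`` parents among its predecessors, and every CPT row is a
    Dirichlet(``dirichlet_alpha``) draw (the sub-uniform default yields
    reasonably peaked conditionals, i.e. detectable dependences).
    Deterministic given ``seed``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if max_parents >= m and m > 1:
        raise ValueError("max_parents must be < m")
    rng = np.random.default_rng(seed)
    names = [f"X{i}" for i in range(m)]
    order = list(rng.permutation(m))
    lo, hi = arity_range
    arities = rng.integers(lo, hi + 1, size=m).tolist()
    parents: dict[str, tuple[str, ...]] = {}
    for pos, i in enumerate(order):
        preds = [names[j] for j in order[:pos]]
        k = int(rng.integers(0, min(max_parents, len(preds)) + 1))
        chosen = sorted(rng.choice(len(preds), size=k, replace=False).tolist())
        parents[names[i]] = tuple(preds[j] for j in chosen)
    cpts: dict[str, np.ndarray] = {}
    for i, nme in enumerate(names):
        r = arities[i]
        n_cfg = int(np.prod([arities[names.index(p)] for p in parents[nme]])) or 1
        tab = rng.dirichlet(np.full(r, dirichlet_alpha), size=n_cfg)
        # keep rows bounded away from degenerate 0/1 so every value stays legal
        tab = (tab + 0.01) / (1 + 0.01 * r)
        cpts[nme] = tab
    return BayesianNetwork(names, arities, parents, cpts,
                           name=f"random_m{m}_s{seed}")
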
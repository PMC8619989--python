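"""Bayesian network container, BIF I/O, d-separation, sampling."""

import itertools

import networkx as nx
import numpy as np
import pytest

from dcmi import (
    BayesianNetwork,
    d_separated,
    emit_bif,
    parse_bif,
    random_network,
    sample,
    true_markov_blanket,
)
from dcmi.bayesnet import BIFParseError
from dcmi.bench import derive_seed

MINIMAL_BIF = """
network tiny {
}
variable A {
  type discrete [ 2 ] { a0, a1 };
}
probability ( A ) {
  table 0.3, 0.7;
}
"""

TWO_NODE_BIF = """
network pair {
}
variable A {
  type discrete [ 2 ] { no, yes };
}
variable B {
  type discrete [ 3 ] { lo, mid, hi };
}
probability ( A ) {
  table 0.4, 0.6;
}
probability ( B | A ) {
  (no) 0.2, 0.3, 0.5;
  (yes) 0.7, 0.2, 0.1;
}
"""


class TestBIF:
    def test_minimal_single_variable(self):
        bn = parse_bif(MINIMAL_BIF)
        assert bn.names == ["A"]
        assert np.allclose(bn.cpts["A"], [[0.3, 0.7]])

    def test_two_node_roundtrip(self):
        bn = parse_bif(TWO_NODE_BIF)
        back = parse_bif(emit_bif(bn))
        assert back.names == bn.names
        assert back.parents == bn.parents
        for n in bn.names:
            assert np.allclose(back.cpts[n], bn.cpts[n])

    def test_missing_brace_is_a_parse_error(self):
        with pytest.raises(BIFParseError):
            parse_bif(MINIMAL_BIF.replace("table 0.3, 0.7;\n}", "table 0.3, 0.7;"))

    def test_cpt_row_not_summing_is_rejected(self):
        with pytest.raises(BIFParseError, match="sum"):
            parse_bif(MINIMAL_BIF.replace("0.3, 0.7", "0.3, 0.5"))

    def test_cycle_is_rejected(self):
        text = TWO_NODE_BIF.replace(
            "probability ( A ) {\n  table 0.4, 0.6;\n}",
            "probability ( A | B ) {\n  (lo) 0.4, 0.6;\n  (mid) 0.4, 0.6;\n"
            "  (hi) 0.4, 0.6;\n}",
        )
        with pytest.raises(BIFParseError, match="cycle"):
            parse_bif(text)

    def test_property_lines_are_ignored(self):
        text = MINIMAL_BIF.replace(
            "variable A {", 'variable A {\n  property "position = (1, 2)";'
        )
        assert parse_bif(text).names == ["A"]


class TestDSeparation:
    def test_chain_blocked_by_middle(self, chain_bn):
        assert d_separated(chain_bn, "A", "C", ["B"])
        assert not d_separated(chain_bn, "A", "C", [])

    def test_collider_activated_by_conditioning(self, collider_bn):
        assert d_separated(collider_bn, "A", "B", [])
        assert not d_separated(collider_bn, "A", "B", ["C"])

    def test_symmetric_in_arguments(self, collider_bn):
        for z in ([], ["C"]):
            assert d_separated(collider_bn, "A", "B", z) == d_separated(
                collider_bn, "B", "A", z
            )

    def test_parent_child_never_separated_marginally(self):
        for seed in range(5):
            bn = random_network(6, max_parents=2, seed=seed)
            for child in bn.names:
                for p in bn.parents[child]:
                    assert not d_separated(bn, p, child, [])

    def test_agrees_with_independent_graph_oracle(self):
        """Bayes-ball reachability vs networkx's d-separation on random DAGs."""
        rng = np.random.default_rng(11)
        for seed in range(20):
            bn = random_network(6, max_parents=3, seed=seed)
            g = nx.DiGraph(bn.edges())
            g.add_nodes_from(bn.names)
            for x, y in itertools.combinations(bn.names, 2):
                others = [n for n in bn.names if n not in (x, y)]
                for _ in range(3):
                    k = rng.integers(0, len(others) + 1)
                    z = set(rng.choice(others, size=k, replace=False))
                    assert d_separated(bn, x, y, z) == nx.is_d_separator(
                        g, {x}, {y}, z
                    )

    def test_blanket_shields_target_from_everything_else(self):
        for seed in range(10):
            bn = random_network(7, max_parents=3, seed=100 + seed)
            for t in bn.names:
                mb = true_markov_blanket(bn, t).blanket
                for u in bn.names:
                    if u != t and u not in mb:
                        assert d_separated(bn, t, u, mb)


class TestMarkovBlanketTruth:
    def test_chain_blankets(self, chain_bn):
        assert true_markov_blanket(chain_bn, "B").blanket == {"A", "C"}
        assert true_markov_blanket(chain_bn, "A").blanket == {"B"}

    def test_collider_spouse(self, collider_bn):
        truth = true_markov_blanket(collider_bn, "A")
        assert truth.blanket == {"B", "C"}
        assert truth.spouses == {"B"}

    def test_unknown_node_raises(self, chain_bn):
        with pytest.raises(KeyError):
            true_markov_blanket(chain_bn, "Z")

    def test_matches_minimal_separating_set_by_exhaustion(self):
        """The graph blanket is the smallest set shielding the target."""
        for seed in range(8):
            bn = random_network(6, max_parents=3, seed=200 + seed)
            for t in bn.names:
                mb = true_markov_blanket(bn, t).blanket
                others = [n for n in bn.names if n != t]
                minimal = None
                for k in range(len(others) + 1):
                    for s in itertools.combinations(others, k):
                        rest = [u for u in others if u not in s]
                        if all(d_separated(bn, t, u, set(s)) for u in rest):
                            minimal = set(s)
                            break
                    if minimal is not None:
                        break
                assert minimal == set(mb)


class TestSampling:
    def test_degenerate_point_mass(self):
        bn = BayesianNetwork(["A"], [2], {}, {"A": [[0.0, 1.0]]})
        ds = sample(bn, 50, seed=0)
        assert (ds.values == 1).all()

    def test_deterministic_copy_chain(self):
        bn = BayesianNetwork(
            ["A", "B"], [2, 2], {"B": ["A"]},
            {"A": [[0.5, 0.5]], "B": [[1.0, 0.0], [0.0, 1.0]]},
        )
        ds = sample(bn, 200, seed=1)
        assert np.array_equal(ds.values[:, 0], ds.values[:, 1])

    def test_marginal_frequency_within_four_standard_errors(self):
        bn = BayesianNetwork(["A"], [2], {}, {"A": [[0.7, 0.3]]})
        ds = sample(bn, 10000, seed=2)
        freq = ds.values[:, 0].mean()
        se = np.sqrt(0.3 * 0.7 / 10000)
        assert abs(freq - 0.3) < 4 * se

    def test_same_seed_reproduces(self, strong5_bn):
        a = sample(strong5_bn, 300, seed=9)
        b = sample(strong5_bn, 300, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_conditional_frequencies_match_cpt(self, strong5_bn):
        """Empirical P(node | parent config) converges on the CPT row."""
        ds = sample(strong5_bn, 20000, seed=3)
        idx = {n: i for i, n in enumerate(strong5_bn.names)}
        for node in ("C", "D"):
            pars = strong5_bn.parents[node]
            tab = strong5_bn.cpts[node]
            cfgs = list(
                itertools.product(*(range(strong5_bn.arities[p]) for p in pars))
            )
            for ci, cfg in enumerate(cfgs):
                mask = np.ones(ds.N, dtype=bool)
                for p, v in zip(pars, cfg):
                    mask &= ds.values[:, idx[p]] == v
                n_cfg = mask.sum()
                assert n_cfg > 100
                for v in range(strong5_bn.arities[node]):
                    p_true = tab[ci, v]
                    p_hat = (ds.values[mask, idx[node]] == v).mean()
                    se = np.sqrt(max(p_true * (1 - p_true), 1e-6) / n_cfg)
                    assert abs(p_hat - p_true) < 5 * se


class TestRandomNetwork:
    def test_single_node(self):
        bn = random_network(1, max_parents=0, seed=0)
        assert len(bn) == 1

    def test_parent_budget_and_acyclicity(self):
        bn = random_network(10, max_parents=3, seed=5)
        assert all(len(bn.parents[n]) <= 3 for n in bn.names)
        assert len(bn.topological_order) == 10  # construction validates DAG

    def test_deterministic_given_seed(self):
        a = random_network(8, max_parents=3, seed=42)
        b = random_network(8, max_parents=3, seed=42)
        assert a.parents == b.parents
        assert all(np.array_equal(a.cpts[n], b.cpts[n]) for n in a.names)

    def test_derive_seed_stays_below_2_31(self):
        for i in range(100):
            s = derive_seed(12345, i, i * 7)
            assert 0 <= s < 2**31
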
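"""Joint-entropy caching and the decomposed G-test."""

import itertools
import math

import numpy as np
import pytest

from dcmi import (
    CITestConfig,
    ContingencyTable,
    DcmiBackend,
    DirectCountBackend,
    DiscreteDataset,
    DoFCache,
    JointEntropyTable,
    ci_test,
    cmi_decomposed,
    count_joint,
    degrees_of_freedom,
    g_test_dcmi,
    get_or_compute_term,
    hit_rate,
    joint_entropy,
)
from dcmi.cache import exhaustive_term_statistics, reuse_factor_formula


class TestJointEntropy:
    def test_uniform_two_cells(self):
        ct = ContingencyTable((0,), {(0,): 5, (1,): 5}, 10)
        assert joint_entropy(ct) == pytest.approx(math.log(2), rel=1e-12)

    def test_point_mass_is_zero(self):
        ct = ContingencyTable((0,), {(0,): 9}, 9)
        assert joint_entropy(ct) == 0.0

    def test_hand_evaluated_mixture(self):
        ct = ContingencyTable((0,), {(0,): 1, (1,): 1, (2,): 2}, 4)
        expected = 0.25 * math.log(4) * 2 + 0.5 * math.log(2)
        assert joint_entropy(ct) == pytest.approx(expected, rel=1e-12)

    def test_bounded_by_log_state_count(self):
        rng = np.random.default_rng(0)
        ds = DiscreteDataset(rng.integers(0, 3, size=(300, 3)))
        ct = count_joint(ds, (0, 1, 2))
        assert 0.0 <= joint_entropy(ct) <= math.log(27) + 1e-9


class TestCMIDecomposition:
    def test_all_zero_terms(self):
        assert cmi_decomposed(0.0, 0.0, 0.0, 0.0) == 0.0

    def test_tiny_negative_cancellation_clamped(self):
        assert cmi_decomposed(1.0, 1.0, 2.0 + 1e-12, 0.0) == 0.0

    def test_large_negative_is_an_error(self):
        with pytest.raises(AssertionError):
            cmi_decomposed(1.0, 1.0, 3.0, 0.0)

    def test_matches_direct_cmi_definition(self):
        """H(X,Z)+H(Y,Z)-H(X,Y,Z)-H(Z) vs I(X;Y,Z)-I(X;Z) from the PMF."""
        rng = np.random.default_rng(4)
        vals = rng.integers(0, 3, size=(400, 3))
        vals[:, 1] = np.where(rng.random(400) < 0.5, vals[:, 0], vals[:, 1])
        ds = DiscreteDataset(vals)

        def h(feats):
            return joint_entropy(count_joint(ds, feats))

        # direct definition: I(X;Y,Z) - I(X;Z) with I(A;B)=H(A)+H(B)-H(A,B)
        i_x_yz = h((0,)) + h((1, 2)) - h((0, 1, 2))
        i_x_z = h((0,)) + h((2,)) - h((0, 2))
        direct = i_x_yz - i_x_z
        decomposed = cmi_decomposed(h((0, 2)), h((1, 2)), h((0, 1, 2)), h((2,)))
        assert decomposed == pytest.approx(direct, abs=1e-9)


class TestCacheSemantics:
    def test_miss_then_hit_same_value(self, random_ds):
        jht = JointEntropyTable()
        v1 = get_or_compute_term(jht, random_ds, {0, 1})
        assert (jht.hits, jht.misses) == (0, 1)
        v2 = get_or_compute_term(jht, random_ds, {0, 1})
        assert (jht.hits, jht.misses) == (1, 1)
        assert v1 == v2

    def test_permuted_queries_share_one_entry(self, random_ds):
        jht = JointEntropyTable()
        get_or_compute_term(jht, random_ds, (2, 0))
        get_or_compute_term(jht, random_ds, (0, 2))
        assert len(jht) == 1 and jht.hits == 1

    def test_empty_set_bypasses_the_cache(self, random_ds):
        jht = JointEntropyTable()
        assert get_or_compute_term(jht, random_ds, ()) == 0.0
        assert jht.hits + jht.misses == 0

    def test_stored_value_matches_recomputation(self, random_ds):
        jht = JointEntropyTable()
        v = get_or_compute_term(jht, random_ds, {1, 3, 4})
        assert v == pytest.approx(
            joint_entropy(count_joint(random_ds, (1, 3, 4))), rel=1e-12
        )

    def test_dof_cache_filled_for_all_pair_permutations(self, random_ds):
        jht, dof = JointEntropyTable(), DoFCache()
        get_or_compute_term(jht, random_ds, {0, 1, 2}, dof)
        joint = count_joint(random_ds, (0, 1, 2))
        for a, b in itertools.combinations((0, 1, 2), 2):
            rest = tuple(f for f in (0, 1, 2) if f not in (a, b))
            assert dof.get(a, b, rest) == degrees_of_freedom(joint, a, b, rest)
        assert len(dof) == 3

    def test_serialization_roundtrip(self, random_ds):
        jht, dof = JointEntropyTable(), DoFCache()
        get_or_compute_term(jht, random_ds, {0, 1, 2}, dof)
        get_or_compute_term(jht, random_ds, {0, 1}, dof)
        jht2 = JointEntropyTable.from_json(jht.to_json())
        dof2 = DoFCache.from_json(dof.to_json())
        assert jht2.entries == jht.entries
        assert (jht2.hits, jht2.misses) == (jht.hits, jht.misses)
        assert dof2.entries == dof.entries


class TestDecomposedGTest:
    def test_equals_canonical_backend(self, random_ds):
        jht, dof = JointEntropyTable(), DoFCache()
        canonical = DirectCountBackend(random_ds)
        for x, y in itertools.combinations(range(random_ds.M), 2):
            for z in ((), (4,), (2, 4)):
                if x in z or y in z:
                    continue
                ref = ci_test(canonical, x, y, z)
                got = g_test_dcmi(random_ds, x, y, z, jht, dof)
                assert got.g == pytest.approx(ref.g, rel=1e-9, abs=1e-9)
                assert got.dof == ref.dof
                assert got.independent == ref.independent

    def test_unconditional_test_uses_three_lookups(self, random_ds):
        jht, dof = JointEntropyTable(), DoFCache()
        g_test_dcmi(random_ds, 0, 1, (), jht, dof)
        assert jht.hits + jht.misses == 3
        assert set(jht.entries) == {(0,), (1,), (0, 1)}

    def test_term_reuse_across_a_test_sequence(self, random_ds):
        """(0,1|∅), (0,2|{1}), (1,2|{0}): 11 lookups over 6 distinct terms."""
        jht, dof = JointEntropyTable(), DoFCache()
        g_test_dcmi(random_ds, 0, 1, (), jht, dof)
        g_test_dcmi(random_ds, 0, 2, (1,), jht, dof)
        g_test_dcmi(random_ds, 1, 2, (0,), jht, dof)
        assert jht.hits + jht.misses == 11
        assert jht.misses == 6
        assert jht.misses < 4 * 3  # fewer distributions than the canonical path

    def test_backend_counter_and_shared_cache(self, random_ds):
        backend = DcmiBackend(random_ds)
        ci_test(backend, 0, 1, (2,))
        ci_test(backend, 1, 0, (2,))  # permuted repeat: all terms hit
        assert backend.ci_tests == 2
        assert backend.jht.hits == 4


class TestHitRate:
    def test_simple_ratio(self):
        jht = JointEntropyTable()
        jht.hits, jht.misses = 97, 3
        assert hit_rate(jht) == pytest.approx(0.97)

    def test_first_lookup_rate_is_zero(self, random_ds):
        jht = JointEntropyTable()
        get_or_compute_term(jht, random_ds, {0})
        assert hit_rate(jht) == 0.0

    def test_no_lookups_is_an_error(self):
        with pytest.raises(RuntimeError):
            hit_rate(JointEntropyTable())

    def test_matches_enumeration_on_exhaustive_pair_tests(self):
        """Hit rate == 1 - distinct/total, counted by an independent scan."""
        rng = np.random.default_rng(9)
        ds = DiscreteDataset(rng.integers(0, 2, size=(100, 6)))
        jht, dof = JointEntropyTable(), DoFCache()
        seen: set[frozenset] = set()
        lookups = 0
        for x, y in itertools.combinations(range(6), 2):
            g_test_dcmi(ds, x, y, (), jht, dof)
            for term in ({x}, {y}, {x, y}):
                seen.add(frozenset(term))
                lookups += 1
        assert hit_rate(jht) == pytest.approx(1 - len(seen) / lookups)


class TestReuseFactor:
    @pytest.mark.parametrize("m", [4, 5, 6, 7, 8])
    def test_enumeration_matches_closed_form(self, m):
        st = exhaustive_term_statistics(m)
        assert st["distinct_terms"] == 2**m - 1
        assert st["ratio"] == pytest.approx(reuse_factor_formula(m), rel=1e-12)

    def test_ratio_approaches_half_m_m_minus_1(self):
        # the asymptotic reuse factor is m(m-1)/2
        for m in (6, 10, 14):
            assert reuse_factor_formula(m) / (m * (m - 1) / 2) == pytest.approx(
                1.0, rel=2 ** -(m - 4)
            )
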
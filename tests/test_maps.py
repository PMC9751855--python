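import numpy as np
import pytest

from comorbmap import Group, burden_profile, edges_at_threshold, \
    exceeds_reference_max, incidence_sum, joint_impairment, pair_counts, \
    total_impaired_pairs

from conftest import make_matrix


def brute_force_pairs(calls):
    """Oracle: exhaustive triple loop over children and domain pairs."""
    n, k = calls.shape
    out = np.zeros((k, k), dtype=int)
    for i in range(n):
        for a in range(k):
            for b in range(k):
                if a != b and calls[i, a] and calls[i, b]:
                    out[a, b] += 1
    return out


@pytest.fixture
def abc_matrix():
    """Three children over three domains: the worked pair-count example."""
    return make_matrix([[1, 1, 0], [1, 0, 1], [1, 1, 1]])


class TestBurden:
    def test_all_false_matrix(self):
        m = make_matrix(np.zeros((4, 5), dtype=bool))
        p = burden_profile(m)
        assert set(p.per_child.values()) == {0}
        assert p.histogram(Group.EPT) == {0: 4}

    def test_direct_counts(self):
        m = make_matrix([[1, 1, 0], [0, 0, 1]])
        p = burden_profile(m)
        assert list(p.per_child.values()) == [2, 1]

    def test_row_sum_oracle_random(self):
        rng = np.random.default_rng(5)
        calls = rng.random((50, 20)) < 0.3
        p = burden_profile(make_matrix(calls))
        for i, cid in enumerate(sorted(p.per_child, key=lambda c: int(c[1:]))):
            manual = sum(1 for j in range(20) if calls[i, j])
            assert p.per_child[cid] == manual

    def test_histogram_mass_equals_group_size(self):
        rng = np.random.default_rng(6)
        calls = rng.random((30, 20)) < 0.25
        groups = [Group.EPT] * 18 + [Group.TERM] * 12
        p = burden_profile(make_matrix(calls, groups=groups))
        assert sum(p.histogram(Group.EPT).values()) == 18
        assert sum(p.histogram(Group.TERM).values()) == 12


class TestExceedance:
    def _profile(self, ept, term):
        calls = np.zeros((len(ept) + len(term), 20), dtype=bool)
        for i, b in enumerate(list(ept) + list(term)):
            calls[i, :b] = True
        groups = [Group.EPT] * len(ept) + [Group.TERM] * len(term)
        return burden_profile(make_matrix(calls, groups=groups))

    def test_strictly_above_reference_max(self):
        res = exceeds_reference_max(self._profile([6, 5, 2], [5, 3]),
                                    Group.TERM)
        assert res.reference_max == 5
        assert res.count == 1  # burden 6 flagged, burden 5 not
        assert res.proportion == pytest.approx(1 / 3)

    def test_all_equal_flags_nobody(self):
        res = exceeds_reference_max(self._profile([4, 4], [4]), Group.TERM)
        assert res.count == 0


class TestPairCounts:
    def test_worked_example(self, abc_matrix):
        g = pair_counts(abc_matrix, Group.EPT)
        assert g.pair_count("MND", "MD") == 2
        assert g.pair_count("MND", "AC") == 2
        assert g.pair_count("MD", "AC") == 1
        assert g.node_counts == {"MND": 3, "MD": 2, "AC": 2}

    def test_no_cooccurrence(self):
        m = make_matrix(np.eye(4, dtype=bool))
        g = pair_counts(m, Group.EPT)
        assert g.pair_matrix.sum() == 0

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            calls = rng.random((rng.integers(5, 100), 20)) < rng.uniform(0.1, 0.5)
            g = pair_counts(make_matrix(calls), Group.EPT)
            assert np.array_equal(g.pair_matrix, brute_force_pairs(calls))

    def test_pair_bounded_by_node_counts(self):
        rng = np.random.default_rng(12)
        calls = rng.random((60, 20)) < 0.3
        g = pair_counts(make_matrix(calls), Group.EPT)
        counts = np.array([g.node_counts[d] for d in g.domains])
        bound = np.minimum.outer(counts, counts)
        np.fill_diagonal(bound, 0)
        assert np.all(g.pair_matrix <= bound)

    def test_missing_cell_excluded_from_pairs(self):
        m = make_matrix([[1, 0], [1, 1]], observed=[[1, 0], [1, 1]])
        g = pair_counts(m, Group.EPT)
        assert g.pair_count("MND", "MD") == 1


class TestThresholds:
    def test_edges_at_thresholds(self, abc_matrix):
        g = pair_counts(abc_matrix, Group.EPT)
        assert len(edges_at_threshold(g, 1)) == 3
        assert edges_at_threshold(g, 2) == [("MND", "MD", 2), ("MND", "AC", 2)]
        assert edges_at_threshold(g, 3) == []

    def test_total_impaired_pairs(self, abc_matrix):
        g = pair_counts(abc_matrix, Group.EPT)
        assert total_impaired_pairs(g, 1) == 3
        assert incidence_sum(g, 1) == 5

    def test_empty_matrix_zero_pairs(self):
        g = pair_counts(make_matrix(np.zeros((3, 20), dtype=bool)), Group.EPT)
        assert total_impaired_pairs(g) == 0

    def test_fully_impaired_child_gives_all_190_pairs(self):
        g = pair_counts(make_matrix(np.ones((1, 20), dtype=bool)), Group.EPT)
        assert total_impaired_pairs(g, 1) == 190  # C(20, 2)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(13)
        calls = rng.random((40, 20)) < 0.35
        g = pair_counts(make_matrix(calls), Group.EPT)
        prev = None
        for k in range(1, 8):
            edges = {(a, b) for a, b, _ in edges_at_threshold(g, k)}
            if prev is not None:
                assert edges <= prev
            assert total_impaired_pairs(g, k) == len(edges)
            prev = edges


class TestJoint:
    def test_triple_conjunction(self):
        m = make_matrix([[1, 1, 1], [1, 1, 0]],
                        domains=("MND", "DC", "FI"))
        res = joint_impairment(m, ["MND", "DC", "FI"])
        assert res.per_child == {"c0": True, "c1": False}
        assert res.group_counts["EPT"] == 1

    def test_unknown_domain_rejected(self):
        m = make_matrix([[1]])
        with pytest.raises(KeyError, match="NOPE"):
            joint_impairment(m, ["NOPE"])

    def test_unobserved_domain_blocks_evaluation(self):
        m = make_matrix([[1, 0]], observed=[[1, 0]])
        res = joint_impairment(m, ["MND", "MD"])
        assert res.per_child["c0"] is False
        assert res.evaluable["c0"] is False

    def test_subset_monotonicity(self):
        rng = np.random.default_rng(14)
        calls = rng.random((50, 20)) < 0.4
        m = make_matrix(calls)
        d = list(m.domains)
        triple = joint_impairment(m, d[:3]).group_counts["EPT"]
        for pair in ([d[0], d[1]], [d[0], d[2]], [d[1], d[2]]):
            assert triple <= joint_impairment(m, pair).group_counts["EPT"]
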
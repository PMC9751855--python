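import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from comorbmap import CohortTable, Group, build_impairment_matrix, \
    classify_mnd, impute_group_median, impute_subtest_mean, is_impaired
from comorbmap.classify import MNDCategory, write_impairment_matrix
from comorbmap.registry import DEFAULT_REGISTRY

from conftest import make_child, make_matrix


class TestMND:
    def test_all_clear_is_normal(self):
        s = classify_mnd([False] * 8)
        assert s.status is MNDCategory.NORMAL
        assert s.n_dysfunctional == 0
        assert not s.impaired

    @pytest.mark.parametrize("n,expected", [
        (1, MNDCategory.SIMPLE), (2, MNDCategory.SIMPLE),
        (3, MNDCategory.COMPLEX), (8, MNDCategory.COMPLEX),
    ])
    def test_simple_complex_boundaries(self, n, expected):
        """1-2 dysfunctional domains = simple MND, more than 2 = complex."""
        flags = [True] * n + [False] * (8 - n)
        s = classify_mnd(flags)
        assert s.status is expected
        assert s.impaired  # simple and complex pool as impairment

    def test_wrong_flag_count_is_structural_error(self):
        with pytest.raises(ValueError, match="8"):
            classify_mnd([True] * 7)

    def test_missing_exam_or_flag_is_indeterminate(self):
        assert classify_mnd(None) is None
        assert classify_mnd([True] * 7 + [None]) is None


class TestCutoffs:
    def test_nepsy_boundary(self):
        spec = DEFAULT_REGISTRY["DeCo"]
        assert is_impaired(7, spec) is True
        assert is_impaired(8, spec) is False

    def test_mabc_boundary(self):
        spec = DEFAULT_REGISTRY["MD"]
        assert is_impaired(7, spec) is True
        assert is_impaired(8, spec) is False

    def test_sipt_strict_boundary_and_flag(self):
        spec = DEFAULT_REGISTRY["FI"]
        assert is_impaired(-1.2, spec) is True
        assert is_impaired(0.0, spec) is False
        assert is_impaired(-1.0, spec) is False  # strict by default
        assert is_impaired(-1.0, spec, sipt_inclusive=True) is True

    def test_missing_score_gives_no_call(self):
        assert is_impaired(None, DEFAULT_REGISTRY["FI"]) is None

    def test_out_of_range_score_names_bounds(self):
        with pytest.raises(ValueError, match=r"\[-3.0, 3.0\]"):
            is_impaired(4.0, DEFAULT_REGISTRY["FI"])
        with pytest.raises(ValueError, match=r"\[1.0, 19.0\]"):
            is_impaired(0, DEFAULT_REGISTRY["DeCo"])


class TestImputation:
    def _cohort(self, values):
        children = [
            make_child(f"c{i}", Group.EPT,
                       scores={} if v is None else {"FI": v})
            for i, v in enumerate(values)
        ]
        return CohortTable(children)

    def test_median_of_two(self):
        out = impute_group_median(self._cohort([-0.5, -1.5, None]), "FI",
                                  Group.EPT)
        assert out.children[2].scores["FI"] == -1.0
        assert out.imputation_log == [("c2", "FI", -1.0)]

    def test_median_by_sorting(self):
        out = impute_group_median(self._cohort([1, 2, 3, None]), "FI",
                                  Group.EPT)
        assert out.children[3].scores["FI"] == 2

    def test_idempotent_and_noop_without_missing(self):
        cohort = self._cohort([1.0, 2.0])
        out = impute_group_median(cohort, "FI", Group.EPT)
        assert [c.scores for c in out.children] == \
               [c.scores for c in cohort.children]
        once = impute_group_median(self._cohort([1, 2, 3, None]), "FI",
                                   Group.EPT)
        twice = impute_group_median(once, "FI", Group.EPT)
        assert [c.scores for c in once.children] == \
               [c.scores for c in twice.children]

    def test_no_observed_value_errors(self):
        with pytest.raises(ValueError, match="no observed"):
            impute_group_median(self._cohort([None, None]), "FI", Group.EPT)

    def test_subtest_mean(self):
        rec = make_child(aux={"block": 10.0, "matrix": 12.0})
        out = impute_subtest_mean(rec, ["block", "matrix", "pict"], "pict")
        assert out.aux_scores["pict"] == 11.0

    def test_subtest_mean_of_available(self):
        rec = make_child(aux={"block": 9.0, "pict": 15.0})
        out = impute_subtest_mean(rec, ["block", "matrix", "pict"], "matrix")
        assert out.aux_scores["matrix"] == 12.0

    def test_subtest_target_observed_is_noop(self):
        rec = make_child(aux={"block": 9.0, "pict": 15.0})
        assert impute_subtest_mean(rec, ["block", "pict"], "pict") is rec

    def test_subtest_all_missing_errors(self):
        with pytest.raises(ValueError, match="no observed member"):
            impute_subtest_mean(make_child(), ["block", "matrix"], "matrix")


class TestMatrix:
    def test_healthy_child_row_all_false(self):
        scores = {d.abbreviation: d.native_mean
                  for d in DEFAULT_REGISTRY.score_domains}
        cohort = CohortTable([make_child(touwen=(False,) * 8, scores=scores)])
        m = build_impairment_matrix(cohort)
        assert not m.calls.any()
        assert m.observed.all()

    def test_single_impairment_lands_in_fi_column(self):
        scores = {d.abbreviation: d.native_mean
                  for d in DEFAULT_REGISTRY.score_domains}
        scores["FI"] = -1.5
        cohort = CohortTable([make_child(touwen=(False,) * 8, scores=scores)])
        m = build_impairment_matrix(cohort)
        assert m.calls.sum() == 1
        assert m.calls[0, m.column("FI")]

    def test_missing_propagates_to_observed_mask(self):
        cohort = CohortTable([make_child(touwen=None, scores={"FI": -2.0})])
        m = build_impairment_matrix(cohort)
        assert not m.observed[0, m.column("MND")]
        assert not m.calls[0, m.column("MND")]
        assert m.observed[0, m.column("FI")]

    def test_call_on_unobserved_cell_rejected(self):
        with pytest.raises(ValueError, match="unobserved"):
            make_matrix([[True]], observed=[[False]])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=-3, max_value=3),
           st.floats(min_value=0.0, max_value=2.0))
    def test_monotonicity_lowering_score_never_unimpairs(self, score, drop):
        """Lowering any score never flips an impairment call true->false."""
        spec = DEFAULT_REGISTRY["FI"]
        hi = is_impaired(score, spec)
        lo = is_impaired(max(score - drop, -3.0), spec)
        assert not (hi and not lo)

    def test_missing_safety_burden_unchanged_by_unobserved_toggle(self):
        m = make_matrix([[True, False, False]],
                        observed=[[True, False, True]])
        burden_before = m.calls.sum(axis=1)
        # an unobserved cell cannot legally hold a call; the burden therefore
        # only depends on observed cells
        assert burden_before[0] == 1
        assert not m.calls[0, 1]

    def test_writer_emits_na_for_unobserved(self, tmp_path, small_cohort):
        m = build_impairment_matrix(small_cohort)
        path = tmp_path / "m.tsv"
        write_impairment_matrix(m, path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t")[2:] == list(m.domains)
        n_na = sum(line.count("NA") for line in lines[1:])
        assert n_na == int((~m.observed).sum())

    def test_mnd_pooling(self, small_cohort):
        """Matrix MND column equals (status != NORMAL)."""
        m = build_impairment_matrix(small_cohort)
        j = m.column("MND")
        for i, child in enumerate(small_cohort.children):
            status = classify_mnd(child.touwen_domains)
            if status is None:
                assert not m.observed[i, j]
            else:
                assert m.calls[i, j] == status.impaired
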
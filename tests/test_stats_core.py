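import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evlong.stats_core import (
    DegenerateTableError,
    auc_rank,
    bh_adjust,
    chi2_2x2,
    rank_sum_test,
    spearman_corr,
    t_test_summary,
)

from .oracles import auc_pairs, bh_stepup, exact_ranksum_p, spearman_formula, spearman_perm_p

# strategies producing tie-free small samples
_distinct_floats = st.lists(
    st.integers(min_value=-100, max_value=100), min_size=2, max_size=10, unique=True
).map(lambda v: [float(x) for x in v])


class TestRankSum:
    @pytest.mark.parametrize(
        "x, y, expected_p",
        [
            ((1, 2, 3), (4, 5, 6), 0.1),       # only 2 of 20 labelings as extreme
            ((1, 3), (2, 4), 2 / 3),           # 4 of 6 labelings as extreme
        ],
    )
    def test_exact_small_sample_p(self, x, y, expected_p):
        res = rank_sum_test(np.array(x, float), np.array(y, float))
        assert res.method_detail == "exact"
        assert res.p_value == pytest.approx(expected_p, abs=1e-12)

    def test_identical_constant_samples_give_p_one(self):
        res = rank_sum_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_large_samples_use_approximation(self):
        rng = np.random.default_rng(0)
        res = rank_sum_test(rng.normal(size=20), rng.normal(size=20))
        assert res.method_detail.startswith("approximate")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(pooled=_distinct_floats, n1=st.integers(min_value=1, max_value=9))
    def test_exact_p_matches_labeling_enumeration(self, pooled, n1):
        """Exact p equals brute-force enumeration for tie-free n <= 10."""
        if n1 >= len(pooled):
            n1 = len(pooled) - 1
        x, y = pooled[:n1], pooled[n1:]
        res = rank_sum_test(x, y)
        assert res.method_detail == "exact"
        assert res.p_value == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)


class TestChi2:
    def test_no_association_gives_zero_statistic(self):
        res = chi2_2x2(10, 10, 10, 10)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_closed_form_value(self):
        # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 8.888..., p ~ 0.00287
        res = chi2_2x2(20, 4, 10, 14)
        assert res.statistic == pytest.approx(8.888888888, abs=1e-8)
        assert res.p_value == pytest.approx(0.00287, abs=2e-5)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi2_2x2(0, 0, 5, 5)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2(-1, 2, 3, 4)


class TestBH:
    def test_step_up_example(self):
        q_values, reject = bh_adjust([0.001, 0.002, 0.009, 0.04], q=0.01)
        assert list(reject) == [True, True, False, False]

    def test_all_ones_reject_none(self):
        _, reject = bh_adjust([1.0, 1.0, 1.0], q=0.01)
        assert not reject.any()

    def test_single_p_threshold_is_q(self):
        _, reject = bh_adjust([0.005], q=0.01)
        assert reject.all()

    def test_q_values_dominate_p_values(self):
        p = [0.3, 0.01, 0.7, 0.04]
        q_values, _ = bh_adjust(p, q=0.05)
        assert (q_values >= np.asarray(p)).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5], q=0.05)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=30),
        q=st.floats(min_value=0.005, max_value=0.5),
    )
    def test_rejections_match_definitional_step_up(self, p, q):
        _, reject = bh_adjust(p, q=q)
        assert (reject == bh_stepup(p, q)).all()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(p=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=20))
    def test_rejected_set_order_invariant(self, p):
        _, reject = bh_adjust(p, q=0.05)
        perm = np.random.default_rng(0).permutation(len(p))
        _, reject_perm = bh_adjust(np.asarray(p)[perm], q=0.05)
        assert (reject_perm == reject[perm]).all()


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert spearman_corr(x, [2.0, 4.0, 9.0, 11.0])[0] == 1.0
        assert spearman_corr(x, [8.0, 5.0, 1.0, 0.0])[0] == -1.0

    def test_rank_formula_example(self):
        rho, _ = spearman_corr([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        xy=st.lists(
            st.tuples(st.integers(-50, 50), st.integers(-50, 50)),
            min_size=5, max_size=7,
            unique_by=(lambda t: t[0], lambda t: t[1]),
        )
    )
    def test_matches_rank_formula_and_permutation_null(self, xy):
        x = [float(a) for a, _ in xy]
        y = [float(b) for _, b in xy]
        rho, p = spearman_corr(x, y)
        assert rho == pytest.approx(spearman_formula(x, y), abs=1e-12)
        # t-approximation vs exact permutation: loose agreement at small n
        assert p == pytest.approx(spearman_perm_p(x, y), abs=0.12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        xy=st.lists(
            st.tuples(st.integers(-50, 50), st.integers(-50, 50)),
            min_size=4, max_size=8,
            unique_by=(lambda t: t[0], lambda t: t[1]),
        )
    )
    def test_invariant_under_monotone_transforms(self, xy):
        x = np.array([a for a, _ in xy], dtype=float)
        y = np.array([b for _, b in xy], dtype=float)
        rho, p = spearman_corr(x, y)
        rho2, p2 = spearman_corr(np.exp(x / 20.0), y**3)
        assert rho2 == pytest.approx(rho, abs=1e-12)
        assert p2 == pytest.approx(p, abs=1e-9)


class TestAUC:
    def test_perfect_separation(self):
        assert auc_rank([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert auc_rank([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_pair_counting_example(self):
        # positives (0.9, 0.4), negatives (0.5, 0.1): 3 of 4 pairs concordant
        assert auc_rank([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_rank([0.1, 0.2], [1, 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        scores=st.lists(st.integers(-5, 5), min_size=2, max_size=12),
        data=st.data(),
    )
    def test_matches_brute_force_and_label_flip(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        scores = [float(s) for s in scores]
        auc = auc_rank(scores, labels)
        assert auc == pytest.approx(auc_pairs(scores, labels), abs=1e-12)
        flipped = [1 - l for l in labels]
        assert auc + auc_rank(scores, flipped) == pytest.approx(1.0, abs=1e-12)


class TestTTestSummary:
    def test_equal_groups_give_p_one(self):
        res = t_test_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            t_test_summary(1.0, 0.0, 10, 2.0, 1.0, 10)

    def test_welch_flag_changes_method(self):
        res = t_test_summary(1.0, 1.0, 10, 2.0, 3.0, 12, equal_var=False)
        assert res.method_detail == "welch"
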
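"""MSAQ scoring and the behavioral statistics battery."""

import numpy as np
import pytest
from scipy import stats as sstats

from vims_hrv.behavioral import (
    CATEGORIES,
    association_analysis,
    delta_scores,
    load_item_categories,
    msaq_condition_comparison,
    order_effect_test,
    paired_t_one_tailed,
    score_msaq,
)
from vims_hrv.errors import InsufficientDataError, ParameterError
from vims_hrv.synthetic import MSAQResponse, _msaq_items


def _resp(items, timing="post"):
    return MSAQResponse(np.asarray(items), timing, "P01", "sham")


class TestScoring:
    def test_item_map_has_the_instrument_structure(self):
        cats = load_item_categories()
        counts = {c: sum(1 for v in cats.values() if v == c) for c in CATEGORIES}
        assert counts == {"gastrointestinal": 4, "central": 5,
                          "peripheral": 3, "sopite": 4}

    def test_maximum_scores(self):
        s = score_msaq(_resp([9] * 16))
        assert all(s[k] == pytest.approx(100.0) for k in
                   ("total",) + CATEGORIES)

    def test_minimum_scores(self):
        s = score_msaq(_resp([1] * 16))
        assert all(s[k] == pytest.approx(100.0 / 9.0) for k in
                   ("total",) + CATEGORIES)

    def test_gastrointestinal_worked_example(self):
        items = [5, 3, 1, 1] + [1] * 12  # items 1-4 are gastrointestinal
        s = score_msaq(_resp(items))
        assert s.gastrointestinal == pytest.approx(10.0 / 36.0 * 100.0)

    def test_item_order_within_category_irrelevant(self):
        a = [5, 3, 1, 1] + [1] * 12
        b = [1, 1, 3, 5] + [1] * 12
        assert score_msaq(_resp(a)).gastrointestinal == pytest.approx(
            score_msaq(_resp(b)).gastrointestinal
        )

    def test_total_is_item_count_weighted_mean_of_categories(self, rng):
        items = rng.integers(1, 10, size=16)
        s = score_msaq(_resp(items))
        weights = {"gastrointestinal": 4, "central": 5, "peripheral": 3,
                   "sopite": 4}
        weighted = sum(weights[c] * s[c] for c in CATEGORIES) / 16
        assert s.total == pytest.approx(weighted)

    def test_delta_change(self):
        pre = score_msaq(_resp([1] * 16, "pre"))
        post = score_msaq(_resp([3] * 16))
        d = delta_scores(pre, post)
        assert d.total == pytest.approx((3 - 1) * 16 / 144 * 100)

    def test_score_range_validated(self):
        with pytest.raises(ParameterError):
            _resp([0] + [1] * 15)
        with pytest.raises(ParameterError):
            _resp([1] * 15)


def _delta_sets(vals_sham, vals_tes):
    scales = ("total",) + CATEGORIES
    return ({s: np.asarray(vals_sham, float) for s in scales},
            {s: np.asarray(vals_tes, float) for s in scales})


class TestMSAQComparison:
    def test_identical_deltas_flagged_degenerate_p_one(self):
        sham, tes = _delta_sets([10, 12, 8, 15, 11, 9], [10, 12, 8, 15, 11, 9])
        res = msaq_condition_comparison(sham, tes)
        assert res["total"].degenerate
        assert res["total"].p_value == 1.0

    def test_one_tailed_direction_and_exact_mode(self):
        sham, tes = _delta_sets([20, 25, 30, 22, 28, 26, 24],
                                [10, 12, 15, 11, 13, 14, 12])
        res = msaq_condition_comparison(sham, tes)
        for scale, r in res.items():
            assert r.tail == "one"
            assert r.direction == "tes < sham"
            assert r.p_value < 0.05

    def test_planted_ordinal_shift_detected_with_high_power(self):
        """Latent-shift MSAQ generator (sham 1.5 vs tES 0.5): the one-tailed
        Wilcoxon on total-score deltas fires in >= 80% of replicates."""
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(900 + rep)
            d_sham, d_tes = [], []
            for _ in range(14):
                base = 1.5 + 0.5 * rng.standard_normal() \
                    + rng.normal(0, 0.4, 16)
                pre_s, post_s = _msaq_items(rng, base, 1.5)
                pre_t, post_t = _msaq_items(rng, base, 0.5)
                d_sham.append(score_msaq(_resp(post_s)).total
                              - score_msaq(_resp(pre_s, "pre")).total)
                d_tes.append(score_msaq(_resp(post_t)).total
                             - score_msaq(_resp(pre_t, "pre")).total)
            sham, tes = _delta_sets(d_sham, d_tes)
            hits += msaq_condition_comparison(sham, tes)["total"].p_value < 0.05
        assert hits >= 0.8 * n_rep


class TestPairedT:
    def test_equal_sets_give_half(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t_one_tailed(x, x.copy())
        assert res.statistic == 0.0
        assert res.p_value == 0.5
        assert res.degenerate

    def test_constant_offset_forced_direction(self):
        x = np.array([1.0, 2.0, 3.0])
        res = paired_t_one_tailed(x + 2.0, x, "greater")
        assert res.degenerate and res.p_value < 1e-6
        res = paired_t_one_tailed(x + 2.0, x, "less")
        assert res.degenerate and res.p_value == 1.0

    def test_shift_invariance(self, rng):
        x = rng.normal(10, 2, 12)
        y = rng.normal(11, 2, 12)
        a = paired_t_one_tailed(x, y, "less")
        b = paired_t_one_tailed(x + 100.0, y + 100.0, "less")
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_df_recorded(self, rng):
        x, y = rng.normal(size=9), rng.normal(size=9)
        assert paired_t_one_tailed(x, y).df == 8


class TestAssociations:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        y = 2 * x + 1
        assert association_analysis(x, y, "pearson").statistic == pytest.approx(1.0)
        lin = association_analysis(x, y, "linreg")
        assert lin.extras["r_squared"] == pytest.approx(1.0)
        assert lin.statistic == pytest.approx(2.0)
        assert lin.extras["intercept"] == pytest.approx(1.0)

    def test_monotone_nonlinear_relation(self):
        x = np.linspace(0, 4, 12)
        y = np.exp(x)
        assert association_analysis(x, y, "spearman").statistic == pytest.approx(1.0)
        assert association_analysis(x, y, "pearson").statistic < 1.0

    def test_constant_input_flagged(self):
        x = np.full(8, 3.0)
        y = np.arange(8.0)
        res = association_analysis(x, y, "pearson")
        assert res.degenerate

    def test_null_correlation_calibrated(self):
        """Independent x, y at n = 14: |r| exceeds the two-tailed critical
        value in about 5% of replicates."""
        rng = np.random.default_rng(0)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            x, y = rng.standard_normal(14), rng.standard_normal(14)
            hits += association_analysis(x, y, "pearson").p_value < 0.05
        lo, hi = sstats.binom.ppf([0.025, 0.975], n_rep, 0.05)
        assert lo <= hits <= hi


class TestOrderEffect:
    def test_identical_groups(self):
        vals = np.array([1.0, 1.0, 1.0, 1.0])
        labels = np.array(["a", "a", "b", "b"])
        res = order_effect_test(vals, labels)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_large_offset_detected(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 7), rng.normal(8, 1, 7)])
        labels = np.array(["a"] * 7 + ["b"] * 7)
        res = order_effect_test(vals, labels)
        assert res.p_value < 0.001 and res.df == 1

    def test_f_equals_squared_pooled_t(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 6), rng.normal(1, 1, 8)])
        labels = np.array(["a"] * 6 + ["b"] * 8)
        res = order_effect_test(vals, labels)
        t = sstats.ttest_ind(vals[labels == "a"], vals[labels == "b"])
        assert res.statistic == pytest.approx(t.statistic**2)

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            order_effect_test(np.array([1.0, 2.0, 3.0]),
                              np.array(["a", "b", "b"]))
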
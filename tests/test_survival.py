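import numpy as np
import pandas as pd
import pytest

from sfcomod.io import ExpressionMatrix, SurvivalTable, ValidationError
from sfcomod.survival import (
    compare_groups,
    logrank_km,
    median_normalize,
    median_split,
    module_score,
)


def _surv(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return SurvivalTable(pd.DataFrame({"time": times, "event": events}, index=ids))


class TestModuleScore:
    def test_single_gene_module_is_that_row(self, tiny_expr):
        score = module_score(tiny_expr, ["g1"])
        pd.testing.assert_series_equal(
            score, tiny_expr.data.loc["g1"], check_names=False
        )

    def test_two_gene_mean(self):
        X = ExpressionMatrix(pd.DataFrame({"s": [2.0, 4.0]}, index=["a", "b"]))
        assert module_score(X, ["a", "b"])["s"] == pytest.approx(3.0)

    def test_tracks_latent_activity(self, small_cohort):
        score = module_score(
            small_cohort.expression, small_cohort.truth.module_genes("enhancer")
        )
        activity = pd.Series(small_cohort.truth.activity)
        r = np.corrcoef(score.loc[activity.index], activity)[0, 1]
        assert r >= 0.9


class TestMedianNormalize:
    def test_odd_count_row(self):
        X = ExpressionMatrix(pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc")))
        out = median_normalize(X)
        np.testing.assert_allclose(out.data.loc["g"], [-1, 0, 1])

    def test_even_count_midpoint_convention(self):
        X = ExpressionMatrix(pd.DataFrame([[1.0, 2, 3, 4]], index=["g"], columns=list("abcd")))
        out = median_normalize(X)
        np.testing.assert_allclose(out.data.loc["g"], [-1.5, -0.5, 0.5, 1.5])

    def test_idempotent_and_median_exactly_zero(self, rng):
        X = ExpressionMatrix(
            pd.DataFrame(rng.normal(8, 2, size=(6, 11)),
                         index=[f"g{i}" for i in range(6)],
                         columns=[f"s{i}" for i in range(11)])
        )
        once = median_normalize(X)
        twice = median_normalize(once)
        np.testing.assert_array_equal(once.data.median(axis=1).to_numpy(), np.zeros(6))
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestCompareGroups:
    def test_identical_groups(self):
        v = pd.Series([1.0, 2, 3, 1, 2, 3])
        lab = pd.Series(["a"] * 3 + ["b"] * 3)
        res = compare_groups(v, lab)
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_hand_worked_pooled_t(self):
        # (1,2,3) vs (4,5,6): pooled sd 1, t = -3.6742, df 4, p ~ 0.0214
        v = pd.Series([1.0, 2, 3, 4, 5, 6])
        lab = pd.Series(["a"] * 3 + ["b"] * 3)
        res = compare_groups(v, lab)
        assert res["statistic"] == pytest.approx(-3.6742, abs=1e-4)
        assert res["df"] == 4
        assert res["p_value"] == pytest.approx(0.0214, abs=2e-4)

    def test_three_groups_use_anova(self, rng):
        v = pd.Series(rng.normal(size=30))
        lab = pd.Series(["a", "b", "c"] * 10)
        res = compare_groups(v, lab)
        assert res["test"] == "anova"
        assert res["statistic"] >= 0

    def test_small_group_rejected(self):
        v = pd.Series([1.0, 2, 3])
        lab = pd.Series(["a", "a", "b"])
        with pytest.raises(ValidationError, match=">= 2 samples"):
            compare_groups(v, lab)


class TestMedianSplit:
    def test_even_split(self):
        s = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        g = median_split(s)
        assert set(g[g == "low"].index) == {"a", "b"}
        assert set(g[g == "high"].index) == {"c", "d"}

    def test_ties_go_low(self):
        s = pd.Series([1.0, 2, 2, 3], index=list("abcd"))
        g = median_split(s)
        assert set(g[g == "high"].index) == {"d"}

    def test_translation_invariance(self):
        s = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        pd.testing.assert_series_equal(median_split(s), median_split(s + 100))

    def test_constant_scores_rejected(self):
        with pytest.raises(ValidationError, match="identical"):
            median_split(pd.Series([2.0, 2, 2, 2]))


class TestLogrankKM:
    def test_identical_groups_null(self):
        surv = _surv([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        groups = pd.Series(["high"] * 3 + ["low"] * 3, index=surv.data.index)
        km = logrank_km(surv, groups)
        assert km.chi_square == pytest.approx(0.0, abs=1e-12)
        assert km.p_value == pytest.approx(1.0)

    def test_hand_worked_example(self):
        # group A events at t=1,2; group B at t=3,4; no censoring:
        # O_A=2, E_A=5/6, V=17/36 -> chi2 = 49/17 ~ 2.882, HR = 19/5 = 3.8
        surv = _surv([1, 2, 3, 4], [1, 1, 1, 1])
        groups = pd.Series(["high", "high", "low", "low"], index=surv.data.index)
        km = logrank_km(surv, groups)
        assert km.chi_square == pytest.approx(49 / 17, abs=1e-3)
        assert km.hazard_ratio == pytest.approx(3.8, abs=1e-3)
        assert km.expected["high"] == pytest.approx(5 / 6, abs=1e-12)

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines.statistics import logrank_test

        times = rng.exponential(5, size=60)
        events = (rng.random(60) < 0.7).astype(int)
        labels = np.where(rng.random(60) < 0.5, "high", "low")
        surv = _surv(times, events)
        km = logrank_km(surv, pd.Series(labels, index=surv.data.index))
        ref = logrank_test(
            times[labels == "high"], times[labels == "low"],
            events[labels == "high"], events[labels == "low"],
        )
        assert km.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
        assert km.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_curve_starts_at_one_and_decreases(self, rng):
        times = rng.exponential(5, size=40)
        events = (rng.random(40) < 0.8).astype(int)
        labels = np.where(rng.random(40) < 0.5, "high", "low")
        surv = _surv(times, events)
        km = logrank_km(surv, pd.Series(labels, index=surv.data.index))
        for curve in km.curves.values():
            assert curve.iloc[0]["survival"] == 1.0
            assert (np.diff(curve["survival"]) <= 1e-12).all()

    def test_zero_event_group_hr_undefined(self):
        surv = _surv([1, 2, 3, 4], [1, 1, 0, 0])
        groups = pd.Series(["high", "high", "low", "low"], index=surv.data.index)
        km = logrank_km(surv, groups)
        assert np.isnan(km.hazard_ratio)
        assert np.isfinite(km.chi_square)
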
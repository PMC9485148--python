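import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dentalage.metrics import (
    MetricError,
    PairedAges,
    age_deviation,
    cohens_kappa,
    mae,
    paired_t_test,
    per_group_mae,
    regression_metrics,
    significance_tier,
)
from dentalage.staging import Sex, standard_bins


def pair_from(ca, da, sex=Sex.FEMALE):
    ca = np.asarray(ca, dtype=float)
    return PairedAges(
        [f"S{i}" for i in range(len(ca))], ca, np.asarray(da, dtype=float),
        [sex] * len(ca),
    )


class TestAgeDeviation:
    def test_zero_when_equal(self):
        _, mean, sd = age_deviation(pair_from([5, 9, 12], [5, 9, 12]))
        assert mean == 0.0 and sd == 0.0

    def test_sign_convention_overestimation_positive(self):
        ad, mean, _ = age_deviation(pair_from([10.0], [9.5]))
        assert ad[0] == pytest.approx(-0.5)

    def test_summary_matches_reported_style(self, rng):
        # DA = CA + N(0.31, 1.18): recovered mean/sd within sampling error
        ca = rng.uniform(2, 18, size=5000)
        da = ca + rng.normal(0.31, 1.18, size=5000)
        _, mean, sd = age_deviation(pair_from(ca, da))
        assert mean == pytest.approx(0.31, abs=0.06)
        assert sd == pytest.approx(1.18, abs=0.06)


class TestMAE:
    def test_zero_for_identical(self):
        assert mae(pair_from([3, 4], [3, 4])) == 0.0

    def test_mae_differs_from_abs_mean_ad(self):
        pair = pair_from([10, 10], [11, 9])
        assert mae(pair) == 1.0
        assert age_deviation(pair)[1] == 0.0

    def test_age_cap_filters_on_ca(self):
        pair = pair_from([15.0, 17.0], [16.0, 15.0])
        assert mae(pair, age_cap=16.0) == pytest.approx(1.0)  # only CA=15 retained
        assert mae(pair, age_cap=18.0) == pytest.approx(1.5)

    def test_cap_18_equals_cap_16_when_all_young(self):
        pair = pair_from([5, 9, 14], [5.5, 9.5, 13.0])
        assert mae(pair, 18.0) == mae(pair, 16.0)

    def test_empty_after_filter_is_error(self):
        with pytest.raises(MetricError):
            mae(pair_from([17.0], [16.0]), age_cap=16.0)


class TestRegressionMetrics:
    def test_perfect_predictions(self):
        out = regression_metrics(pair_from([4, 8, 12], [4, 8, 12]))
        assert out == {"MSE": 0.0, "RMSE": 0.0, "MAE": 0.0, "R2": 1.0}

    def test_constant_unit_error(self):
        out = regression_metrics(pair_from([4, 8, 12, 16], [5, 9, 13, 17]))
        assert out["MSE"] == out["RMSE"] == out["MAE"] == 1.0

    def test_hand_computed_four_points(self):
        # AD = [1, -1, 2, 0]; MSE = 6/4; CA centered SS = 20
        out = regression_metrics(pair_from([2, 4, 6, 8], [3, 3, 8, 8]))
        assert out["MSE"] == pytest.approx(1.5)
        assert out["RMSE"] == pytest.approx(np.sqrt(1.5))
        assert out["MAE"] == pytest.approx(1.0)
        assert out["R2"] == pytest.approx(1 - 6 / 20)

    def test_zero_ca_variance_rejected(self):
        with pytest.raises(MetricError, match="variance"):
            regression_metrics(pair_from([5, 5], [4, 6]))

    @given(
        st.lists(
            st.tuples(
                st.floats(2, 17.99),
                st.floats(-3, 3),
            ),
            min_size=3,
            max_size=60,
        )
    )
    @settings(deadline=None, max_examples=200)
    def test_rmse_dominates_mae(self, pairs):
        ca = np.array([p[0] for p in pairs])
        da = ca + np.array([p[1] for p in pairs])
        if np.ptp(ca) == 0:
            return
        out = regression_metrics(pair_from(ca, da))
        assert out["RMSE"] >= out["MAE"] - 1e-12
        assert out["MSE"] == pytest.approx(out["RMSE"] ** 2, rel=1e-12)


class TestPairedT:
    def test_symmetric_deviations_give_t_zero(self):
        t, p = paired_t_test(pair_from([10, 10], [10.5, 9.5]))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_three_points(self):
        # AD = {1,2,3}: mean 2, sd 1, t = 2*sqrt(3)
        t, p = paired_t_test(pair_from([5, 5, 5], [6, 7, 8]))
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert p == pytest.approx(0.0742, abs=2e-4)

    def test_large_n_small_shift_significant(self, rng):
        ca = rng.uniform(2, 18, size=833)
        da = ca + rng.normal(0.3, 1.15, size=833)
        _, p = paired_t_test(pair_from(ca, da))
        assert p < 0.001

    def test_matches_reference_routine(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 40))
            ca = rng.uniform(2, 18, size=n)
            da = ca + rng.normal(0, 1, size=n)
            t, p = paired_t_test(pair_from(ca, da))
            ref = stats.ttest_rel(da, ca)
            assert t == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_degenerate_zero_variance(self):
        with pytest.raises(MetricError):
            paired_t_test(pair_from([3, 4], [4, 5]))

    def test_significance_tiers(self):
        assert significance_tier(0.0005) == "***"
        assert significance_tier(0.005) == "**"
        assert significance_tier(0.03) == "*"
        assert significance_tier(0.3) == "ns"


class TestKappa:
    def test_identical_sequences(self):
        assert cohens_kappa(list("AABBC"), list("AABBC")) == pytest.approx(1.0)

    def test_independent_ratings_near_zero(self, rng):
        a = rng.choice(list("ABCDEFGH"), size=10000)
        b = rng.choice(list("ABCDEFGH"), size=10000)
        assert abs(cohens_kappa(a.tolist(), b.tolist())) < 0.05

    def test_two_by_two_hand_value(self):
        a = ["X"] * 50 + ["Y"] * 50
        b = ["X"] * 45 + ["Y"] * 5 + ["X"] * 5 + ["Y"] * 45
        assert cohens_kappa(a, b) == pytest.approx(0.8)

    def test_matches_reference_implementation(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.choice(list("ABCD"), size=300).tolist()
        b = [x if rng.random() < 0.7 else rng.choice(list("ABCD")) for x in a]
        assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-10)

    def test_weighted_variant_matches_reference(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(1, 9, size=400).tolist()
        b = [x if rng.random() < 0.6 else int(rng.integers(1, 9)) for x in a]
        got = cohens_kappa(a, b, weighted=True)
        ref = cohen_kappa_score(a, b, weights="linear")
        assert got == pytest.approx(ref, abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(MetricError):
            cohens_kappa(["A"], ["A", "B"])


class TestPerGroupMAE:
    def test_single_bin_equals_global(self):
        pair = pair_from([5.1, 5.7], [5.6, 5.0])
        out = per_group_mae(pair)
        assert len(out) == 1
        (value,) = out.values()
        assert value == pytest.approx(mae(pair))

    def test_perfect_predictions_all_zero(self, small_cohort):
        ca = small_cohort.ages()
        pair = pair_from(ca, ca)
        assert all(v == 0.0 for v in per_group_mae(pair).values())

    def test_matches_brute_force_group_by(self, rng):
        ca = rng.uniform(2, 18, size=400)
        da = ca + rng.normal(0, 1, size=400)
        pair = pair_from(ca, da)
        out = per_group_mae(pair)
        for b in standard_bins():
            mask = (ca >= b.lower) & (ca < b.upper)
            if mask.any():
                assert out[b] == pytest.approx(np.abs(da[mask] - ca[mask]).mean())
            else:
                assert b not in out
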
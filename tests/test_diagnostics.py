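"""Diagnostics: z-transform, squeeze diagrams, the r·z(Y) prediction,
ordering of means, and the split-half retest check."""

import numpy as np
import pandas as pd
import pytest

from regmean import (
    BivariateSample,
    CANONICAL_SPEC,
    SKLAR_SPEC,
    galton_squeeze,
    linear_model_moments,
    ordering_check,
    regression_artifact_test,
    regression_expectation,
    retest_regression_test,
    selected_mean_expectation,
    simulate_linear_common_source,
    simulate_retest,
    split_half_reliability,
    standard_normal_band_mean,
    z_transform,
)


def make_sample(x, y, **extra):
    df = pd.DataFrame({"id": range(len(x)), "x": x, "y": y, **extra})
    return BivariateSample(df)


class TestZTransform:
    def test_standardizes_to_unit_moments(self, canonical_sample_200):
        z = z_transform(canonical_sample_200)
        assert z.x.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.x.std(ddof=1) == pytest.approx(1.0)
        assert z.y.std(ddof=1) == pytest.approx(1.0)

    def test_correlation_invariant(self, canonical_sample_200):
        before = np.corrcoef(canonical_sample_200.x, canonical_sample_200.y)[0, 1]
        z = z_transform(canonical_sample_200)
        after = np.corrcoef(z.x, z.y)[0, 1]
        assert after == pytest.approx(before, abs=1e-12)

    def test_three_point_toy(self):
        # n-1 denominator: SD of (1,2,3) is 1, so z = (-1, 0, 1)
        z = z_transform(make_sample([1.0, 2.0, 3.0], [3.0, 1.0, 2.0]))
        np.testing.assert_allclose(z.x, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="zero SD"):
            z_transform(make_sample([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestGaltonSqueeze:
    def test_canonical_quartiles(self, canonical_sample_200):
        """Partitioned on Y, the extreme quartiles sit near ±1.27 on z(Y)
        but only near ±r·1.27 on z(X) — the funnel."""
        d = galton_squeeze(canonical_sample_200, "y", 4)
        band_mean = standard_normal_band_mean(0.75, 1.0)
        r = linear_model_moments(CANONICAL_SPEC).r
        top_y, top_x = d.band(4)
        bot_y, bot_x = d.band(1)
        # sampling bands at n=200 (50 per quartile)
        assert top_y == pytest.approx(band_mean, abs=0.2)
        assert bot_y == pytest.approx(-band_mean, abs=0.2)
        assert top_x == pytest.approx(r * band_mean, abs=0.55)
        assert bot_x == pytest.approx(-r * band_mean, abs=0.55)
        assert abs(top_x) < abs(top_y) and abs(bot_x) < abs(bot_y)

    def test_band_sizes_sum_and_monotone_partition_means(self,
                                                         canonical_sample_200):
        d = galton_squeeze(canonical_sample_200, "y", 4)
        assert d.bands["n"].sum() == 200
        part = d.bands["mean_z_partition"].to_numpy()
        assert (np.diff(part) > 0).all()

    def test_no_squeeze_at_perfect_correlation(self):
        x = np.linspace(-2, 2, 40)
        d = galton_squeeze(make_sample(x, x.copy()), "y", 4)
        np.testing.assert_allclose(d.bands["mean_z_companion"],
                                   d.bands["mean_z_partition"], atol=1e-12)

    def test_bidirectional_mirror(self, canonical_sample_200):
        """Partitioning on X of the original equals partitioning on Y of
        the X<->Y-swapped sample."""
        d_x = galton_squeeze(canonical_sample_200, "x", 4)
        swapped = make_sample(canonical_sample_200.y, canonical_sample_200.x)
        d_y = galton_squeeze(swapped, "y", 4)
        pd.testing.assert_frame_equal(d_x.bands, d_y.bands)

    def test_squeeze_inequality_large_sample(self, canonical_sample_large):
        d = galton_squeeze(canonical_sample_large, "y", 4)
        for band in range(1, 5):
            p, c = d.band(band)
            assert abs(c) <= abs(p)


class TestRegressionExpectation:
    @pytest.mark.parametrize("r,zy,expected", [
        (0.28, -1.3, -0.364),     # canonical bottom quartile
        (0.10, -1.04, -0.104),    # contextual-cuing reanalysis
        (0.198, -0.785, -0.155),  # CFS-arithmetic reanalysis
        (0.0, -3.0, 0.0),         # complete regression at r = 0
    ])
    def test_worked_examples(self, r, zy, expected):
        assert regression_expectation(r, zy) == pytest.approx(expected,
                                                              abs=5e-4)

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            regression_expectation(1.5, -1.0)


class TestRegressionArtifactTest:
    def test_prediction_equals_r_times_zy(self, canonical_sample_200):
        diag = regression_artifact_test(canonical_sample_200, 0.0)
        assert diag.predicted_zX == pytest.approx(
            regression_expectation(diag.r, diag.mean_zY_selected))

    def test_null_model_verdict_usually_consistent(self):
        """Across seeded replicates of a no-true-effect model, the
        exceeds-regression verdict rate stays near CI miscoverage."""
        verdicts = [
            regression_artifact_test(
                simulate_linear_common_source(SKLAR_SPEC, 200, seed=s),
                0.1).verdict
            for s in range(300)
        ]
        exceed = sum(v == "exceeds-regression" for v in verdicts) / len(verdicts)
        assert exceed <= 0.07

    def test_uncorrelated_random_subsample_consistent(self):
        rng = np.random.default_rng(21)
        sample = make_sample(rng.normal(size=500), rng.normal(size=500))
        diag = regression_artifact_test(sample, 0.0)
        assert abs(diag.predicted_zX) < 0.3
        assert diag.verdict == "consistent-with-regression"

    def test_empty_subgroup_raises(self, canonical_sample_200):
        with pytest.raises(ValueError, match="empty"):
            regression_artifact_test(canonical_sample_200, -1e9)


class TestOrderingCheck:
    def test_perfectly_correlated_data_ordered(self):
        x = np.linspace(-2, 2, 30)
        rep = ordering_check(make_sample(x, x.copy()), 0.0)
        assert rep.consistent

    def test_large_canonical_simulation_ordered(self, canonical_sample_large):
        rep = ordering_check(canonical_sample_large, 0.0)
        assert rep.consistent
        assert rep.zX_above > rep.zX_all > rep.zX_below

    def test_violation_is_reported(self):
        """An 'unaware' subgroup whose performance exceeds the group mean
        violates the ordering and must be flagged, not masked."""
        # overall r > 0, but the below-cutoff records carry above-average x
        sample = make_sample([3.0, 3.5, 1.0, 2.0, 3.0, 4.0],
                             [-1.0, -0.5, 0.5, 1.0, 1.5, 2.0])
        rep = ordering_check(sample, 0.0)
        assert rep.r > 0
        assert not rep.consistent
        assert rep.zX_below > rep.zX_all

    def test_mirrored_under_exchange(self, canonical_sample_large):
        """Regression is bidirectional: cutting on X and asking about Y
        obeys the same ordering as cutting on Y and asking about X."""
        rep = ordering_check(canonical_sample_large, 0.0)
        swapped = make_sample(canonical_sample_large.y,
                              canonical_sample_large.x)
        rep_sw = ordering_check(swapped, 100.0)  # cutoff on the X scale
        assert rep.consistent and rep_sw.consistent
        assert rep.r == pytest.approx(rep_sw.r)


class TestRetestRegression:
    def test_identical_halves_all_tied(self):
        s = make_sample([1.0, 2.0, 3.0, 4.0], [0.1, 0.2, 0.3, 0.4],
                        y1=[0.1, 0.2, 0.3, 0.4], y2=[0.1, 0.2, 0.3, 0.4])
        rep = retest_regression_test(s, 0.25)
        assert rep.mean_change == 0.0
        assert rep.n_tied == rep.n_selected
        assert rep.n_improved == rep.n_worsened == 0

    def test_low_selected_subgroup_improves_by_shrinkage(self):
        """Mean Test-2 change of the selected subgroup matches the
        truncated-normal + reliability shrinkage closed form."""
        s = simulate_retest(CANONICAL_SPEC, 10_000, seed=22)
        rep = retest_regression_test(s, 0.0)
        m = linear_model_moments(CANONICAL_SPEC)
        sel = selected_mean_expectation(m, 0.0)
        expected_change = (m.reliability_Y - 1) * (sel.mean_Y_selected
                                                   - m.mean_Y)
        assert rep.mean_change > 0
        assert rep.mean_change == pytest.approx(expected_change, abs=0.06)
        assert rep.n_improved > rep.n_worsened

    def test_high_selected_subgroup_drops(self):
        s = simulate_retest(CANONICAL_SPEC, 5_000, seed=23)
        rep = retest_regression_test(s, 1.0, direction="above")
        assert rep.mean_change < 0

    def test_mirrored_selection_on_second_half(self):
        s = simulate_retest(CANONICAL_SPEC, 10_000, seed=24)
        rep1 = retest_regression_test(s, 0.0, select_on="y1")
        rep2 = retest_regression_test(s, 0.0, select_on="y2")
        assert rep2.mean_change > 0
        assert rep2.mean_change == pytest.approx(rep1.mean_change, abs=0.1)

    def test_counts_partition_subgroup(self):
        s = simulate_retest(CANONICAL_SPEC, 500, seed=25)
        rep = retest_regression_test(s, 0.0)
        assert rep.n_improved + rep.n_worsened + rep.n_tied == rep.n_selected

    def test_missing_halves_rejected(self):
        s = make_sample([1.0, 2.0, 3.0], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="y1/y2"):
            retest_regression_test(s, 0.2)


class TestSplitHalfReliability:
    def test_identical_halves(self):
        assert split_half_reliability([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_reversed_halves(self):
        assert split_half_reliability([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_sklar_model_reliability(self):
        s = simulate_retest(SKLAR_SPEC, 1_000_000, seed=26)
        rel = split_half_reliability(s.column("y1"), s.column("y2"))
        assert rel == pytest.approx(0.6923, abs=0.005)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            split_half_reliability([1, 2, 3], [1, 2])
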
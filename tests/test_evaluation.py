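import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from fcdlif import (
    BloodCurve,
    DynamicPETImage,
    canonical_schedule,
    compare_curves,
    compare_dataset,
    deming_regression,
    predict_aif,
    rank_samples,
    shift_test,
    truncate_test,
    tsne_features,
)


def _curve(values, schedule):
    return BloodCurve(schedule.midpoints, np.asarray(values, float))


class TestCompareCurves:
    def test_identical_nonconstant_curves(self, schedule):
        c = _curve(np.linspace(5, 0.1, 42), schedule)
        result = compare_curves(c, c, schedule)
        assert result.mse == 0.0
        assert result.pearson_r == pytest.approx(1.0)
        assert result.deming_slope == pytest.approx(1.0)
        assert result.deming_intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_curves_flag_undefined_correlation(self, schedule):
        c = _curve(np.full(42, 2.0), schedule)
        result = compare_curves(c, c, schedule)
        assert np.isnan(result.pearson_r)

    def test_constant_offset(self, schedule):
        m = _curve(np.linspace(5, 0.1, 42), schedule)
        p = _curve(m.values + 1.0, schedule)
        result = compare_curves(p, m, schedule)
        assert result.mse == pytest.approx(1.0)
        assert result.pearson_r == pytest.approx(1.0)

    def test_hand_worked_mse(self):
        t = np.arange(1.0, 6.0)
        p = BloodCurve(t, np.array([1.0, 2.0, 4.0, 2.0, 1.0]))
        m = BloodCurve(t, np.array([1.5, 2.0, 3.0, 2.5, 0.0]))
        # diffs: -0.5, 0, 1, -0.5, 1 -> (0.25 + 0 + 1 + 0.25 + 1)/5 = 0.5
        assert compare_curves(p, m).mse == pytest.approx(0.5)

    def test_grid_mismatch_rejected(self, schedule):
        a = _curve(np.zeros(42), schedule)
        b = BloodCurve(np.arange(42.0) + 0.5, np.zeros(42))
        with pytest.raises(ValueError, match="grid"):
            compare_curves(a, b)

    def test_segments_partition_canonical_frames(self, schedule):
        c = _curve(np.linspace(5, 0.1, 42), schedule)
        segs = compare_curves(c, c, schedule).segments
        assert (segs == "peak").sum() == 25
        assert (segs == "intermediate").sum() == 9
        assert (segs == "tail").sum() == 8


class TestDemingRegression:
    def test_collinear_points(self):
        x = np.linspace(0, 10, 20)
        slope, intercept = deming_regression(x, 2 * x)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_swap_symmetry_gives_reciprocal_slope(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = 1.7 * x + rng.normal(scale=0.3, size=50)
        s_xy, _ = deming_regression(x, y)
        s_yx, _ = deming_regression(y, x)
        assert s_xy == pytest.approx(1.0 / s_yx)

    def test_symmetric_spread_around_identity(self):
        # a point set invariant under reflection about y = x: for each base
        # point both (x, x+d) and (x+d, x) are included, so the orthogonal
        # fit must coincide with the identity line
        base = np.linspace(0, 10, 25)
        x = np.concatenate([base, base + 0.7])
        y = np.concatenate([base + 0.7, base])
        slope, intercept = deming_regression(x, y)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_large_variance_ratio_approaches_ols(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        y = 0.8 * x + rng.normal(scale=0.5, size=100)
        ols = np.polyfit(x, y, 1)[0]
        slope, _ = deming_regression(x, y, variance_ratio=1e9)
        assert slope == pytest.approx(ols, rel=1e-3)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            deming_regression(np.ones(5), np.ones(5))


class TestRankSamples:
    def _cmp(self, mse):
        from fcdlif.evaluation import CurveComparison

        return CurveComparison(mse, np.zeros(1), 1.0, 1.0, 1.0, 0.0, np.array(["peak"]))

    def test_basic_ordering(self):
        best, median, worst = rank_samples([self._cmp(m) for m in (3.0, 1.0, 2.0)])
        assert (best, median, worst) == (1, 2, 0)

    def test_single_sample(self):
        assert rank_samples([self._cmp(4.0)]) == (0, 0, 0)

    def test_ties_broken_by_lower_index(self):
        best, median, worst = rank_samples([self._cmp(m) for m in (1.0, 1.0, 1.0)])
        assert (best, median, worst) == (0, 1, 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_samples([])


class TestDatasetComparison:
    def test_ttest_and_qq_outputs(self, schedule):
        rng = np.random.default_rng(0)
        measured = [_curve(np.linspace(5, 0.1, 42), schedule) for _ in range(8)]
        predicted = [
            _curve(m.values + rng.normal(0, 0.05, 42), schedule) for m in measured
        ]
        result = compare_dataset(predicted, measured, schedule)
        assert result["p_values"].shape == (42,)
        assert 0.9 < result["pearson_r"] <= 1.0
        qq = result["qq_pairs"]
        assert np.all(np.diff(qq[:, 0]) >= 0) and np.all(np.diff(qq[:, 1]) >= 0)

    def test_biased_predictions_flagged_significant(self, schedule):
        rng = np.random.default_rng(1)
        measured = [_curve(np.linspace(5, 0.1, 42), schedule) for _ in range(10)]
        predicted = [
            _curve(m.values + 0.5 + rng.normal(0, 0.01, 42), schedule) for m in measured
        ]
        result = compare_dataset(predicted, measured, schedule)
        assert len(result["significant_frames"]) == 42


class TestShiftAndTruncate:
    @pytest.mark.parametrize("mode", ["empty", "copy"])
    def test_shift_extends_output_by_one(self, reduced_network, noiseless_phantom, mode):
        image, _, _ = noiseless_phantom
        original, shifted, score = shift_test(reduced_network, image, mode=mode)
        assert len(original) == 42
        assert len(shifted) == 43
        assert score >= 0

    @pytest.mark.parametrize("mode", ["empty", "copy"])
    def test_interior_shift_covariance(self, reduced_network, noiseless_phantom, mode):
        # same-padded temporal convolutions commute with time shifts away
        # from the sequence boundaries (within the TFE receptive radius)
        image, _, _ = noiseless_phantom
        original, shifted, _ = shift_test(reduced_network, image, mode=mode)
        r = reduced_network.config.tfe_receptive_radius
        interior_orig = original.values[r:-r]
        interior_shift = shifted.values[1 + r : -r]
        np.testing.assert_allclose(interior_shift, interior_orig, rtol=1e-4, atol=1e-4)

    def test_invalid_mode_rejected(self, reduced_network, noiseless_phantom):
        with pytest.raises(ValueError, match="mode"):
            shift_test(reduced_network, noiseless_phantom[0], mode="noise")

    def test_truncation_lengths_and_schedule(self, reduced_network, noiseless_phantom):
        image, _, _ = noiseless_phantom
        curve = truncate_test(reduced_network, image)
        assert len(curve) == 32  # 42 - 4 - 6
        removed_tail = image.schedule.durations[-6:].sum()
        assert removed_tail == 1800.0  # the discarded tail spans 30 min
        # schedule re-anchored: first retained frame starts at 0
        kept = image.schedule.subset(slice(4, 36))
        np.testing.assert_allclose(curve.times, kept.midpoints)

    def test_too_few_frames_rejected(self, reduced_network):
        from fcdlif import build_schedule

        image = DynamicPETImage(
            np.zeros((8, 32, 16, 16), np.float32), build_schedule([8], [30])
        )
        with pytest.raises(ValueError, match="frames"):
            truncate_test(reduced_network, image)


class TestTsneFeatures:
    def test_embedding_shape_and_determinism(self, schedule):
        rng = np.random.default_rng(0)
        mats = [rng.normal(size=(42, 32)) for _ in range(2)]
        df1 = tsne_features(mats, ["a", "b"], seed=3, schedule=schedule)
        df2 = tsne_features(mats, ["a", "b"], seed=3, schedule=schedule)
        assert df1.shape[0] == 84
        np.testing.assert_array_equal(df1[["x", "y"]].values, df2[["x", "y"]].values)
        assert set(df1["segment"]) == {"peak", "intermediate", "tail"}

    def test_separated_clusters_stay_separated(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.05, size=(30, 32))
        b = rng.normal(0, 0.05, size=(30, 32)) + 5.0
        df = tsne_features([a, b], ["a", "b"], seed=0)
        labels = (df["group"] == "b").astype(int)
        assert silhouette_score(df[["x", "y"]].values, labels) > 0.5

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="5"):
            tsne_features([np.zeros((2, 32))], ["a"], seed=0)
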
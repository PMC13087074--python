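import numpy as np
import pytest

from fcdlif import (
    AIFParams,
    KineticParams,
    aif_model,
    build_schedule,
    canonical_schedule,
    default_phantom_spec,
    frame_average,
    generate_phantom,
    sample_dataset,
    simulate_2tcm,
)
from fcdlif.phantom import Ellipsoid, Organ, PhantomSpec


class TestAifModel:
    def test_zero_at_arrival(self):
        p = AIFParams()
        assert aif_model(p, p.t0) == pytest.approx(0.0)
        assert aif_model(p, 0.0) == 0.0

    def test_zero_amplitudes_give_zero_curve(self):
        p = AIFParams(A1=0.0, A2=0.0, A3=0.0)
        t = np.linspace(0, 2730, 500)
        assert np.all(aif_model(p, t) == 0.0)

    def test_default_curve_nonnegative_single_peak(self):
        # dense-grid oracle: non-negative everywhere, exactly one interior maximum
        t = np.linspace(0.0, 2730.0, 200_001)
        c = aif_model(AIFParams(), t)
        assert np.all(c >= 0)
        d = np.diff(c)
        sign_changes = np.sum(np.diff(np.sign(d[d != 0])) != 0)
        assert sign_changes == 1
        assert 0 < t[np.argmax(c)] < 2730

    def test_invalid_rate_ordering_rejected(self):
        with pytest.raises(ValueError):
            AIFParams(l1=0.01, l2=0.05, l3=1e-4)


class TestSimulate2TCM:
    def test_no_influx_means_zero_tissue(self):
        p = KineticParams(K1=0.0, k2=0.3, k3=0.1, vB=0.0)
        t = np.linspace(1, 2000, 100)
        assert np.all(simulate_2tcm(p, lambda t: np.full_like(np.asarray(t, float), 2.0), t) == 0)

    def test_closed_form_single_compartment(self):
        # constant plasma, k3 = 0: C1(t) = (K1 c / k2)(1 - exp(-k2 t)), rates per min
        K1, k2, c = 0.4, 0.6, 2.0
        p = KineticParams(K1=K1, k2=k2, k3=0.0, vB=0.0)
        t = np.linspace(30, 3000, 50)
        model = simulate_2tcm(p, lambda t: np.full_like(np.asarray(t, float), c), t)
        expected = (K1 * c / k2) * (1 - np.exp(-(k2 / 60.0) * t))
        np.testing.assert_allclose(model, expected, rtol=1e-6)

    def test_late_slope_equals_net_influx_rate(self):
        # Ki = K1 k3/(k2+k3) = 0.125/min for K1=0.5, k2=0.3, k3=0.1
        c = 3.0
        p = KineticParams(K1=0.5, k2=0.3, k3=0.1, vB=0.0)
        t = np.linspace(0, 36000, 721)  # long horizon so the transient has died
        model = simulate_2tcm(p, lambda t: np.full_like(np.asarray(t, float), c), t)
        late = t > 18000
        slope_per_min = np.polyfit(t[late] / 60.0, model[late], 1)[0]
        assert slope_per_min == pytest.approx(0.125 * c, rel=1e-3)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(K1=0.5, k2=-0.3, k3=0.1)


class TestFrameAverage:
    def test_constant_function(self, schedule):
        curve = frame_average(lambda t: np.full_like(np.asarray(t, float), 4.2), schedule)
        np.testing.assert_allclose(curve.values, 4.2)
        np.testing.assert_allclose(curve.times, schedule.midpoints)

    def test_linear_function_hits_midpoints(self, schedule):
        curve = frame_average(lambda t: np.asarray(t, float), schedule)
        np.testing.assert_allclose(curve.values, schedule.midpoints, rtol=1e-12)

    def test_against_dense_trapezoid_oracle(self, schedule):
        f = lambda t: aif_model(AIFParams(), t)
        curve = frame_average(f, schedule)
        for i, (s, d) in enumerate(zip(schedule.starts, schedule.durations)):
            ts = np.linspace(s, s + d, 10_000)
            oracle = np.trapezoid(f(ts), ts) / d
            assert curve.values[i] == pytest.approx(oracle, rel=1e-3)


class TestGeneratePhantom:
    def test_deterministic_per_seed(self):
        spec = default_phantom_spec(noise_scale=2.0)
        a, aif_a, _ = generate_phantom(spec, seed=7)
        b, aif_b, _ = generate_phantom(spec, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(aif_a.values, aif_b.values)

    def test_noiseless_blood_pool_equals_ground_truth(self, noiseless_phantom):
        image, aif, masks = noiseless_phantom
        pool = masks["labels"] == [k for k, v in masks["names"].items() if v == "blood_pool"][0]
        assert pool.sum() > 0
        pool_mean = image.values[:, pool].mean(axis=1, dtype=np.float64)
        np.testing.assert_allclose(pool_mean, aif.values, rtol=1e-6)

    def test_noiseless_values_nonnegative_finite(self, noiseless_phantom):
        image, _, _ = noiseless_phantom
        assert np.all(np.isfinite(image.values))
        assert np.all(image.values >= 0)

    def test_empty_spec_gives_zero_image(self):
        spec = PhantomSpec(
            grid_shape=(8, 8, 8),
            blood_pool=Ellipsoid(center=(4, 4, 4), axes=(1.5, 1.5, 1.5)),
            organs=(),
            background=None,
            aif=AIFParams(A1=0.0, A2=0.0, A3=0.0),
        )
        image, aif, _ = generate_phantom(spec, seed=0)
        assert np.all(image.values == 0)
        assert np.all(aif.values == 0)

    def test_overlapping_regions_warn_last_writer_wins(self):
        ell = Ellipsoid(center=(4, 4, 4), axes=(2, 2, 2))
        spec = PhantomSpec(
            grid_shape=(8, 8, 8),
            blood_pool=ell,
            organs=(Organ("o1", ell, KineticParams(K1=0.3, k2=0.5, k3=0.05)),),
            background=None,
        )
        with pytest.warns(UserWarning, match="overlap"):
            image, aif, masks = generate_phantom(spec, seed=0)
        # blood pool painted last: the shared voxels carry the AIF
        pool = masks["labels"] == 2
        np.testing.assert_allclose(
            image.values[:, pool].mean(axis=1, dtype=np.float64), aif.values, rtol=1e-6
        )

    def test_noise_preserves_expectation_within_3se(self):
        # uniform region: mean over voxels of one noisy frame ~ truth +/- 3 SE,
        # with per-voxel variance value/(duration * scale)
        spec = default_phantom_spec(noise_scale=50.0)
        image, aif, masks = generate_phantom(spec, seed=5)
        pool = masks["labels"] == [k for k, v in masks["names"].items() if v == "blood_pool"][0]
        n = pool.sum()
        for frame in (1, 30, 41):
            truth = aif.values[frame]
            if truth <= 0:
                continue
            se = np.sqrt(truth / (spec.schedule.durations[frame] * 50.0 * n))
            observed = image.values[frame, pool].mean(dtype=np.float64)
            assert abs(observed - truth) < 3 * se + 1e-12

    def test_longer_frames_are_smoother(self):
        # coefficient of variation in a uniform region falls with duration
        spec = default_phantom_spec(noise_scale=20.0)
        image, aif, masks = generate_phantom(spec, seed=9)
        pool = masks["labels"] == [k for k, v in masks["names"].items() if v == "blood_pool"][0]
        short = 30   # a 20-s frame in the washout
        long = 41    # a 300-s frame with comparable concentration
        cv = lambda f: image.values[f, pool].std(dtype=np.float64) / aif.values[f]
        # normalize out the concentration difference: CV scales as 1/sqrt(value*duration)
        expected_ratio = np.sqrt(
            (aif.values[long] * spec.schedule.durations[long])
            / (aif.values[short] * spec.schedule.durations[short])
        )
        assert cv(short) > cv(long)
        assert cv(short) / cv(long) == pytest.approx(expected_ratio, rel=0.5)


def test_sample_dataset_varies_and_is_deterministic():
    ds1 = sample_dataset(3, seed=4)
    ds2 = sample_dataset(3, seed=4)
    for (im1, c1), (im2, c2) in zip(ds1, ds2):
        np.testing.assert_array_equal(im1.values, im2.values)
        np.testing.assert_array_equal(c1.values, c2.values)
    peaks = [c.values.max() for _, c in ds1]
    assert len(set(np.round(peaks, 6))) == 3  # physiology actually varies
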
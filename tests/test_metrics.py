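"""Dyssynchrony metric correctness against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dyssync.curves import MeasurementKind, SegmentId, DeformationCurve
from dyssync.errors import (
    CurveDataError,
    DegenerateCurveError,
    InsufficientDataError,
)
from dyssync.metrics import (
    FEATURE_COLUMNS,
    base_to_apex_delay,
    ccd_global,
    ccd_segment,
    compute_features,
    global_strain,
    interpolate_1ms,
    max_opposing_wall_delay,
    sdttp,
    time_to_peak,
)
from dyssync.validation import ccd_oracle_scan, random_periodic_curve

from conftest import cosine_bump, make_ventricle


def _curve(samples, hr=100.0, kind=MeasurementKind.CIRC_STRAIN):
    return DeformationCurve(kind, SegmentId(0, 1), np.asarray(samples, float),
                            60000.0 / hr)


class TestInterpolation:
    def test_point_count_and_sample_agreement(self):
        samples = cosine_bump(amplitude=-15.0)
        interp = interpolate_1ms(samples, 600.0)
        assert interp.shape == (600,)
        # exact agreement at native sample times (multiples of 20 ms)
        np.testing.assert_allclose(interp[::20], samples, rtol=0, atol=0)

    def test_constant_curve_stays_constant(self):
        interp = interpolate_1ms(np.full(30, 3.7), 732.0)
        np.testing.assert_allclose(interp, 3.7)

    def test_linear_segment_midpoint_is_mean_of_endpoints(self):
        samples = np.zeros(30)
        samples[10], samples[11] = 2.0, 6.0
        interp = interpolate_1ms(samples, 600.0)
        assert interp[210] == pytest.approx(4.0)  # midpoint of [200, 220] ms

    def test_periodic_wrap_between_last_and_first_sample(self):
        samples = np.zeros(30)
        samples[0], samples[29] = 4.0, 2.0
        interp = interpolate_1ms(samples, 600.0)
        # t=590 is halfway from sample 29 (t=580) to sample 0 of the next cycle
        assert interp[590] == pytest.approx(3.0)

    def test_non_finite_sample_rejected(self):
        samples = np.zeros(30)
        samples[5] = np.nan
        with pytest.raises(CurveDataError):
            interpolate_1ms(samples, 600.0)


class TestTimeToPeak:
    def test_raised_cosine_peak_at_sample_10(self):
        t = np.arange(30)
        samples = -np.cos(np.pi * (t - 10) / 30.0) ** 2  # min exactly at sample 10
        assert time_to_peak(_curve(samples)) == pytest.approx(200.0, abs=1e-9)

    @pytest.mark.parametrize("delta", [50.0, -50.0, 37.0])
    def test_circular_shift_moves_peak_by_shift(self, delta):
        base = cosine_bump(amplitude=-15.0)
        L = 600.0
        t = np.arange(30) * 20.0
        u = ((t - delta) / L - 0.15) % 1.0
        shifted = -15.0 * np.where(u < 0.7, 0.5 * (1 - np.cos(2 * np.pi * u / 0.7)), 0.0)
        d = (time_to_peak(_curve(shifted)) - time_to_peak(_curve(base))) % L
        assert min(d, L - d) == pytest.approx(abs(delta), abs=1.0)

    def test_equal_extrema_tie_breaks_to_earliest(self):
        samples = np.zeros(30)
        samples[7] = samples[17] = -5.0  # symmetric spikes at 140 and 340 ms
        samples[6] = samples[8] = samples[16] = samples[18] = -2.0
        assert time_to_peak(_curve(samples)) == pytest.approx(140.0)

    def test_polarity_picks_maximum_for_radial(self):
        samples = cosine_bump(amplitude=15.0)
        tt = time_to_peak(_curve(samples, kind=MeasurementKind.RAD_STRAIN))
        assert tt == pytest.approx(0.5 * 600.0, abs=1.0)

    def test_flat_curve_is_degenerate(self):
        with pytest.raises(DegenerateCurveError):
            time_to_peak(_curve(np.full(30, 1.0)))


class TestDispersionMetrics:
    def test_sdttp_hand_example(self):
        assert sdttp([100.0, 120.0, 140.0]) == pytest.approx(20.0)

    def test_sdttp_zero_for_synchrony(self):
        assert sdttp([88.0] * 42) == 0.0

    def test_sdttp_requires_two_segments(self):
        with pytest.raises(InsufficientDataError):
            sdttp([100.0])

    def test_sdttp_estimates_planted_dispersion(self):
        rng = np.random.default_rng(7)
        estimates = [sdttp(rng.normal(300.0, 30.0, size=42)) for _ in range(500)]
        assert np.mean(estimates) == pytest.approx(30.0, rel=0.02)

    def test_mowd_hand_example(self):
        ttps = np.tile([100.0, 110.0, 105.0, 150.0, 120.0, 115.0], (4, 1))
        assert max_opposing_wall_delay(ttps) == pytest.approx(50.0)

    def test_mowd_shift_invariant_and_zero_when_synchronous(self):
        ttps = np.tile([100.0, 110.0, 105.0, 150.0, 120.0, 115.0], (4, 1))
        assert max_opposing_wall_delay(ttps + 77.0) == pytest.approx(
            max_opposing_wall_delay(ttps))
        assert max_opposing_wall_delay(np.full((4, 6), 200.0)) == 0.0

    def test_bad_uses_only_end_slices(self):
        grid = np.vstack([
            np.full(6, 100.0),  # apical
            np.full(6, 999.0),  # middle slices must not matter
            np.full(6, -50.0),
            np.full(6, 130.0),  # basal
        ])
        assert base_to_apex_delay(grid) == pytest.approx(30.0)

    def test_bad_requires_two_slices(self):
        with pytest.raises(InsufficientDataError):
            base_to_apex_delay(np.full((1, 6), 10.0))


class TestCCD:
    def test_identical_curves_give_zero_delay(self):
        x = interpolate_1ms(cosine_bump(amplitude=-15.0), 600.0)
        assert ccd_segment(x, x) == 0.0

    @pytest.mark.parametrize("delta", [37, -37])
    def test_planted_shift_recovered_and_absolute(self, delta):
        rng = np.random.default_rng(3)
        r = random_periodic_curve(700, rng)
        x = np.roll(r, delta)  # x(t) = r(t - delta)
        assert ccd_segment(x, r) == abs(delta)
        assert ccd_oracle_scan(x, r) == abs(delta)

    def test_matches_exhaustive_scan_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            L = int(rng.integers(500, 1200))
            x = random_periodic_curve(L, rng)
            r = random_periodic_curve(L, rng)
            assert ccd_segment(x, r) == ccd_oracle_scan(x, r)

    def test_tie_breaks_smallest_magnitude_then_negative(self):
        L = 600
        t = np.arange(L)
        r = np.cos(2 * np.pi * t / L * 2)  # period L/2: shifts 0 and +/-300...
        x = np.roll(r, 150)  # correlation equal at -150 and +150
        assert ccd_segment(x, r, signed=True) == -150.0

    def test_flat_curve_rejected(self):
        x = interpolate_1ms(cosine_bump(), 600.0)
        with pytest.raises(DegenerateCurveError):
            ccd_segment(np.zeros(600), x)

    def test_ccd_global_order_statistics(self):
        assert ccd_global([40.0] * 7) == 40.0
        vals = np.arange(0.0, 101.0, 10.0)  # n = 11
        assert ccd_global(vals) == pytest.approx(80.0)
        with pytest.raises(InsufficientDataError):
            ccd_global([1.0, 2.0, 3.0, 4.0])

    @given(st.lists(st.floats(0, 500), min_size=5, max_size=60))
    def test_ccd_global_bounded_by_input_range(self, vals):
        assert min(vals) - 1e-9 <= ccd_global(vals) <= max(vals) + 1e-9


class TestGlobalStrain:
    def test_identical_segments_preserve_peak(self, uniform_ventricle):
        assert global_strain(uniform_ventricle, MeasurementKind.CIRC_STRAIN) == \
            pytest.approx(-15.0, abs=0.01)
        assert global_strain(uniform_ventricle, MeasurementKind.RAD_STRAIN) > 0

    def test_mean_is_linear_in_amplitudes(self):
        ds = make_ventricle(n_slices=4)
        cs = ds.values[MeasurementKind.CIRC_STRAIN]
        half = cs.copy()
        half[: 2] = cs[: 2] / 15.0 * 10.0  # peaks -10
        half[2:] = cs[2:] / 15.0 * 20.0  # peaks -20
        ds.values[MeasurementKind.CIRC_STRAIN] = half
        assert global_strain(ds, MeasurementKind.CIRC_STRAIN) == pytest.approx(-15.0, abs=0.01)


class TestComputeFeatures:
    def test_feature_vector_has_24_delay_metrics(self, uniform_ventricle):
        feats = compute_features(uniform_ventricle)
        assert len(FEATURE_COLUMNS) == 24
        assert set(feats.metrics) == set(FEATURE_COLUMNS)
        d = feats.to_dict()
        assert len(d) == 26 and "gcs" in d and "grs" in d

    def test_synchronous_ventricle_has_zero_dyssynchrony(self, uniform_ventricle):
        feats = compute_features(uniform_ventricle)
        for col in FEATURE_COLUMNS:
            assert feats.metrics[col] == pytest.approx(0.0, abs=1e-6), col

    def test_planted_wall_shift_recovered(self):
        shifts = np.tile([0.0, 0.0, 0.0, 60.0, 60.0, 60.0], (7, 1))
        ds = make_ventricle(n_slices=7, heart_rate_bpm=82.0, shifts_ms=shifts)
        assert ds.n_segments == 42
        feats = compute_features(ds)
        for kind_ab in ("cs", "rs", "rd"):
            assert feats.metrics[f"mowd_{kind_ab}"] == pytest.approx(60.0, abs=1.0)
            assert feats.metrics[f"bad_{kind_ab}"] == pytest.approx(0.0, abs=1.0)
        # Against the pooled (bimodal) average curve, the optimal alignment of
        # either half sits near delta/2 for smooth templates; assert agreement
        # with the exhaustive-scan oracle rather than a nominal 60 ms.
        from dyssync.metrics import _interp_matrix, _ccd_shifts

        interp = _interp_matrix(ds.segment_matrix(MeasurementKind.CIRC_STRAIN),
                                ds.cycle_length_ms)
        ref = interp.mean(axis=0)
        oracle = np.array([ccd_oracle_scan(row, ref) for row in interp])
        assert feats.metrics["ccd_cs"] == pytest.approx(
            float(np.percentile(oracle, 80)), abs=1e-9)
        assert feats.metrics["ccd_cs"] == pytest.approx(30.0, abs=2.0)

    def test_translation_and_scale_invariance(self):
        rng = np.random.default_rng(5)
        shifts = rng.normal(0.0, 40.0, size=(4, 6))
        ds = make_ventricle(n_slices=4, heart_rate_bpm=75.0, shifts_ms=shifts)
        base = compute_features(ds).to_dict()
        ds2 = make_ventricle(n_slices=4, heart_rate_bpm=75.0, shifts_ms=shifts)
        for kind in ds2.values:
            ds2.values[kind] = ds2.values[kind] * 2.5 + 7.0
        transformed = compute_features(ds2).to_dict()
        for col in FEATURE_COLUMNS:
            assert transformed[col] == pytest.approx(base[col], abs=1e-6), col

    def test_all_features_finite_and_within_cycle(self):
        rng = np.random.default_rng(9)
        shifts = rng.normal(0.0, 80.0, size=(5, 6))
        ds = make_ventricle(n_slices=5, heart_rate_bpm=66.0, shifts_ms=shifts)
        feats = compute_features(ds)
        for col in FEATURE_COLUMNS:
            v = feats.metrics[col]
            assert np.isfinite(v) and 0.0 <= v < ds.cycle_length_ms

    def test_sdttp_monotone_in_planted_dispersion(self):
        means = []
        for sd in (10.0, 40.0, 90.0):
            vals = []
            for rep in range(8):
                rng = np.random.default_rng(100 * rep + int(sd))
                shifts = rng.normal(0.0, sd, size=(7, 6))
                ds = make_ventricle(n_slices=7, heart_rate_bpm=80.0, shifts_ms=shifts)
                vals.append(compute_features(ds).metrics["sdttp_cs"])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
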
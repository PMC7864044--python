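"""Densitometry: lane extraction, baseline correction, areas, calibration."""

import math

import numpy as np
import pytest

from hemestar import densitometry as dens

SQRT_2PI = math.sqrt(2 * math.pi)


def profile_from(values, lane_id="lane"):
    return dens.LaneProfile(np.arange(len(values), dtype=float), np.asarray(values, float),
                            lane_id=lane_id)


def gaussian_profile(n=120, center=60.0, sigma=5.0, amp=1.0, ramp=0.0, offset=0.0):
    x = np.arange(n, dtype=float)
    y = amp * np.exp(-((x - center) ** 2) / (2 * sigma**2)) + ramp * x + offset
    return dens.LaneProfile(x, y)


WINDOW = dens.BandWindow(start=35.0, end=85.0, flank_width=5)


class TestExtractLaneProfiles:
    def test_uniform_image_gives_flat_profiles(self):
        img = np.full((50, 40), 0.7)
        rects = [dens.LaneRect(0, 5, 50, 10), dens.LaneRect(0, 25, 50, 10)]
        for p in dens.extract_lane_profiles(img, rects):
            np.testing.assert_allclose(p.intensities, 0.0)

    def test_identical_lanes_give_identical_profiles(self):
        rng = np.random.default_rng(1)
        lane = rng.uniform(0, 1, size=(60, 8))
        img = np.ones((60, 30))
        img[:, 2:10] = lane
        img[:, 15:23] = lane
        p1, p2 = dens.extract_lane_profiles(
            img, [dens.LaneRect(0, 2, 60, 8), dens.LaneRect(0, 15, 60, 8)]
        )
        np.testing.assert_array_equal(p1.intensities, p2.intensities)

    def test_dark_band_maps_to_positive_peak_at_its_row(self):
        img = np.full((80, 20), 0.9)
        rows = np.arange(80.0)
        img[:, 3:11] -= 0.5 * np.exp(-((rows - 33.0) ** 2) / (2 * 9.0))[:, None]
        (p,) = dens.extract_lane_profiles(img, [dens.LaneRect(0, 3, 80, 8)])
        assert abs(p.positions[np.argmax(p.intensities)] - 33.0) <= 1.0

    def test_unequal_rectangles_rejected(self):
        img = np.ones((50, 40))
        with pytest.raises(ValueError, match="size"):
            dens.extract_lane_profiles(
                img, [dens.LaneRect(0, 0, 50, 10), dens.LaneRect(0, 20, 40, 10)]
            )

    def test_overlapping_or_out_of_bounds_rectangles_rejected(self):
        img = np.ones((50, 40))
        with pytest.raises(ValueError, match="overlap"):
            dens.extract_lane_profiles(
                img, [dens.LaneRect(0, 0, 50, 10), dens.LaneRect(0, 5, 50, 10)]
            )
        with pytest.raises(ValueError, match="bounds"):
            dens.extract_lane_profiles(img, [dens.LaneRect(0, 35, 50, 10)])


class TestBaseline:
    def test_straight_line_profile_corrects_to_zero(self):
        p = gaussian_profile(amp=0.0, ramp=0.3, offset=2.0)
        corrected = dens.subtract_linear_baseline(p, WINDOW)
        mask = (p.positions >= WINDOW.start) & (p.positions <= WINDOW.end)
        assert np.max(np.abs(corrected.intensities[mask])) < 1e-9

    def test_band_on_ramp_equals_pure_band(self):
        pure = gaussian_profile(ramp=0.0)
        ramped = gaussian_profile(ramp=0.05, offset=1.0)
        corrected = dens.subtract_linear_baseline(ramped, WINDOW)
        mask = (pure.positions >= WINDOW.start) & (pure.positions <= WINDOW.end)
        np.testing.assert_allclose(
            corrected.intensities[mask], pure.intensities[mask], atol=1e-6
        )

    def test_window_too_close_to_edge_rejected(self):
        p = gaussian_profile(n=60)
        with pytest.raises(ValueError, match="flank_width"):
            dens.subtract_linear_baseline(p, dens.BandWindow(2.0, 30.0, flank_width=5))

    def test_invalid_band_window_parameters_rejected(self):
        with pytest.raises(ValueError, match="precede"):
            dens.BandWindow(10.0, 5.0)
        with pytest.raises(ValueError, match="flank_width"):
            dens.BandWindow(5.0, 10.0, flank_width=2)


class TestPeakArea:
    def test_zero_profile_gives_zero_area(self):
        assert dens.peak_area(profile_from(np.zeros(120)), WINDOW) == 0.0

    def test_gaussian_area_matches_analytic(self):
        # unit amplitude, sigma 5 -> area 5*sqrt(2*pi) ~ 12.533
        p = gaussian_profile(sigma=5.0, amp=1.0)
        expected = 5.0 * SQRT_2PI
        assert dens.peak_area(p, WINDOW) == pytest.approx(expected, rel=0.01)

    def test_area_linear_in_amplitude(self):
        a1 = dens.peak_area(gaussian_profile(amp=1.0), WINDOW)
        a2 = dens.peak_area(gaussian_profile(amp=2.0), WINDOW)
        assert a2 == pytest.approx(2 * a1, rel=1e-9)

    def test_area_invariant_under_linear_trend(self):
        base = dens.peak_area(gaussian_profile(), WINDOW)
        trended = dens.peak_area(gaussian_profile(ramp=0.08, offset=3.0), WINDOW)
        assert trended == pytest.approx(base, rel=1e-6)

    def test_noisy_band_on_ramp_area_within_3_percent(self):
        rng = np.random.default_rng(0)
        expected = 5.0 * SQRT_2PI
        areas = []
        for _ in range(100):
            p = gaussian_profile(ramp=0.02, offset=0.5)
            noisy = dens.LaneProfile(
                p.positions, p.intensities + rng.normal(0, 0.01, len(p))
            )
            areas.append(dens.peak_area(noisy, WINDOW))
        assert np.mean(areas) == pytest.approx(expected, rel=0.03)


class TestCalibration:
    def test_noiseless_line_recovered_exactly(self):
        c = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        a = 3.5 * c + 1.2
        curve = dens.fit_calibration(c, a)
        assert curve.slope == pytest.approx(3.5, abs=1e-9)
        assert curve.intercept == pytest.approx(1.2, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_too_few_points_or_no_spread_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            dens.fit_calibration([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="spread"):
            dens.fit_calibration([2.0, 2.0, 2.0], [1.0, 1.1, 0.9])

    def test_noisy_slope_unbiased_within_5_percent(self):
        rng = np.random.default_rng(0)
        c = np.array([2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0])
        slopes = []
        for _ in range(200):
            a = 2.0 * c * (1 + rng.normal(0, 0.10, c.size))
            slopes.append(dens.fit_calibration(c, a).slope)
        assert np.mean(slopes) == pytest.approx(2.0, rel=0.05)


class TestEstimateConcentration:
    @pytest.fixture
    def curve(self):
        c = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        return dens.fit_calibration(c, 3.0 * c + 0.5)

    def test_area_on_line_returns_calibration_point(self, curve):
        est = dens.estimate_concentration(curve, 3.0 * 6.0 + 0.5)
        assert est.value == pytest.approx(6.0, abs=1e-9)
        assert not est.extrapolated

    def test_area_at_intercept_gives_zero_flagged_extrapolated(self, curve):
        est = dens.estimate_concentration(curve, 0.5)
        assert est.value == pytest.approx(0.0, abs=1e-9)
        assert est.extrapolated  # below the 2 uM calibration range

    def test_estimate_linear_in_area_above_intercept(self, curve):
        e1 = dens.estimate_concentration(curve, 0.5 + 9.0)
        e2 = dens.estimate_concentration(curve, 0.5 + 18.0)
        assert e2.value == pytest.approx(2 * e1.value, rel=1e-9)

    def test_monte_carlo_round_trip_and_coverage(self):
        # truth 6 uM with additive area noise, the model the
        # inverse-prediction standard error assumes; 200 replicates.
        # Enough calibration points that 2*sd is close to a 95 % CI
        # (with few points the t-quantile correction would matter).
        rng = np.random.default_rng(42)
        c = np.linspace(2.0, 12.0, 16)
        estimates, covered = [], 0
        for _ in range(200):
            areas = 3.0 * c + rng.normal(0, 1.8, c.size)
            curve = dens.fit_calibration(c, areas)
            area = 3.0 * 6.0 + rng.normal(0, 1.8)
            est = dens.estimate_concentration(curve, area)
            estimates.append(est.value)
            covered += abs(est.value - 6.0) <= 2 * est.sd
        assert np.mean(estimates) == pytest.approx(6.0, abs=0.3)
        assert covered / 200 >= 0.90


class TestProfileIO:
    def test_csv_round_trip(self, tmp_path):
        profiles = [gaussian_profile(amp=a) for a in (0.5, 1.5)]
        profiles = [
            dens.LaneProfile(p.positions, p.intensities, lane_id=f"L{i}")
            for i, p in enumerate(profiles)
        ]
        path = tmp_path / "profiles.csv"
        dens.write_lane_profiles_csv(profiles, path)
        back = dens.read_lane_profiles_csv(path)
        assert [p.lane_id for p in back] == ["L0", "L1"]
        np.testing.assert_allclose(back[1].intensities, profiles[1].intensities)
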
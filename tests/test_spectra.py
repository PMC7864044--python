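"""Spectra: resampling, normalization, and constrained unmixing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemestar import spectra as sp
from hemestar import synthetic as synth


def make_spectrum(values, start=400.0, step=1.0, **kwargs):
    wl = start + step * np.arange(len(values))
    return sp.AbsorbanceSpectrum(wl, np.asarray(values, float), **kwargs)


class TestAbsorbanceSpectrum:
    def test_rejects_short_unsorted_or_out_of_band_wavelengths(self):
        with pytest.raises(ValueError, match="at least 10"):
            make_spectrum(np.ones(5))
        with pytest.raises(ValueError, match="strictly increasing"):
            sp.AbsorbanceSpectrum(np.array([400.0] * 12), np.ones(12))
        with pytest.raises(ValueError, match="200-1000"):
            make_spectrum(np.ones(12), start=100.0)
        with pytest.raises(ValueError, match="length"):
            sp.AbsorbanceSpectrum(np.arange(400.0, 412.0), np.ones(10))

    def test_restrict_keeps_window(self):
        s = make_spectrum(np.arange(50.0))
        r = s.restrict((405.0, 430.0))
        assert r.span == (405.0, 430.0)


class TestResample:
    def test_identity_on_own_grid(self):
        s = make_spectrum(np.random.default_rng(0).uniform(0, 1, 30))
        r = sp.resample_to_grid(s, s.wavelengths)
        np.testing.assert_array_equal(r.absorbances, s.absorbances)

    def test_linear_ramp_midpoints_are_neighbor_means(self):
        ramp = np.arange(20.0)
        s = make_spectrum(ramp)
        mid = s.wavelengths[:-1] + 0.5
        r = sp.resample_to_grid(s, mid)
        np.testing.assert_allclose(r.absorbances, (ramp[:-1] + ramp[1:]) / 2)

    def test_gaussian_band_refined_grid_matches_analytic(self, gaussian_spectrum):
        s, analytic, _ = gaussian_spectrum
        fine = np.arange(300.0, 700.01, 0.5)
        r = sp.resample_to_grid(s, fine)
        max_err = np.max(np.abs(r.absorbances - analytic(fine)))
        assert max_err < 0.005 * analytic(450.0)  # 0.5 % of peak

    def test_extrapolation_refused_with_endpoints_named(self):
        s = make_spectrum(np.ones(20))
        with pytest.raises(ValueError, match="extrapolate"):
            sp.resample_to_grid(s, np.arange(390.0, 420.0))


class TestNormalize:
    def test_unit_area_idempotent_and_scale_invariant(self, gaussian_spectrum):
        s, _, _ = gaussian_spectrum
        once = sp.normalize(s, "unit-area")
        twice = sp.normalize(once, "unit-area")
        np.testing.assert_allclose(twice.absorbances, once.absorbances, rtol=1e-12)
        doubled = sp.normalize(
            sp.AbsorbanceSpectrum(s.wavelengths, 2 * s.absorbances), "unit-area"
        )
        np.testing.assert_allclose(doubled.absorbances, once.absorbances, rtol=1e-12)

    def test_unit_area_gaussian_peak_height(self, gaussian_spectrum):
        s, _, sigma = gaussian_spectrum
        n = sp.normalize(s, "unit-area")
        expected_peak = 1.0 / (sigma * math.sqrt(2 * math.pi))
        assert abs(n.absorbances.max() - expected_peak) < 0.01 * expected_peak

    def test_extinction_mode_sets_global_maximum(self, gaussian_spectrum):
        s, _, _ = gaussian_spectrum
        n = sp.normalize(s, "per-heme-extinction", extinction_at_peak=117000.0)
        assert n.absorbances.max() == pytest.approx(117000.0)
        with pytest.raises(ValueError, match="extinction_at_peak"):
            sp.normalize(s, "per-heme-extinction")

    def test_all_zero_spectrum_rejected(self):
        s = make_spectrum(np.zeros(20))
        with pytest.raises(ValueError, match="normalize"):
            sp.normalize(s, "unit-area")


def mix_of(basis, f, noise=0.0, seed=0):
    mix, _ = synth.make_mixture(basis, f, noise_sd=noise, seed=seed)
    return mix


class TestUnmix:
    def test_pure_component_recovers_one(self, default_basis):
        res = sp.unmix_two_component(default_basis.basis_a, default_basis)
        assert res.f_a == pytest.approx(1.0, abs=1e-12)
        assert res.sse == pytest.approx(0.0, abs=1e-20)

    def test_exact_recovery_of_constructed_mixture(self, default_basis):
        res = sp.unmix_two_component(mix_of(default_basis, 0.3), default_basis)
        assert abs(res.f_a - 0.3) < 1e-9
        assert not res.clipped

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(f=st.floats(min_value=0.0, max_value=1.0))
    def test_noise_free_recovery_exact_for_any_fraction(self, default_basis, f):
        res = sp.unmix_two_component(mix_of(default_basis, f), default_basis)
        assert abs(res.f_a - f) < 1e-9
        assert res.f_a + res.f_b == pytest.approx(1.0, abs=0)

    def test_closed_form_matches_grid_search_on_noisy_mixtures(self, default_basis):
        for seed in range(20):
            mix = mix_of(default_basis, 0.6, noise=0.01, seed=seed)
            f_closed = sp.unmix_two_component(mix, default_basis).f_a
            f_grid = sp.unmix_grid_search(mix, default_basis, step=0.001)
            assert abs(f_closed - f_grid) <= 0.001

    def test_scale_consistency(self, default_basis):
        mix = mix_of(default_basis, 0.42)
        scaled = sp.BasisPair(
            sp.AbsorbanceSpectrum(
                default_basis.grid, 7.0 * default_basis.basis_a.absorbances
            ),
            sp.AbsorbanceSpectrum(
                default_basis.grid, 7.0 * default_basis.basis_b.absorbances
            ),
            default_basis.grid,
        )
        scaled_mix = sp.AbsorbanceSpectrum(mix.wavelengths, 7.0 * mix.absorbances)
        res = sp.unmix_two_component(scaled_mix, scaled)
        assert res.f_a == pytest.approx(0.42, abs=1e-9)

    def test_swapped_bases_return_swapped_fractions(self, default_basis):
        mix = mix_of(default_basis, 0.3, noise=0.01, seed=5)
        fwd = sp.unmix_two_component(mix, default_basis)
        swapped = sp.BasisPair(
            default_basis.basis_b, default_basis.basis_a, default_basis.grid
        )
        rev = sp.unmix_two_component(mix, swapped)
        assert rev.f_a == pytest.approx(fwd.f_b, abs=1e-9)

    def test_out_of_range_optimum_is_clipped_and_flagged(self, default_basis):
        a, b = default_basis.basis_a, default_basis.basis_b
        beyond = sp.AbsorbanceSpectrum(
            default_basis.grid, 1.5 * a.absorbances - 0.5 * b.absorbances
        )
        res = sp.unmix_two_component(beyond, default_basis)
        assert res.f_a == 1.0
        assert res.clipped

    def test_identical_bases_raise_degenerate_error(self, default_basis):
        same = sp.BasisPair(
            default_basis.basis_a, default_basis.basis_a, default_basis.grid
        )
        with pytest.raises(sp.DegenerateBasisError):
            sp.unmix_two_component(default_basis.basis_a, same)

    def test_tiny_window_rejected(self, default_basis):
        with pytest.raises(ValueError, match="grid points"):
            sp.unmix_two_component(
                default_basis.basis_a, default_basis, window=(400.0, 401.0)
            )

    def test_result_serialization_round_trip(self, default_basis):
        res = sp.unmix_two_component(
            mix_of(default_basis, 0.55, noise=0.01, seed=3), default_basis
        )
        back = sp.UnmixResult.from_dict(res.to_dict())
        assert back.f_a == res.f_a and back.n_points == res.n_points


class TestHemeTransfer:
    def test_identical_results_give_no_transfer(self, default_basis):
        res = sp.unmix_two_component(mix_of(default_basis, 0.5), default_basis)
        rep = sp.heme_transfer_evidence(res, res)
        assert rep.delta_f_b == 0.0 and not rep.transfer

    def test_full_transfer_flagged(self, default_basis):
        before = sp.unmix_two_component(default_basis.basis_a, default_basis)
        after = sp.unmix_two_component(default_basis.basis_b, default_basis)
        rep = sp.heme_transfer_evidence(before, after)
        assert rep.delta_f_b == pytest.approx(1.0, abs=1e-9)
        assert rep.transfer

    def test_noisy_transfer_delta_recovered(self, default_basis):
        deltas = []
        for seed in range(20):
            before = sp.unmix_two_component(
                mix_of(default_basis, 0.8, noise=0.01, seed=seed), default_basis
            )
            after = sp.unmix_two_component(
                mix_of(default_basis, 0.4, noise=0.01, seed=1000 + seed), default_basis
            )
            deltas.append(sp.heme_transfer_evidence(before, after).delta_f_b)
        assert np.mean(deltas) == pytest.approx(0.4, abs=0.02)

    def test_mismatched_windows_rejected(self, default_basis):
        r1 = sp.unmix_two_component(mix_of(default_basis, 0.5), default_basis)
        r2 = sp.unmix_two_component(
            mix_of(default_basis, 0.5), default_basis, window=(380.0, 680.0)
        )
        with pytest.raises(ValueError, match="window"):
            sp.heme_transfer_evidence(r1, r2)


class TestSpectrumIO:
    def test_write_read_round_trip(self, tmp_path, default_basis):
        path = tmp_path / "basis.csv"
        sp.write_spectrum(default_basis.basis_a, path)
        back = sp.read_spectrum(path)
        np.testing.assert_allclose(
            back.absorbances, default_basis.basis_a.absorbances, rtol=1e-9
        )
        np.testing.assert_allclose(back.wavelengths, default_basis.basis_a.wavelengths)

    def test_reader_accepts_comments_and_whitespace(self, tmp_path):
        path = tmp_path / "s.txt"
        lines = ["# a comment", "wavelength absorbance"]
        lines += [f"{400 + i} {1.0 + i / 10}  # inline" for i in range(12)]
        path.write_text("\n".join(lines))
        s = sp.read_spectrum(path)
        assert len(s) == 12
        assert s.absorbances[1] == pytest.approx(1.1)
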
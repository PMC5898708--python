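"""Spread profiles: idealized shapes, EFI fitting, FWHM, excitation."""

import numpy as np
import pytest

import cimodel as cm


class TestIdealizedProfiles:
    def test_peak_and_decay_values(self, geometry):
        lam = 2.5
        profiles = cm.idealized_profiles(geometry, lam)
        for e in [0, 10, 21]:
            p = profiles[e]
            x_e = geometry.electrode_positions_mm[e]
            assert p(x_e) == pytest.approx(1.0)
            assert p(x_e + lam) == pytest.approx(np.exp(-1))
            assert p(x_e + 2 * lam) == pytest.approx(np.exp(-2))

    def test_nonpositive_lambda_rejected(self, geometry):
        with pytest.raises(ValueError):
            cm.idealized_profiles(geometry, 0.0)


class TestFitEfiProfiles:
    @pytest.mark.parametrize("lam", [1.0, 2.0, 4.0, 8.0])
    @pytest.mark.parametrize("offset", [0.0, 0.5])
    def test_noiseless_round_trip(self, geometry, lam, offset):
        spec = cm.SyntheticEFISpec(
            lambda_apical_mm=lam, lambda_basal_mm=lam,
            peak_kohm=2.0 + offset, offset_kohm=offset, noise_cv=0.0,
        )
        profiles = cm.fit_efi_profiles(cm.synth_efi(spec, geometry), geometry)
        for e in range(2, 20):  # interior electrodes: >= 3 points per side
            p = profiles[e]
            assert p.apical_lambda_mm == pytest.approx(lam, rel=1e-3)
            assert p.basal_lambda_mm == pytest.approx(lam, rel=1e-3)
            assert p.apical_amplitude == pytest.approx(2.0, rel=1e-3)
            assert p.apical_offset == pytest.approx(offset, abs=1e-3 * (offset + 1))

    def test_noisy_median_lambda_error(self, geometry):
        """5% multiplicative measurement noise: median decay-length error
        below 10% over 20 seeds."""
        errors = []
        for seed in range(20):
            spec = cm.SyntheticEFISpec(
                lambda_apical_mm=3.0, lambda_basal_mm=3.0,
                peak_kohm=2.2, offset_kohm=0.2, noise_cv=0.05,
            )
            profiles = cm.fit_efi_profiles(cm.synth_efi(spec, geometry, seed), geometry)
            for e in range(2, 20):
                errors.append(abs(profiles[e].apical_lambda_mm - 3.0) / 3.0)
                errors.append(abs(profiles[e].basal_lambda_mm - 3.0) / 3.0)
        assert np.median(errors) < 0.10

    def test_constant_map_degenerate(self, geometry):
        m = np.full((22, 22), 0.3)
        np.fill_diagonal(m, 5.0)
        efi = cm.EFIMap(m, geometry.electrode_positions_mm)
        profiles = cm.fit_efi_profiles(efi, geometry)
        p = profiles[10]
        assert p.degenerate
        assert p.apical_amplitude == pytest.approx(0.0, abs=1e-6)
        xs = np.linspace(5, 30, 50)
        np.testing.assert_allclose(p(xs), 0.3, rtol=1e-6)

    def test_edge_electrodes_mirrored(self, geometry):
        efi = cm.synth_efi(cm.SyntheticEFISpec(noise_cv=0.0), geometry)
        profiles = cm.fit_efi_profiles(efi, geometry)
        assert profiles[0].mirrored_side == "apical"
        assert profiles[21].mirrored_side == "basal"
        assert profiles[10].mirrored_side is None

    def test_continuity_at_interpolation_edges(self, geometry):
        efi = cm.synth_efi(cm.SyntheticEFISpec(noise_cv=0.02), geometry, seed=1)
        profiles = cm.fit_efi_profiles(efi, geometry)
        for e in [5, 11, 16]:
            p = profiles[e]
            x_e = p.peak_position_mm
            for x_edge, apical in [(x_e - 0.75, True), (x_e + 0.75, False)]:
                side = p._side_value(np.array(x_edge), apical=apical)
                assert p(x_edge) == pytest.approx(float(side), rel=1e-9)

    def test_nonfinite_map_rejected(self, geometry):
        m = np.ones((22, 22))
        m[3, 4] = np.nan
        with pytest.raises(ValueError):
            cm.EFIMap(m, geometry.electrode_positions_mm)


class TestFWHM:
    def test_symmetric_analytic(self, geometry):
        profiles = cm.idealized_profiles(geometry, 2.0)
        fwhm, clipped = cm.profile_fwhm(profiles[10], geometry)
        assert fwhm == pytest.approx(4 * np.log(2), rel=1e-9)
        assert not clipped

    def test_asymmetric_analytic(self, geometry):
        p = cm.SpreadProfile(
            electrode=10, peak_position_mm=17.5,
            apical_amplitude=1.0, apical_lambda_mm=1.0, apical_offset=0.0,
            basal_amplitude=1.0, basal_lambda_mm=3.0, basal_offset=0.0,
        )
        fwhm, clipped = cm.profile_fwhm(p, geometry)
        assert fwhm == pytest.approx((1 + 3) * np.log(2), rel=1e-9)
        assert not clipped

    def test_offset_dominated_clipped(self, geometry):
        p = cm.SpreadProfile(
            electrode=10, peak_position_mm=17.5,
            apical_amplitude=0.4, apical_lambda_mm=2.0, apical_offset=0.6,
            basal_amplitude=0.4, basal_lambda_mm=2.0, basal_offset=0.6,
        )
        fwhm, clipped = cm.profile_fwhm(p, geometry)
        assert fwhm == pytest.approx(geometry.length_mm)
        assert clipped

    @pytest.mark.parametrize("lam", [0.5, 1.0, 3.0, 6.0])
    def test_idealized_identity(self, geometry, lam):
        profiles = cm.idealized_profiles(geometry, lam)
        fwhm, _ = cm.profile_fwhm(profiles[11], geometry)
        assert fwhm == pytest.approx(2 * lam * np.log(2), rel=1e-9)


class TestSpreadExcitation:
    def _one_pulse(self, electrode, current=200.0, t=0.001):
        return cm.Electrodogram(
            electrodes=np.array([electrode]),
            times_s=np.array([t]),
            currents_ua=np.array([current]),
            n_electrodes=22,
            duration_s=0.005,
        )

    def test_fiber_at_electrode_gets_full_current(self, small_geometry):
        profiles = cm.idealized_profiles(small_geometry, 3.0)
        x_e = small_geometry.electrode_positions_mm[10]
        # place a fiber exactly at the electrode via a custom position grid
        drive = cm.spread_excitation(
            self._one_pulse(10), profiles, small_geometry
        )
        w = profiles.weight_matrix(small_geometry.fiber_positions_mm)
        nearest = np.argmin(np.abs(small_geometry.fiber_positions_mm - x_e))
        assert drive[nearest].max() == pytest.approx(200.0 * w[10, nearest])

    def test_distance_lambda_gives_one_over_e(self, small_geometry):
        lam = 3.0
        profiles = cm.idealized_profiles(small_geometry, lam)
        drive = cm.spread_excitation(self._one_pulse(10), profiles, small_geometry)
        x_e = small_geometry.electrode_positions_mm[10]
        target = np.argmin(
            np.abs(small_geometry.fiber_positions_mm - (x_e + lam))
        )
        d = abs(small_geometry.fiber_positions_mm[target] - x_e)
        assert drive[target].max() == pytest.approx(
            200.0 * np.exp(-d / lam), rel=1e-9
        )

    def test_linearity_in_current(self, small_geometry):
        profiles = cm.idealized_profiles(small_geometry, 3.0)
        d1 = cm.spread_excitation(
            self._one_pulse(10, current=100.0), profiles, small_geometry
        )
        d2 = cm.spread_excitation(
            self._one_pulse(10, current=300.0), profiles, small_geometry
        )
        assert d2.sum() == pytest.approx(3.0 * d1.sum(), rel=1e-12)
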
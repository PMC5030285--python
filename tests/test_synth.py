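"""Forward model: lineshapes, dipolar kernels, titrations, release traces."""

import numpy as np
import pytest
from scipy.signal import argrelmax

import spinflux as sf
from spinflux.errors import ParameterError, ScheduleError, WindowError
from spinflux.synth import FULL_DOSE_RATE_PER_S


class TestLineshape:
    def test_three_hyperfine_maxima(self, grid):
        """Noiseless triplet absorption peaks exactly at B0 and B0 ± a_N."""
        cfg = sf.LineshapeConfig(slow_fraction=0.0)
        spec = sf.simulate_spectrum(cfg, grid=grid)
        absorption = sf.integrate(spec).absorption
        peaks = argrelmax(absorption)[0]
        assert len(peaks) == 3
        np.testing.assert_allclose(
            grid[peaks], [335.0 - 1.6, 335.0, 335.0 + 1.6], atol=spec.spacing
        )

    def test_unit_spin_count(self, grid):
        spec = sf.simulate_spectrum(sf.LineshapeConfig(), grid=grid)
        assert sf.double_integral(spec) == pytest.approx(1.0, rel=1e-6)

    def test_determinism(self, grid):
        a = sf.simulate_spectrum(sf.LineshapeConfig(), grid=grid, noise_sd=0.05,
                                 baseline_coeffs=(0.0, 0.01), seed=42)
        b = sf.simulate_spectrum(sf.LineshapeConfig(), grid=grid, noise_sd=0.05,
                                 baseline_coeffs=(0.0, 0.01), seed=42)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_invalid_configs(self):
        with pytest.raises(ParameterError):
            sf.LineshapeConfig(a_n_mT=-1.0)
        with pytest.raises(ParameterError):
            sf.LineshapeConfig(slow_fraction=1.5)
        with pytest.raises(ParameterError):
            sf.DipolarConfig(r_nm=0.0)


class TestDipolarKernel:
    @pytest.mark.parametrize("kind", ["pake", "gaussian"])
    @pytest.mark.parametrize("r", [0.9, 1.2, 1.8])
    def test_unit_area(self, kind, r):
        k = sf.dipolar_kernel(sf.DipolarConfig(r_nm=r, kernel=kind), 0.02)
        assert abs(k.weights.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(k.weights, k.weights[::-1])  # symmetric

    def test_beyond_cutoff_is_delta(self):
        k = sf.dipolar_kernel(sf.DipolarConfig(r_nm=3.0), 0.02)
        assert k.weights.shape == (1,)
        assert k.weights[0] == 1.0

    def test_second_moment_matches_powder_law(self):
        """Pake kernel variance equals d(r)²/5 with d = C_dd/r³ in mT."""
        cfg = sf.DipolarConfig(r_nm=1.2)
        k = sf.dipolar_kernel(cfg, 0.004)
        assert k.second_moment_mT2 == pytest.approx(
            cfg.splitting_mT**2 / 5.0, rel=1e-3
        )

    def test_gaussian_variant_matches_pake_moment(self):
        cfg_p = sf.DipolarConfig(r_nm=1.2, kernel="pake")
        cfg_g = sf.DipolarConfig(r_nm=1.2, kernel="gaussian")
        mp = sf.dipolar_kernel(cfg_p, 0.004).second_moment_mT2
        mg = sf.dipolar_kernel(cfg_g, 0.004).second_moment_mT2
        assert mg == pytest.approx(mp, rel=5e-3)

    def test_partial_labeling_scales_moment(self):
        full = sf.dipolar_kernel(sf.DipolarConfig(r_nm=1.2), 0.01)
        half = sf.dipolar_kernel(
            sf.DipolarConfig(r_nm=1.2, labeled_fraction=0.5), 0.01
        )
        assert half.second_moment_mT2 == pytest.approx(
            0.5 * full.second_moment_mT2, rel=1e-9
        )

    def test_kernel_wider_than_window_rejected(self, grid):
        # r = 0.35 nm gives a ~43 mT splitting: cannot fit a 33 mT sweep
        with pytest.raises(WindowError):
            sf.simulate_spectrum(
                sf.LineshapeConfig(), sf.DipolarConfig(r_nm=0.35), grid=grid
            )

    def test_convolution_conserves_spins_and_adds_variance(self, grid):
        """Unit-area kernel: double integral conserved, second moments add."""
        spec = sf.simulate_spectrum(sf.LineshapeConfig(), grid=grid)
        kern = sf.dipolar_kernel(sf.DipolarConfig(r_nm=1.2), spec.spacing)
        broad = spec.copy(intensity=sf.convolve(spec.intensity, kern))
        assert sf.double_integral(broad) == pytest.approx(
            sf.double_integral(spec), rel=1e-6
        )
        m_plain = sf.second_moment(sf.integrate(spec))
        m_broad = sf.second_moment(sf.integrate(broad))
        assert m_broad - m_plain == pytest.approx(
            kern.second_moment_mT2, abs=1e-3
        )


class TestTitration:
    def test_saturated_spectra_identical(self):
        truth = sf.TitrationGroundTruth(noise_sd=0.0, baseline_coeffs=())
        out = {(c, l): s for c, l, s in sf.simulate_titration(truth)}
        for labeling in ("maximal", "minimal"):
            a = out[(30.0, labeling)].intensity
            for c in (40.0, 50.0):
                np.testing.assert_allclose(out[(c, labeling)].intensity, a,
                                           atol=1e-12)

    def test_spin_count_constant_across_series(self, noiseless_titration):
        truth, spectra, processed = noiseless_titration
        dis = [sf.double_integral(corr) for corr, _ in processed.values()]
        np.testing.assert_allclose(dis, 1.0, rtol=1e-6)

    def test_maximal_condition_is_broader_at_zero_lpc(self, noiseless_titration):
        truth, spectra, processed = noiseless_titration
        m_max = sf.second_moment(processed[(0.0, "maximal")][1])
        m_min = sf.second_moment(processed[(0.0, "minimal")][1])
        assert m_max > m_min

    def test_open_fraction_saturates(self):
        truth = sf.TitrationGroundTruth(c_sat_molpct=30.0)
        f = [truth.open_fraction(c) for c in (0, 10, 20, 30, 40, 50)]
        assert f[0] == 0.0
        assert all(b >= a for a, b in zip(f, f[1:]))
        assert f[3] == f[4] == f[5] == 1.0

    def test_bit_identical_for_fixed_seed(self):
        truth = sf.TitrationGroundTruth(seed=7)
        a = sf.simulate_titration(truth)
        b = sf.simulate_titration(truth)
        for (_, _, sa), (_, _, sb) in zip(a, b):
            np.testing.assert_array_equal(sa.intensity, sb.intensity)

    def test_config_round_trip(self):
        truth = sf.TitrationGroundTruth(c_sat_molpct=20.0, noise_sd=0.005)
        again = sf.TitrationGroundTruth.from_dict(truth.to_dict())
        assert again == truth


class TestReleaseTrace:
    def test_no_events_constant(self):
        truth = sf.ReleaseGroundTruth(schedule=[], noise_sd=0.0)
        trace = sf.simulate_release_trace(truth, 0.5, 60.0)
        np.testing.assert_allclose(trace.intensity, truth.i0)

    def test_single_dose_approaches_but_never_reaches_asymptote(self):
        truth = sf.ReleaseGroundTruth(
            rate_per_s=FULL_DOSE_RATE_PER_S, noise_sd=0.0,
            schedule=[(0.0, "LPC")],
        )
        trace = sf.simulate_release_trace(truth, 0.5, 600.0)
        assert np.all(np.diff(trace.intensity) >= 0)
        assert trace.intensity[-1] < truth.i100
        assert trace.intensity[-1] > truth.i0 + 0.99 * (truth.i100 - truth.i0)

    def test_bsa_arrests_release(self):
        truth = sf.ReleaseGroundTruth(
            noise_sd=0.0, schedule=[(0.0, "LPC"), (120.0, "BSA")]
        )
        trace = sf.simulate_release_trace(truth, 0.5, 300.0)
        after = trace.intensity[trace.time > 120.0]
        np.testing.assert_allclose(after, after[0], atol=1e-12)

    def test_lysis_jumps_to_full_release(self):
        truth = sf.ReleaseGroundTruth(
            noise_sd=0.0, schedule=[(0.0, "LPC"), (60.0, "lysis")]
        )
        trace = sf.simulate_release_trace(truth, 0.5, 120.0)
        np.testing.assert_allclose(
            trace.intensity[trace.time >= 60.0], truth.i100
        )

    def test_lysis_before_lpc_rejected(self):
        with pytest.raises(ScheduleError):
            sf.ReleaseGroundTruth(schedule=[(10.0, "lysis"), (20.0, "LPC")])

    def test_deterministic(self):
        truth = sf.ReleaseGroundTruth(seed=3)
        a = sf.simulate_release_trace(truth)
        b = sf.simulate_release_trace(truth)
        np.testing.assert_array_equal(a.intensity, b.intensity)
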
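"""Moment statistics, linewidths, quantitation arithmetic."""


import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spinflux as sf
from spinflux.errors import DegenerateInputError, ResolutionError
from spinflux.synth import _gauss_abs, _gauss_deriv, _lorentz_deriv


def absorption_from(grid, values):
    return sf.AbsorptionSpectrum(grid, values, {})


def oracle_moments(field, absorption):
    """Brute-force trapezoidal moments, independent of the implementation."""
    area = np.trapezoid(absorption, field)
    bf = np.trapezoid(field * absorption, field) / area
    m2 = np.trapezoid((field - bf) ** 2 * absorption, field) / area
    return bf, m2


class TestFirstMoment:
    def test_symmetric_line_centroid(self, grid):
        a = absorption_from(grid, _gauss_abs(grid - 335.0, 0.5))
        assert sf.first_moment(a) == pytest.approx(335.0, abs=grid[1] - grid[0])

    def test_translation_equivariance(self, grid):
        values = _gauss_abs(grid - 335.0, 0.5)
        a = absorption_from(grid, values)
        b = absorption_from(grid + 2.0, values)
        assert sf.first_moment(b) - sf.first_moment(a) == pytest.approx(2.0,
                                                                        abs=1e-9)

    def test_two_equal_lines_average(self, grid):
        values = _gauss_abs(grid - 333.0, 0.3) + _gauss_abs(grid - 337.0, 0.3)
        assert sf.first_moment(absorption_from(grid, values)) == pytest.approx(
            335.0, abs=1e-6
        )

    def test_zero_area_degenerate(self, grid):
        with pytest.raises(DegenerateInputError):
            sf.first_moment(absorption_from(grid, np.zeros_like(grid)))


class TestSecondMoment:
    def test_gaussian_variance(self, fine_grid):
        a = absorption_from(fine_grid, _gauss_abs(fine_grid - 335.0, 0.5))
        assert sf.second_moment(a) == pytest.approx(0.25, abs=1e-4)

    def test_scale_invariance(self, grid):
        values = _gauss_abs(grid - 335.0, 0.5)
        m1 = sf.second_moment(absorption_from(grid, values))
        m2 = sf.second_moment(absorption_from(grid, 10.0 * values))
        assert m2 == pytest.approx(m1, rel=1e-12)

    def test_hyperfine_triplet_against_oracle(self, fine_grid):
        """σ² + (2/3)a_N² for three equal lines at B0, B0 ± a_N."""
        values = sum(
            _gauss_abs(fine_grid - (335.0 + off), 0.2) for off in (-1.6, 0.0, 1.6)
        )
        a = absorption_from(fine_grid, values)
        expected = 0.2**2 + (2.0 / 3.0) * 1.6**2
        assert sf.second_moment(a) == pytest.approx(expected, abs=1e-3)
        assert sf.second_moment(a) == pytest.approx(
            oracle_moments(fine_grid, values)[1], rel=1e-9
        )

    def test_lorentzian_window_dependence_documented(self):
        """Lorentzian-tailed second moments grow ~linearly with the window."""
        gamma = 0.3
        m = {}
        for span in (20.0, 40.0):
            grid = sf.default_grid(span=span, n=8192)
            values = (gamma / np.pi) / ((grid - 335.0) ** 2 + gamma**2)
            m[span] = sf.second_moment(absorption_from(grid, values))
        assert m[40.0] / m[20.0] == pytest.approx(2.0, rel=0.10)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        shift=st.floats(min_value=-5.0, max_value=5.0),
        sigma=st.floats(min_value=0.1, max_value=1.0),
        split=st.floats(min_value=0.0, max_value=3.0),
    )
    def test_scaling_and_translation_properties(self, scale, shift, sigma, split):
        grid = sf.default_grid(n=1024)
        values = _gauss_abs(grid - (335.0 - split), sigma) + 2.0 * _gauss_abs(
            grid - (335.0 + split), sigma
        )
        a = absorption_from(grid, values)
        b = absorption_from(grid + shift, values * scale)
        assert sf.second_moment(b) == pytest.approx(sf.second_moment(a), rel=1e-9)
        assert sf.first_moment(b) - sf.first_moment(a) == pytest.approx(
            shift, abs=1e-8
        )


class TestDeltaSecondMoment:
    def test_self_difference_is_exactly_zero(self, grid):
        a = absorption_from(grid, _gauss_abs(grid - 335.0, 0.5))
        assert sf.delta_second_moment(a, a).delta_mT2 == 0.0

    def test_gaussian_kernel_convolution(self, grid):
        """S ⊗ N(0, 0.3 mT) gains exactly the kernel variance: 9.0e-8 T²."""
        spec = sf.simulate_spectrum(sf.LineshapeConfig(), grid=grid)
        spacing = spec.spacing
        off = np.arange(-60, 61) * spacing
        kern = np.exp(-0.5 * (off / 0.3) ** 2)
        kern /= kern.sum()
        broad = spec.copy(intensity=np.convolve(spec.intensity, kern, mode="same"))
        d = sf.delta_second_moment(sf.integrate(broad), sf.integrate(spec))
        assert d.delta_T2 == pytest.approx(9.0e-8, rel=0.02)
        assert not d.negative

    def test_negative_delta_flagged_not_clamped(self, grid):
        narrow = absorption_from(grid, _gauss_abs(grid - 335.0, 0.3))
        wide = absorption_from(grid, _gauss_abs(grid - 335.0, 0.6))
        with pytest.warns(UserWarning, match="negative"):
            d = sf.delta_second_moment(narrow, wide)
        assert d.negative
        assert d.delta_mT2 == pytest.approx(0.09 - 0.36, abs=1e-3)


class TestCentralLinewidth:
    def test_gaussian_peak_to_peak(self, fine_grid):
        spec = sf.Spectrum(fine_grid, _gauss_deriv(fine_grid - 335.0, 0.2), {})
        dh, inv = sf.inverse_central_linewidth(spec)
        step = fine_grid[1] - fine_grid[0]
        assert dh == pytest.approx(0.4, abs=step)
        assert inv == pytest.approx(2.5, rel=step / 0.4)

    def test_lorentzian_peak_to_peak(self, fine_grid):
        spec = sf.Spectrum(fine_grid, _lorentz_deriv(fine_grid - 335.0, 0.3), {})
        dh, _ = sf.inverse_central_linewidth(spec)
        step = fine_grid[1] - fine_grid[0]
        assert dh == pytest.approx(2 * 0.3 / np.sqrt(3), abs=step)

    def test_narrower_open_state_raises_inverse_width(self, noiseless_titration):
        truth, spectra, processed = noiseless_titration
        widths = [
            sf.inverse_central_linewidth(processed[(c, "minimal")][0])[1]
            for c in truth.lpc_molpct
        ]
        assert all(b >= a - 1e-12 for a, b in zip(widths, widths[1:]))
        assert widths[-1] > widths[0]

    def test_flat_spectrum_unresolvable(self, grid):
        spec = sf.Spectrum(grid, np.zeros_like(grid), {})
        with pytest.raises(ResolutionError):
            sf.inverse_central_linewidth(spec)


class TestQuantitation:
    def test_equal_integrals_recover_reference(self):
        assert sf.spin_concentration(3.3, 3.3, 100.0) == 100.0

    def test_proportionality(self):
        assert sf.spin_concentration(2.0, 1.0, 100.0) == 200.0

    def test_sle_examples(self):
        assert sf.labeling_efficiency(149.6, 170.0) == pytest.approx(0.88)
        assert sf.labeling_efficiency(0.0, 170.0) == 0.0
        assert sf.labeling_efficiency(170.0, 170.0) == 1.0

    def test_sle_above_one_warns(self):
        with pytest.warns(UserWarning, match="SLE > 1"):
            sf.labeling_efficiency(200.0, 170.0)

    def test_invalid_inputs(self):
        with pytest.raises(DegenerateInputError):
            sf.spin_concentration(1.0, 0.0, 100.0)
        with pytest.raises(DegenerateInputError):
            sf.labeling_efficiency(1.0, 0.0)

    def test_quantitate_record(self):
        q = sf.quantitate(0.5, 1.0, 100.0, 170.0)
        assert q.c_samp == 50.0
        assert q.sle == pytest.approx(50.0 / 170.0)
        assert (q.n_samp, q.n_ref, q.c_ref, q.c_prot) == (0.5, 1.0, 100.0, 170.0)


class TestMobilityResult:
    def test_window_recorded_and_units_consistent(self, noiseless_titration):
        truth, spectra, processed = noiseless_titration
        corrected, absorption = processed[(0.0, "minimal")]
        mob = sf.mobility_result(corrected, absorption)
        lo, hi = mob.window_mT
        assert corrected.field[0] <= lo < hi <= corrected.field[-1]
        assert mob.second_moment_T2 == pytest.approx(
            mob.second_moment_mT2 * 1e-6
        )
        assert mob.inv_dh_per_mT == pytest.approx(1.0 / mob.dh_pp_mT)
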
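"""Spectral-moment statistics, linewidths, spin quantitation, labeling efficiency.

The mobility parameters of site-directed spin-label EPR:

* first moment  B_F  = ∫ B·S(B) dB / ∫ S(B) dB            (mT)
* second moment ⟨ΔB²⟩ = ∫ (B−B_F)²·S(B) dB / ∫ S(B) dB    (mT²)
* inverse central linewidth ΔH⁻¹ = 1 / ΔH_pp              (mT⁻¹)

with S(B) the absorption spectrum.  The spin–spin interaction proxy is the
difference of second moments between a dipolar-broadened (maximally
labeled, interacting) and a non-broadened (minimally labeled) spectrum,

    Δ⟨ΔB²⟩ = ⟨ΔB_I²⟩ − ⟨ΔB_N²⟩,

each moment taken about its own first moment.  Moments are computed over
the recorded field window only — no tail extrapolation — which is the only
defensible convention for Lorentzian-tailed lineshapes; the window is part
of every result.  Computation is in mT²; values are also reported in T²
(1 mT² = 1e-6 T²) which is the customary scale for tabulating Δ⟨ΔB²⟩.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ResolutionError
from .io import AbsorptionSpectrum, Spectrum

MT2_TO_T2 = 1e-6


@dataclass
class MobilityResult:
    """Per-spectrum mobility statistics with the window they were taken on."""

    first_moment_mT: float
    second_moment_mT2: float
    dh_pp_mT: float
    inv_dh_per_mT: float
    double_integral: float
    window_mT: tuple[float, float]

    @property
    def second_moment_T2(self) -> float:
        return self.second_moment_mT2 * MT2_TO_T2


@dataclass
class DeltaSecondMoment:
    """Difference of second moments, interacting minus non-interacting."""

    delta_mT2: float
    window_mT: tuple[float, float]

    @property
    def delta_T2(self) -> float:
        return self.delta_mT2 * MT2_TO_T2

    @property
    def negative(self) -> bool:
        return self.delta_mT2 < 0


@dataclass
class QuantitationResult:
    """Spin concentration and labeling efficiency with their inputs echoed."""

    c_samp: float
    sle: float
    n_samp: float
    n_ref: float
    c_ref: float
    c_prot: float


def signal_support(spectrum: Spectrum, threshold: float = 0.02,
                   pad_mT: float = 2.0) -> tuple[float, float]:
    """Contiguous field span carrying the signal, from the derivative envelope.

    The span between the first and last points where the boxcar-smoothed
    |derivative| exceeds ``threshold`` of its maximum, padded by ``pad_mT``
    on each side (clipped to the sweep).  Used as the default moment
    window: restricting the doubly-integrated moments to the support keeps
    the noise random walk of the absorption from dominating them on wide
    sweeps.
    """
    env = np.convolve(np.abs(spectrum.intensity), np.ones(9) / 9.0, mode="same")
    # noise floor: the lower quartile of the envelope is noise-dominated on
    # any sweep where the signal occupies a minority of the window; staying
    # a factor 8 above it keeps lone noise excursions out of the support
    floor = float(np.percentile(env, 25.0))
    thr = max(threshold * float(np.max(env)), 8.0 * floor)
    idx = np.flatnonzero(env >= thr)
    if idx.size == 0:
        raise DegenerateInputError("no signal above the support threshold")
    lo = max(float(spectrum.field[idx[0]]) - pad_mT, float(spectrum.field[0]))
    hi = min(float(spectrum.field[idx[-1]]) + pad_mT, float(spectrum.field[-1]))
    return lo, hi


def _windowed(absorption: AbsorptionSpectrum, window):
    """Slice to the window and re-anchor the absorption to zero at both ends.

    Subtracting the straight line through the windowed endpoints turns the
    accumulated integration noise into a bridge; for a clean spectrum whose
    signal the window covers it is a no-op to numerical precision.
    """
    b, s = absorption.field, absorption.absorption
    if window is not None:
        lo, hi = window
        sel = (b >= lo) & (b <= hi)
        if np.count_nonzero(sel) < 8:
            raise DegenerateInputError("moment window holds too few points")
        b, s = b[sel], s[sel]
        s = s - (s[0] + (s[-1] - s[0]) * (b - b[0]) / (b[-1] - b[0]))
    return b, s


def _area(b: np.ndarray, s: np.ndarray) -> float:
    area = float(np.trapezoid(s, b))
    scale = float(np.max(np.abs(s)))
    span = b[-1] - b[0]
    if scale == 0 or area <= 1e-12 * scale * span:
        raise DegenerateInputError("absorption spectrum has (near-)zero area")
    return area


def first_moment(absorption: AbsorptionSpectrum,
                 window: tuple[float, float] | None = None) -> float:
    """Centroid field of the absorption lineshape over the moment window.

    The window defaults to the full recorded sweep; there is never any
    tail extrapolation beyond it.
    """
    b, s = _windowed(absorption, window)
    return float(np.trapezoid(b * s, b) / _area(b, s))


def second_moment(absorption: AbsorptionSpectrum,
                  window: tuple[float, float] | None = None) -> float:
    """Variance of the absorption lineshape about its own first moment (mT²)."""
    b, s = _windowed(absorption, window)
    area = _area(b, s)
    bf = float(np.trapezoid(b * s, b) / area)
    return float(np.trapezoid((b - bf) ** 2 * s, b) / area)


def delta_second_moment(
    interacting: AbsorptionSpectrum,
    noninteracting: AbsorptionSpectrum,
    window: tuple[float, float] | None = None,
) -> DeltaSecondMoment:
    """Δ⟨ΔB²⟩ between a dipolar-broadened and a non-broadened spectrum.

    Both moments are taken over the *same* window (default: the full
    sweep), each about its own first moment.  Spin normalization is *not*
    required — moments are scale-invariant.  Negative values are
    physically anomalous (e.g. a not fully closed channel in the
    interacting sample); they are flagged with a warning but never
    clamped.
    """
    d = second_moment(interacting, window) - second_moment(noninteracting, window)
    if window is None:
        window = (float(interacting.field[0]), float(interacting.field[-1]))
    result = DeltaSecondMoment(d, (float(window[0]), float(window[1])))
    if result.negative:
        warnings.warn(
            f"negative delta second moment ({d:.3g} mT²): interacting spectrum "
            "narrower than non-interacting one",
            stacklevel=2,
        )
    return result


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-grid extremum position by a 3-point parabola around index i."""
    if i <= 0 or i >= x.size - 1:
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(x[i] + delta * (x[1] - x[0]))


def inverse_central_linewidth(
    spectrum: Spectrum, search_window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Peak-to-peak width of the central line and its inverse.

    Locates the global derivative maximum inside the search window
    (default: middle third of the sweep) and the minimum that follows it;
    both extrema are refined to sub-grid precision by local parabolic
    interpolation.  Returns ``(dh_pp in mT, 1/dh_pp in mT⁻¹)``.
    """
    b = spectrum.field
    y = spectrum.intensity
    n = b.size
    if search_window is None:
        lo, hi = n // 3, 2 * n // 3
    else:
        lo = int(np.searchsorted(b, search_window[0], side="left"))
        hi = int(np.searchsorted(b, search_window[1], side="right"))
    if hi - lo < 5:
        raise ResolutionError("central search window too small")
    seg = y[lo:hi]
    imax = lo + int(np.argmax(seg))
    if imax >= hi - 1:
        raise ResolutionError("no derivative maximum/minimum pair in window")
    imin = imax + 1 + int(np.argmin(y[imax + 1 : hi]))
    if y[imin] >= y[imax]:
        raise ResolutionError("central line not resolvable (flat window)")
    b_max = _parabolic_refine(b, y, imax)
    b_min = _parabolic_refine(b, y, imin)
    dh_pp = b_min - b_max
    if dh_pp <= 0:
        raise ResolutionError("non-positive peak-to-peak width")
    return float(dh_pp), float(1.0 / dh_pp)


def spin_concentration(sample_N: float, reference_N: float, c_ref: float) -> float:
    """Spin concentration from double integrals against a reference probe.

    C_samp = N_samp · C_ref / N_ref, valid only when sample and reference
    spectra were acquired and processed identically (the caller attests
    comparability).
    """
    if reference_N <= 0:
        raise DegenerateInputError("reference double integral must be positive")
    return float(sample_N * c_ref / reference_N)


def labeling_efficiency(c_samp: float, c_prot: float) -> float:
    """Spin labeling efficiency SLE = C_samp / C_prot.

    Values above 1 are allowed (over-labeling or quantitation error) but
    warned about.
    """
    if c_prot <= 0:
        raise DegenerateInputError("protein concentration must be positive")
    sle = float(c_samp / c_prot)
    if sle > 1.0:
        warnings.warn(f"SLE > 1 ({sle:.3g}): over-labeling or quantitation error",
                      stacklevel=2)
    return sle


def quantitate(
    n_samp: float, n_ref: float, c_ref: float, c_prot: float
) -> QuantitationResult:
    """Convenience: spin concentration and SLE in one record."""
    c_samp = spin_concentration(n_samp, n_ref, c_ref)
    return QuantitationResult(
        c_samp=c_samp,
        sle=labeling_efficiency(c_samp, c_prot),
        n_samp=n_samp,
        n_ref=n_ref,
        c_ref=c_ref,
        c_prot=c_prot,
    )


def mobility_result(
    spectrum: Spectrum,
    absorption: AbsorptionSpectrum,
    search_window: tuple[float, float] | None = None,
    moment_window="auto",
) -> MobilityResult:
    """All mobility statistics for one baseline-corrected spectrum.

    ``moment_window`` is ``"auto"`` (the spectrum's :func:`signal_support`,
    the noise-robust default), ``None`` (full sweep) or an explicit
    ``(low, high)`` in mT; the window used is recorded in the result.
    """
    from .preprocess import double_integral  # local import avoids cycle

    if moment_window == "auto":
        moment_window = signal_support(spectrum)
    bf = first_moment(absorption, moment_window)
    m2 = second_moment(absorption, moment_window)
    dh_pp, inv_dh = inverse_central_linewidth(spectrum, search_window)
    used = moment_window or (float(spectrum.field[0]), float(spectrum.field[-1]))
    return MobilityResult(
        first_moment_mT=bf,
        second_moment_mT2=m2,
        dh_pp_mT=dh_pp,
        inv_dh_per_mT=inv_dh,
        double_integral=double_integral(spectrum, moment_window),
        window_mT=(float(used[0]), float(used[1])),
    )
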
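"""Baseline correction, integration and normalization of derivative spectra.

The standard cw-EPR workflow: a polynomial fitted to the signal-free edges
of the first-derivative sweep is subtracted, then the first integral is
given a second-stage linear correction (a constant on the derivative) so
the absorption returns to zero at the high-field end of the sweep.  All
integration uses the trapezoidal rule on the uniform grid; no resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import BaselineError, DegenerateInputError, ParameterError
from .io import AbsorptionSpectrum, Spectrum
from .errors import GridError

log = logging.getLogger(__name__)

MAX_ORDER = 3
MAX_EDGE_FRACTION = 0.25

#: |end-of-sweep absorption| / max|absorption| above which a residual
#: (under-modelled) baseline is flagged, measured before the second-stage
#: constant correction forces the endpoint to zero.
RESIDUAL_BASELINE_TOL = 0.02

#: edge-region RMS / max|signal| above which hyperfine wings are suspected
#: to intrude into the baseline fit region.
EDGE_SIGNAL_TOL = 0.05


@dataclass
class BaselineModel:
    """Fitted baseline: polynomial on the derivative + constant on the integral.

    ``coefficients`` are ascending powers of (B - B_center) in signal units;
    ``integral_constant`` is the constant subtracted from the derivative so
    that the absorption ends at zero.  ``flags`` carries quality diagnostics
    (``residual_baseline``, ``edge_signal``) — warnings, never failures.
    """

    order: int
    edge_fraction: float
    coefficients: np.ndarray
    integral_constant: float = 0.0
    flags: dict = dc_field(default_factory=dict)

    @property
    def slope(self) -> float:
        """Linear coefficient of the fitted polynomial (a.u. per mT)."""
        return float(self.coefficients[1]) if len(self.coefficients) > 1 else 0.0


def baseline_correct(
    spectrum: Spectrum, order: int = 1, edge_fraction: float = 0.1
) -> tuple[Spectrum, BaselineModel]:
    """Fit and subtract a polynomial baseline using the sweep edges.

    Parameters
    ----------
    order:
        Polynomial order fitted to the derivative edges (0-3; default 1,
        the common practice for bench-top cw instruments).
    edge_fraction:
        Fraction of points at *each* end of the sweep treated as
        signal-free (0 < f <= 0.25, default 0.1).

    Returns the corrected spectrum and the fitted :class:`BaselineModel`.
    """
    if not (0 <= order <= MAX_ORDER):
        raise ParameterError(f"baseline order must be in [0, {MAX_ORDER}]")
    if not (0 < edge_fraction <= MAX_EDGE_FRACTION):
        raise ParameterError(
            f"edge fraction must be in (0, {MAX_EDGE_FRACTION}]"
        )
    n = spectrum.field.size
    k = int(round(edge_fraction * n))
    if k < order + 1 or 2 * k >= n:
        raise ParameterError("edge regions overlap or are too small for the order")

    b = spectrum.field
    y = spectrum.intensity
    center = 0.5 * (b[0] + b[-1])
    x = b - center
    edge_idx = np.r_[0:k, n - k : n]
    coeffs = np.polynomial.polynomial.polyfit(x[edge_idx], y[edge_idx], order)
    corrected = y - np.polynomial.polynomial.polyval(x, coeffs)

    # Second stage: force the absorption back to zero at the high-field end.
    absorption = cumulative_trapezoid(corrected, b, initial=0.0)
    span = b[-1] - b[0]
    const = float(absorption[-1]) / span
    corrected = corrected - const

    abs_scale = float(np.max(np.abs(absorption)))
    flags = {}
    if abs_scale > 0 and abs(absorption[-1]) / abs_scale > RESIDUAL_BASELINE_TOL:
        flags["residual_baseline"] = True
        log.warning(
            "%s: nonzero end-of-sweep absorption (%.3g of max) — baseline "
            "order %d may be insufficient",
            spectrum.meta.get("label", "spectrum"),
            abs(absorption[-1]) / abs_scale,
            order,
        )
    sig_scale = float(np.max(np.abs(corrected)))
    if sig_scale > 0:
        edge_rms = float(np.sqrt(np.mean(corrected[edge_idx] ** 2)))
        if edge_rms / sig_scale > EDGE_SIGNAL_TOL:
            flags["edge_signal"] = True
            log.warning(
                "%s: signal detected in baseline edge regions (RMS %.3g of peak)",
                spectrum.meta.get("label", "spectrum"),
                edge_rms / sig_scale,
            )

    model = BaselineModel(order, edge_fraction, coeffs, const, flags)
    return spectrum.copy(intensity=corrected), model


def integrate(spectrum: Spectrum) -> AbsorptionSpectrum:
    """Cumulative trapezoidal integral of the derivative: the absorption."""
    absorption = cumulative_trapezoid(spectrum.intensity, spectrum.field, initial=0.0)
    return AbsorptionSpectrum(
        spectrum.field.copy(),
        absorption,
        provenance={"source": spectrum.meta.get("label", "unlabeled")},
    )


def double_integral(spectrum: Spectrum, window=None) -> float:
    """Area of the absorption spectrum: the spin-count proxy (a.u.·mT²).

    ``window`` restricts the integration: ``None`` is the full sweep,
    ``"auto"`` the spectrum's signal support, a ``(low, high)`` tuple an
    explicit range in mT.  Within a window the absorption is re-anchored
    to zero at both ends, which suppresses the integration random walk of
    noisy spectra.  Strictly positive for any physical baseline-corrected
    spectrum; a negative value beyond numerical tolerance signals a
    failed baseline.
    """
    from .moments import _windowed, signal_support  # deferred: avoids cycle

    if isinstance(window, str) and window == "auto":
        window = signal_support(spectrum)
    absorption = integrate(spectrum)
    b, s = _windowed(absorption, window)
    di = float(np.trapezoid(s, b))
    scale = float(np.max(np.abs(s)))
    span = b[-1] - b[0]
    if di < -1e-9 * max(scale * span, 1e-300):
        raise BaselineError(f"negative double integral ({di:.3g}): baseline failure")
    return di


def _central_pp_amplitude(spectrum: Spectrum) -> float:
    """Peak-to-peak derivative amplitude within the middle third of the sweep."""
    n = spectrum.field.size
    lo, hi = n // 3, 2 * n // 3
    seg = spectrum.intensity[lo:hi]
    return float(np.max(seg) - np.min(seg))


def normalize(
    spectrum: Spectrum,
    mode: str = "spins",
    reference: Spectrum | None = None,
    window=None,
) -> Spectrum:
    """Scale a spectrum to a reference by spin count or central-line amplitude.

    ``spins`` matches double integrals (both spectra must be
    baseline-corrected; ``window`` as in :func:`double_integral` is applied
    to both); ``central-amplitude`` matches the peak-to-peak amplitude of
    the central line.  Without a reference the statistic is scaled to 1.
    Scaling never changes spectral moments.
    """
    if mode == "spins":
        own = double_integral(spectrum, window)
        if own <= 0:
            raise DegenerateInputError("zero double integral in spins normalization")
        target = 1.0 if reference is None else double_integral(reference, window)
    elif mode == "central-amplitude":
        own = _central_pp_amplitude(spectrum)
        if own <= 0:
            raise DegenerateInputError("zero central amplitude")
        target = 1.0 if reference is None else _central_pp_amplitude(reference)
    else:
        raise ParameterError(f"unknown normalization mode {mode!r}")
    if reference is not None and not np.array_equal(
        np.shape(reference.field), np.shape(spectrum.field)
    ):
        raise GridError("reference grid length differs from spectrum")
    return spectrum.copy(intensity=spectrum.intensity * (target / own))
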
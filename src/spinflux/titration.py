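"""Dose–response assembly: mobility curves, saturation, spin–spin trends.

Takes a titration manifest (spectra keyed by LPC mol% and labeling
condition), runs preprocessing and moment statistics on every entry,
pairs maximally and minimally labeled spectra per concentration to form
Δ⟨ΔB²⟩, finds the saturation concentration of any monotone-trending
statistic, localizes the largest drop of the spin–spin term, and scores
how completely a BSA-reverted spectrum returns to the closed-state one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import GridError, SizeError
from .io import Spectrum, TitrationManifest, read_spectrum, resolve_entry_path
from .moments import MT2_TO_T2, delta_second_moment, mobility_result, signal_support
from .preprocess import baseline_correct, integrate, normalize

log = logging.getLogger(__name__)

#: default saturation tolerance: fraction of the statistic's full range
DEFAULT_SATURATION_TOL_FRACTION = 0.10

#: Δ⟨ΔB²⟩ below this (T²) counts as negligible spin–spin interaction;
#: matches the ±20e-10 T² uncertainty customary for tabulated values.
DEFAULT_NEGLIGIBLE_T2 = 20e-10


@dataclass
class TitrationSeriesResult:
    """Per-spectrum statistics plus paired Δ⟨ΔB²⟩ and the saturation point."""

    table: pd.DataFrame
    delta_table: pd.DataFrame
    saturation_molpct: float | None = None
    flags: dict = dc_field(default_factory=dict)


@dataclass
class TrendReport:
    """Largest drop of Δ⟨ΔB²⟩ along the titration and negligible values."""

    drop_interval_molpct: tuple | None
    drop_T2: float | None
    negligible_molpct: list
    threshold_T2: float


def _process_one(spectrum: Spectrum, order: int, edge_fraction: float):
    corrected, model = baseline_correct(spectrum, order, edge_fraction)
    absorption = integrate(corrected)
    return corrected, absorption, mobility_result(corrected, absorption), model


def _mixing_coordinate(corrected: dict) -> dict:
    """Two-state mixing coefficient per spectrum of one labeling condition.

    Least-squares decomposition of each derivative spectrum on the span of
    the lowest-concentration (closed) and highest-concentration (open)
    spectra, S(c) ≈ a·S_lo + b·S_hi; the coordinate is b/(a+b): 0 at the
    closed end, 1 at the open end, linear in the open fraction for a
    two-state titration, scale-invariant, and far more noise-robust than
    any doubly-integrated statistic.
    """
    concs = sorted(corrected)
    lo0, hi0 = signal_support(corrected[concs[0]])
    lo1, hi1 = signal_support(corrected[concs[-1]])
    field = corrected[concs[0]].field
    sel = (field >= min(lo0, lo1)) & (field <= max(hi0, hi1))
    n = field.size
    edge = np.r_[0 : n // 10, n - n // 10 : n]

    def noise_var(spec):
        return float(np.var(spec.intensity[edge]))

    s0 = corrected[concs[0]].intensity[sel]
    s1 = corrected[concs[-1]].intensity[sel]
    m = int(np.count_nonzero(sel))
    # errors-in-variables correction: the self-products overestimate the
    # clean Gram matrix by m·sigma² (sigma from the signal-free edges)
    g = np.array(
        [
            [s0 @ s0 - m * noise_var(corrected[concs[0]]), s0 @ s1],
            [s0 @ s1, s1 @ s1 - m * noise_var(corrected[concs[-1]])],
        ]
    )
    if g[0, 0] <= 0 or g[1, 1] <= 0:
        g = np.array([[s0 @ s0, s0 @ s1], [s0 @ s1, s1 @ s1]])
    out = {}
    for c in concs:
        y = corrected[c].intensity[sel]
        try:
            a, b = np.linalg.solve(g, np.array([s0 @ y, s1 @ y]))
        except np.linalg.LinAlgError:
            out[c] = np.nan
            continue
        out[c] = float(b / (a + b)) if (a + b) != 0 else np.nan
    return out


def build_series(
    manifest: TitrationManifest,
    order: int = 1,
    edge_fraction: float = 0.1,
    saturation_statistic: str = "mixing_coord",
    saturation_tolerance: float | None = None,
) -> TitrationSeriesResult:
    """Run preprocessing + moments over a manifest and assemble the series.

    Every entry is baseline-corrected, integrated and reduced to its
    mobility statistics (moments over the automatic signal-support
    window).  Δ⟨ΔB²⟩ is formed wherever a maximal/minimal pair exists at
    exactly the same concentration (no interpolation), over a window
    shared by the pair; a missing partner produces a warning, never a
    failure.  Each labeling condition additionally gets a two-state
    mixing coordinate, the default statistic for saturation detection
    (computed on the minimal-labeling curve when available, else the
    maximal one).
    """
    rows = []
    flags: dict = {}
    corrected_by = {}
    absorption_by = {}
    for entry in manifest.entries:
        spec = read_spectrum(resolve_entry_path(manifest, entry))
        corrected, absorption, mob, model = _process_one(spec, order, edge_fraction)
        if entry.role == "sample":
            corrected_by[(entry.lpc_molpct, entry.labeling)] = corrected
            absorption_by[(entry.lpc_molpct, entry.labeling)] = absorption
        rows.append(
            {
                "file": entry.file,
                "lpc_molpct": entry.lpc_molpct,
                "labeling": entry.labeling,
                "role": entry.role,
                "dh_pp_mT": mob.dh_pp_mT,
                "inv_dh_per_mT": mob.inv_dh_per_mT,
                "first_moment_mT": mob.first_moment_mT,
                "second_moment_mT2": mob.second_moment_mT2,
                "second_moment_T2": mob.second_moment_T2,
                "double_integral": mob.double_integral,
                "baseline_flags": ";".join(sorted(model.flags)) or "",
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["lpc_molpct", "labeling"], kind="stable", ignore_index=True
    )

    mix = {}
    for labeling in ("maximal", "minimal"):
        sub = {c: s for (c, lab), s in corrected_by.items() if lab == labeling}
        if len(sub) >= 2:
            mix[labeling] = _mixing_coordinate(sub)
    table["mixing_coord"] = [
        mix.get(r["labeling"], {}).get(r["lpc_molpct"], np.nan)
        if r["role"] == "sample"
        else np.nan
        for _, r in table.iterrows()
    ]

    deltas = []
    concs = sorted({c for c, _ in corrected_by})
    for c in concs:
        if (c, "maximal") in corrected_by and (c, "minimal") in corrected_by:
            lo_a, hi_a = signal_support(corrected_by[(c, "maximal")])
            lo_b, hi_b = signal_support(corrected_by[(c, "minimal")])
            window = (min(lo_a, lo_b), max(hi_a, hi_b))
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                dd = delta_second_moment(
                    absorption_by[(c, "maximal")],
                    absorption_by[(c, "minimal")],
                    window=window,
                )
            if dd.negative:
                flags.setdefault("negative_delta", []).append(float(c))
            deltas.append(
                {
                    "lpc_molpct": float(c),
                    "delta_mT2": dd.delta_mT2,
                    "delta_T2": dd.delta_T2,
                }
            )
        else:
            log.warning("no maximal/minimal pair at %g mol%%: delta omitted", c)
            flags.setdefault("unpaired_molpct", []).append(float(c))
    delta_table = pd.DataFrame(deltas, columns=["lpc_molpct", "delta_mT2", "delta_T2"])

    samples = table[table["role"] == "sample"]
    saturation = None
    for labeling in ("minimal", "maximal"):
        curve = samples[samples["labeling"] == labeling].dropna(
            subset=[saturation_statistic]
        )
        if len(curve) >= 4:
            saturation = saturation_point(
                curve["lpc_molpct"].to_numpy(),
                curve[saturation_statistic].to_numpy(),
                tolerance=saturation_tolerance,
            )
            break
    return TitrationSeriesResult(table, delta_table, saturation, flags)


def saturation_point(
    concentrations: np.ndarray,
    values: np.ndarray,
    tolerance: float | None = None,
    tol_fraction: float = DEFAULT_SATURATION_TOL_FRACTION,
) -> float | None:
    """Smallest concentration from which the statistic stays flat.

    A plateau is the longest tail (at least two points) whose total spread
    (max − min) does not exceed the tolerance; the default tolerance is
    ``tol_fraction`` of the statistic's full range over the series, standing
    in for an unavailable replicate-derived error estimate.  Returns the
    smallest qualifying concentration, or None when no plateau exists.
    """
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(values, dtype=float)
    if c.size < 4:
        raise SizeError("need at least 4 concentrations for saturation detection")
    order = np.argsort(c)
    c, v = c[order], v[order]
    vrange = float(np.max(v) - np.min(v))
    tol = tolerance if tolerance is not None else tol_fraction * vrange
    if vrange == 0.0:
        return float(c[0])
    for i in range(c.size - 1):
        tail = v[i:]
        if float(np.max(tail) - np.min(tail)) <= tol:
            return float(c[i])
    log.info("no plateau within the titration range (tolerance %.3g)", tol)
    return None


def interaction_trend(
    concentrations: np.ndarray,
    delta_T2: np.ndarray,
    threshold_T2: float = DEFAULT_NEGLIGIBLE_T2,
) -> TrendReport:
    """Locate the largest drop in Δ⟨ΔB²⟩ and flag negligible interaction.

    The drop interval is the pair of consecutive concentrations with the
    largest decrease; values below ``threshold_T2`` are classified as
    negligible spin–spin interaction.  A series with no decrease at all
    yields a no-drop report.
    """
    c = np.asarray(concentrations, dtype=float)
    d = np.asarray(delta_T2, dtype=float)
    if c.size < 3:
        raise SizeError("need at least 3 paired values for a trend report")
    order = np.argsort(c)
    c, d = c[order], d[order]
    drops = d[:-1] - d[1:]
    i = int(np.argmax(drops))
    if drops[i] <= 0:
        interval, drop = None, None
    else:
        interval, drop = (float(c[i]), float(c[i + 1])), float(drops[i])
    negligible = [float(cc) for cc, dd in zip(c, d) if dd < threshold_T2]
    return TrendReport(interval, drop, negligible, threshold_T2)


def reversibility_score(
    reference_closed: Spectrum,
    test: Spectrum,
    support_fraction: float = 0.02,
) -> float:
    """RMS distance of a test spectrum from the closed-state reference.

    Both derivative spectra are spin-normalized to the reference, then the
    score is the RMS of their difference divided by the reference's RMS
    amplitude, evaluated over the reference's signal support — the
    contiguous field span where the smoothed |reference| exceeds
    ``support_fraction`` of its maximum.  Restricting to the support makes
    the score independent of how much empty baseline the sweep contains.
    0 means identical; a BSA-reverted spectrum scores near 0, an open one
    scores large.
    """
    if reference_closed.field.size != test.field.size or not np.allclose(
        reference_closed.field, test.field, rtol=0, atol=1e-9
    ):
        raise GridError("spectra are on different field grids; resampling refused")
    window = signal_support(reference_closed)
    ref = normalize(reference_closed, "spins", window=window)
    tst = normalize(test, "spins", reference=ref, window=window)

    envelope = np.convolve(np.abs(ref.intensity), np.ones(9) / 9.0, mode="same")
    mask = envelope >= support_fraction * float(np.max(envelope))
    idx = np.flatnonzero(mask)
    sl = slice(int(idx[0]), int(idx[-1]) + 1)
    diff = tst.intensity[sl] - ref.intensity[sl]
    ref_rms = float(np.sqrt(np.mean(ref.intensity[sl] ** 2)))
    return float(np.sqrt(np.mean(diff**2)) / ref_rms)
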
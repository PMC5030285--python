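"""Calcein-dequenching trace analysis: % release, segmentation, rate fits.

A liposome dye-efflux experiment produces a fluorescence intensity trace
I(t).  Self-quenched calcein released through open channels dequenches, so
intensity rises toward the full-lysis value I₁₀₀.  Percent release is

    %Release = 100 · (I − I₀) / (I₁₀₀ − I₀)

with I₀ the initial background intensity.  Channels opened by a lysolipid
(LPC) addition drive an exponential approach to full release; a BSA
addition extracts the lysolipid and arrests the release immediately; a
final detergent lysis releases everything and calibrates I₁₀₀.  The
analyzer segments a trace into open / arrested intervals from the data
alone (the lysis marker is the one experimental annotation it uses, for
calibration), estimates a first-order rate per open segment, and reports
plateau times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    DegenerateInputError,
    FitQualityError,
    SizeError,
)

#: fraction of the maximum rolling slope below which a segment is "arrested"
DEFAULT_SLOPE_FRACTION = 0.05
DEFAULT_WINDOW_S = 10.0
#: fraction of the post-lysis tail used for the I100 median
LYSIS_TAIL_FRACTION = 0.10


@dataclass
class ReleaseTrace:
    """Fluorescence time series with event annotations.

    ``events`` is a list of ``(time_s, label)`` with labels in
    {"LPC", "BSA", "lysis"}.  ``i0``/``i100`` may be given explicitly;
    otherwise ``i0`` defaults to the first intensity sample and ``i100``
    is calibrated from the post-lysis tail by the analyzer.
    """

    time: np.ndarray
    intensity: np.ndarray
    events: list = dc_field(default_factory=list)
    i0: float | None = None
    i100: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise SizeError("time and intensity must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        times = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if self.i0 is not None and self.i100 is not None and self.i100 <= self.i0:
            raise ValueError("I100 must exceed I0")

    def lysis_time(self) -> float | None:
        for t, label in self.events:
            if label == "lysis":
                return float(t)
        return None


@dataclass
class Segment:
    start_s: float
    end_s: float
    kind: str  # "open" | "arrested"
    release_end_pct: float
    rate_per_s: float | None = None


@dataclass
class CycleReport:
    """Segmentation of a release trace into open / arrested intervals."""

    segments: list
    i0: float
    i100: float
    plateau_time_s: float | None = None
    flags: dict = dc_field(default_factory=dict)

    def change_points(self) -> list[float]:
        """Interior segment boundaries (s)."""
        return [s.start_s for s in self.segments[1:]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.start_s, s.end_s, s.kind, s.release_end_pct, s.rate_per_s)
                for s in self.segments
            ],
            columns=["start_s", "end_s", "kind", "release_end_pct", "rate_per_s"],
        )


def percent_release(I, i0: float, i100: float):
    """Percent of total encapsulated dye released at intensity ``I``.

    Noise can push values slightly outside [0, 100]; they are passed
    through unchanged (with a warning), never clipped.
    """
    if i100 == i0:
        raise DegenerateInputError("I100 equals I0: zero dynamic range")
    r = (np.asarray(I, dtype=float) - i0) / (i100 - i0) * 100.0
    if np.any(r < -1.0) or np.any(r > 101.0):
        warnings.warn("percent release outside [0, 100] beyond noise margin",
                      stacklevel=2)
    return r if r.ndim else float(r)


def _rolling_slope(t: np.ndarray, y: np.ndarray, half: int) -> np.ndarray:
    """Centered least-squares slope in a (2·half+1)-sample rolling window."""
    n = y.size
    w = 2 * half + 1
    dt = t[1] - t[0]
    k = (np.arange(w) - half) * dt
    weights = k / np.sum(k * k)
    full = np.convolve(y, weights[::-1], mode="same")
    # windows at the edges are truncated; fall back to one-sided estimates
    for i in range(half):
        full[i] = np.polyfit(t[: i + half + 1], y[: i + half + 1], 1)[0]
        full[n - 1 - i] = np.polyfit(t[n - 1 - i - half :], y[n - 1 - i - half :], 1)[0]
    return full


def _refine_breakpoint(t: np.ndarray, y: np.ndarray, b: int, half: int) -> int:
    """Best two-segment piecewise-linear breakpoint near index ``b``."""
    lo = max(2, b - half)
    hi = min(y.size - 2, b + half)
    best, best_sse = b, np.inf
    wlo = max(0, b - 2 * half)
    whi = min(y.size, b + 2 * half)
    for j in range(lo, hi + 1):
        sse = 0.0
        for sl in ((slice(wlo, j + 1)), (slice(j, whi))):
            ts, ys = t[sl], y[sl]
            if ts.size < 2:
                continue
            coeff = np.polyfit(ts, ys, 1)
            resid = ys - np.polyval(coeff, ts)
            sse += float(resid @ resid)
        if sse < best_sse - 1e-15:
            best_sse, best = sse, j
    return best


def detect_events(
    trace: ReleaseTrace,
    slope_threshold: float | None = None,
    window_s: float = DEFAULT_WINDOW_S,
    plateau_tolerance_pct: float = 1.0,
) -> CycleReport:
    """Segment a release trace into open and arrested intervals.

    The %-release curve is scanned with rolling linear fits of width
    ``window_s``; samples whose slope exceeds ``slope_threshold`` (default:
    5% of the maximum rolling slope) are "open", the rest "arrested".
    Each boundary is then refined by a local two-segment piecewise-linear
    fit.  Open segments long enough for a kinetic fit get a first-order
    rate estimate; the plateau time is the first time %release stays
    within ``plateau_tolerance_pct`` of its final pre-lysis value.
    """
    t, y = trace.time, trace.intensity
    i0 = trace.i0 if trace.i0 is not None else float(y[0])
    t_lysis = trace.lysis_time()
    if trace.i100 is not None:
        i100 = trace.i100
    else:
        if t_lysis is None or t_lysis >= t[-1]:
            raise CalibrationError(
                "I100 unknown and no post-lysis region to calibrate it from"
            )
        post = y[t >= t_lysis]
        tail = post[-max(1, int(round(LYSIS_TAIL_FRACTION * post.size))):]
        i100 = float(np.median(tail))
    if i100 <= i0:
        raise CalibrationError("calibrated I100 does not exceed I0")

    # analysis region: everything before lysis
    end = int(np.searchsorted(t, t_lysis)) if t_lysis is not None else t.size
    if end < 4:
        raise SizeError("trace too short before lysis")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = percent_release(y[:end], i0, i100)
    tt = t[:end]
    dt = float(tt[1] - tt[0])
    half = max(2, int(round(window_s / dt / 2)))
    if tt.size < 2 * (2 * half + 1):
        raise SizeError("trace must cover at least two rolling windows")

    slope = _rolling_slope(tt, r, half)
    thr = slope_threshold
    if thr is None:
        thr = DEFAULT_SLOPE_FRACTION * float(np.max(slope)) if np.max(slope) > 0 else 0.0
    open_mask = slope > thr if thr > 0 else np.zeros_like(slope, dtype=bool)

    # raw boundaries from the classification, then morphological cleaning:
    # drop state flips shorter than half a window
    bounds = list(np.flatnonzero(np.diff(open_mask.astype(int))) + 1)
    min_len = half
    cleaned: list[int] = []
    for bidx in bounds:
        if cleaned and bidx - cleaned[-1] < min_len:
            cleaned.pop()
        else:
            cleaned.append(bidx)
    bounds = [_refine_breakpoint(tt, r, bidx, half) for bidx in cleaned]
    bounds = sorted(set(b for b in bounds if 0 < b < tt.size - 1))

    edges = [0] + bounds + [tt.size - 1]
    segments: list[Segment] = []
    for a, b in zip(edges[:-1], edges[1:]):
        mid = slice(a, b + 1)
        kind = "open" if np.median(slope[mid]) > thr and thr > 0 else "arrested"
        seg = Segment(
            start_s=float(tt[a]),
            end_s=float(tt[b]),
            kind=kind,
            release_end_pct=float(r[b]),
        )
        if kind == "open" and (b - a + 1) >= 10 and r[b] > r[a]:
            try:
                seg.rate_per_s = estimate_rate(tt[mid], r[mid])
            except FitQualityError:
                seg.rate_per_s = None
        elif kind == "arrested":
            seg.rate_per_s = float(np.polyfit(tt[mid], r[mid], 1)[0])
        segments.append(seg)

    r_final = float(r[-1])
    within = np.abs(r - r_final) <= plateau_tolerance_pct
    plateau_time = None
    # first index from which the release stays inside the band
    outside = np.flatnonzero(~within)
    first_in = (outside[-1] + 1) if outside.size else 0
    if first_in < tt.size:
        plateau_time = float(tt[first_in])

    flags = {}
    rel = np.diff([s.release_end_pct for s in segments])
    if np.any(rel < -plateau_tolerance_pct):
        flags["nonmonotone_release"] = True
    return CycleReport(segments, i0=i0, i100=i100, plateau_time_s=plateau_time,
                       flags=flags)


def estimate_rate(
    time: np.ndarray, release_pct: np.ndarray, r_inf: float = 100.0
) -> float:
    """First-order rate constant of an open segment (s⁻¹).

    Fits log(1 − R/R∞) against time by weighted least squares, with
    weights proportional to (1 − R/R∞) so that points approaching the
    asymptote — whose log is noise-dominated — contribute according to
    their actual information content.  R∞ defaults to 100%, the model
    asymptote of complete release, and can be replaced by a
    segment-specific or pre-lysis plateau value.  Points within 2% of the
    asymptote are excluded entirely.
    """
    t = np.asarray(time, float)
    r = np.asarray(release_pct, float)
    if t.size < 10:
        raise FitQualityError("need at least 10 points for a rate fit")
    span = r[-1] - r[0]
    if span <= 0:
        raise FitQualityError(
            f"non-positive release span ({span:.3g}%): segment not opening"
        )
    frac = 1.0 - r / r_inf
    mask = frac > 0.02
    if np.count_nonzero(mask) < 10:
        raise FitQualityError("too few points below the asymptote for a fit")
    slope, _ = np.polyfit(t[mask], np.log(frac[mask]), 1, w=frac[mask])
    k = -float(slope)
    if k <= 0:
        raise FitQualityError(f"non-positive fitted rate ({k:.3g} s⁻¹)")
    return k


def read_trace(path: str, events_path: str | None = None) -> ReleaseTrace:
    """Load a trace CSV (time_s, intensity) plus an optional events CSV."""
    df = pd.read_csv(path)
    if not {"time_s", "intensity"} <= set(df.columns):
        raise SizeError(f"{path}: expected columns time_s, intensity")
    events: list = []
    if events_path is not None:
        ev = pd.read_csv(events_path)
        events = [(float(r.time_s), str(r.label)) for r in ev.itertuples()]
        events.sort(key=lambda e: e[0])
    return ReleaseTrace(df["time_s"].to_numpy(), df["intensity"].to_numpy(), events)


def write_trace(trace: ReleaseTrace, path: str, events_path: str | None = None) -> str:
    pd.DataFrame({"time_s": trace.time, "intensity": trace.intensity}).to_csv(
        path, index=False
    )
    if events_path is not None and trace.events:
        pd.DataFrame(trace.events, columns=["time_s", "label"]).to_csv(
            events_path, index=False
        )
    return path
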
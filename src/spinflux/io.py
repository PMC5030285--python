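"""Plain-text I/O for cw-EPR spectra and titration manifests.

Native spectrum dialect
-----------------------
Header lines of the form ``#key: value`` (one per metadata key), then two
whitespace-delimited numeric columns: field in mT, first-derivative
intensity in arbitrary units.  Numbers are printed with 17 significant
digits (the float64 round-trip precision); the precision is recorded in the
file itself under the ``precision`` key.

Fields are magnetic fields, always in mT internally.  Callers holding data
in gauss must convert first (1 G = 0.1 mT); no unit sniffing is attempted.
Spectra are functions of field, never of frequency, and no resampling is
ever performed implicitly.

Manifests are CSV with the header row ``file,lpc_molpct,labeling,role``
mapping spectrum files to LPC mol% (relative to lipid), labeling condition
(``maximal`` | ``minimal``) and sample role.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import GridError, SizeError, SpectrumFormatError

#: Metadata keys that must be present (or explicitly "unknown") on every
#: validated spectrum: microwave frequency, modulation amplitude, scans.
REQUIRED_META = ("mw_freq_GHz", "mod_amp_mT", "scans")

#: Additional keys the acquisition normally carries.
KNOWN_META = REQUIRED_META + ("mod_freq_kHz", "temperature", "label", "precision")

MIN_POINTS = 64
GRID_RTOL = 1e-9
_FMT = "%.17g"

LABELING_TOKENS = ("maximal", "minimal")
ROLE_TOKENS = ("sample", "reference", "closed-control", "BSA-reverted")


def _validate_grid(field: np.ndarray) -> float:
    """Return the uniform spacing, raising on any grid violation."""
    if field.ndim != 1 or field.size < MIN_POINTS:
        raise SizeError(f"need at least {MIN_POINTS} points, got {field.size}")
    d = np.diff(field)
    if np.any(d <= 0):
        raise GridError("field values must be strictly increasing")
    dm = float(np.mean(d))
    if np.max(np.abs(d - dm)) > GRID_RTOL * dm:
        raise GridError(
            f"field grid not uniform: spacing varies by more than "
            f"{GRID_RTOL:g} relative"
        )
    return dm


@dataclass
class Spectrum:
    """First-derivative cw-EPR trace on a uniform field grid.

    Attributes
    ----------
    field:
        Magnetic field values in mT, strictly increasing, uniformly spaced.
    intensity:
        First-derivative signal, arbitrary units, same length as ``field``.
    meta:
        Acquisition metadata.  The keys in :data:`REQUIRED_META` are always
        present after validation; missing ones are set to ``"unknown"``
        rather than silently defaulted.
    """

    field: np.ndarray
    intensity: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.field.shape != self.intensity.shape:
            raise SizeError("field and intensity must have equal length")
        _validate_grid(self.field)
        for key in REQUIRED_META:
            self.meta.setdefault(key, "unknown")

    @property
    def spacing(self) -> float:
        """Uniform grid spacing in mT."""
        return float(self.field[1] - self.field[0])

    @property
    def window(self) -> tuple[float, float]:
        """(low, high) bounds of the acquisition window in mT."""
        return float(self.field[0]), float(self.field[-1])

    def copy(self, intensity: np.ndarray | None = None) -> "Spectrum":
        new_int = self.intensity if intensity is None else np.asarray(intensity, float)
        return Spectrum(self.field.copy(), new_int.copy(), dict(self.meta))


@dataclass
class AbsorptionSpectrum:
    """Single-integrated (absorption-mode) spectrum on the source grid."""

    field: np.ndarray
    absorption: np.ndarray
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        self.absorption = np.asarray(self.absorption, dtype=float)
        if self.field.shape != self.absorption.shape:
            raise SizeError("field and absorption must have equal length")
        _validate_grid(self.field)


@dataclass
class ManifestEntry:
    file: str
    lpc_molpct: float
    labeling: str
    role: str = "sample"


@dataclass
class TitrationManifest:
    """Ordered mapping of spectrum files to LPC mol% and labeling condition."""

    entries: list
    path: str | None = None

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.lpc_molpct < 0:
                raise ValueError(f"negative LPC mol% for {e.file}")
            if e.labeling not in LABELING_TOKENS:
                raise SpectrumFormatError(f"unknown labeling token {e.labeling!r}")
            if e.role not in ROLE_TOKENS:
                raise SpectrumFormatError(f"unknown role token {e.role!r}")
        n_ref = sum(e.role == "reference" for e in self.entries)
        if n_ref > 1:
            raise ValueError("at most one reference entry per analysis group")
        self.entries = sorted(
            self.entries, key=lambda e: (e.lpc_molpct, e.labeling, e.file)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.file, e.lpc_molpct, e.labeling, e.role) for e in self.entries],
            columns=["file", "lpc_molpct", "labeling", "role"],
        )


def _parse_meta_value(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def read_spectrum(path: str, dialect: str = "native") -> Spectrum:
    """Read a spectrum file in the package's native two-column dialect.

    Raises
    ------
    SpectrumFormatError
        On an unknown dialect or an unparseable line (named by number).
    GridError, SizeError
        When the validated grid invariants are violated.
    """
    if dialect != "native":
        raise SpectrumFormatError(f"unknown dialect {dialect!r}")
    meta: dict = {}
    fields: list[float] = []
    intens: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = _parse_meta_value(value.strip())
                continue
            parts = line.split()
            if len(parts) != 2:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                fields.append(float(parts[0]))
                intens.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: unparseable number ({exc})"
                ) from None
    return Spectrum(np.asarray(fields), np.asarray(intens), meta)


def write_spectrum(spectrum: Spectrum, path: str) -> str:
    """Write a spectrum in the native dialect; returns the path written.

    One ``#key: value`` line is emitted per metadata key; a ``precision``
    key documenting the numeric format is added once if absent.  Writing
    the same spectrum twice produces byte-identical files.
    """
    meta = dict(spectrum.meta)
    meta.setdefault("precision", _FMT)
    lines = [f"#{k}: {v}\n" for k, v in meta.items()]
    for b, y in zip(spectrum.field, spectrum.intensity):
        lines.append(f"{b:.17g} {y:.17g}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.writelines(lines)
    return path


def read_manifest(path: str) -> TitrationManifest:
    """Load a titration manifest CSV; rows are returned sorted by LPC mol%."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SpectrumFormatError(f"{path}: empty manifest") from None
    required = {"file", "lpc_molpct", "labeling", "role"}
    missing = required - set(df.columns)
    if missing:
        raise SpectrumFormatError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise SpectrumFormatError(f"{path}: manifest has no rows")
    entries = [
        ManifestEntry(
            file=str(r.file),
            lpc_molpct=float(r.lpc_molpct),
            labeling=str(r.labeling),
            role=str(r.role),
        )
        for r in df.itertuples()
    ]
    return TitrationManifest(entries, path=path)


def write_manifest(manifest: TitrationManifest, path: str) -> str:
    manifest.to_frame().to_csv(path, index=False)
    return path


def resolve_entry_path(manifest: TitrationManifest, entry: ManifestEntry) -> str:
    """Resolve an entry's file relative to the manifest location."""
    if os.path.isabs(entry.file) or manifest.path is None:
        return entry.file
    return os.path.join(os.path.dirname(os.path.abspath(manifest.path)), entry.file)
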
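"""Exception hierarchy shared across the package."""


class SpinfluxError(Exception):
    """Base class for all package errors."""


class GridError(SpinfluxError):
    """Field grid is not strictly increasing / not uniform / mismatched."""


class SizeError(SpinfluxError):
    """Too few points to form a valid spectrum or segment."""


class SpectrumFormatError(SpinfluxError):
    """Unparseable spectrum or manifest file content."""


class WindowError(SpinfluxError):
    """Requested kernel or search window does not fit the field sweep."""


class ParameterError(SpinfluxError):
    """Invalid processing parameter (baseline order, edge fraction, ...)."""


class BaselineError(SpinfluxError):
    """Baseline correction failed, e.g. negative double integral."""


class DegenerateInputError(SpinfluxError):
    """Zero-area / zero-amplitude spectrum where a ratio is required."""


class ResolutionError(SpinfluxError):
    """No resolvable central line (max/min pair) in the search window."""


class ScheduleError(SpinfluxError):
    """Invalid event schedule for a release-trace simulation."""


class CalibrationError(SpinfluxError):
    """Missing post-lysis region: the 100%-release intensity is unknown."""


class FitQualityError(SpinfluxError):
    """Kinetic fit rejected (non-monotone segment, too few points, ...)."""
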
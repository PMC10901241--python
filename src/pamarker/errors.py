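"""Exception hierarchy shared across the toolkit."""


class PamarkerError(Exception):
    """Base class for all toolkit errors."""


class InvalidParameterError(PamarkerError, ValueError):
    """A function argument violates its contract (non-positive pitch, bad enum, ...)."""


class InvalidGeometryError(PamarkerError, ValueError):
    """Source/element configuration is physically degenerate (e.g. zero distance)."""


class FormatError(PamarkerError, ValueError):
    """A persisted container is missing a dataset or attribute; the message names it."""


class NoPeakError(PamarkerError, ValueError):
    """Raised when a peak/feature query is made on an all-zero image."""


class CoverageWarning(UserWarning):
    """Part of the reconstruction grid is unreachable within the recorded time window."""
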
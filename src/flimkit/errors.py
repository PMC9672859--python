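"""Exception hierarchy for flimkit.

Every error raised by the library derives from :class:`FlimError`, so
callers (and the CLI) can distinguish library failures from programming
errors with a single ``except`` clause.
"""


class FlimError(Exception):
    """Base class for all flimkit errors."""


class InvalidGridError(FlimError):
    """Time grid is non-uniform, too short, or otherwise unusable."""


class InvalidParameterError(FlimError):
    """A model or fit parameter is outside its valid domain."""


class GridMismatchError(FlimError):
    """Two histograms/curves that must share a grid do not."""


class LowCountsError(FlimError):
    """Not enough photons for the requested fit."""


class DegenerateRangeError(FlimError):
    """Endpoint sweep has fewer than two candidate endpoints."""


class FitFailureError(FlimError):
    """A fit that the pipeline cannot proceed without failed to converge."""


class PtuFormatError(FlimError):
    """A PTU file is malformed, truncated, or of an unsupported type."""


class ReconstructionError(FlimError):
    """Photon-to-pixel assignment failed (e.g. unbalanced line markers)."""


class CsvFormatError(FlimError):
    """A decay CSV file is malformed."""


class SceneConfigError(FlimError):
    """A synthetic scene configuration is invalid (e.g. overlapping ROIs)."""


class CoordinateError(FlimError):
    """A segment references pixels outside the image bounds."""
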
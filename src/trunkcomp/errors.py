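"""Exception hierarchy.

Precondition violations raise; degenerate-but-legal outcomes (an empty
segmentation, a failed mixture fit with a documented fallback) are returned
as flagged results instead, so batch runs can skip bad inputs without
corrupting the cohort table.
"""


class TrunkCompError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(TrunkCompError):
    """A phantom/cohort specification violates its invariants."""


class GeometryConflictError(InvalidSpecError):
    """Two phantom compartments overlap after rasterization."""


class FormatIntegrityError(TrunkCompError):
    """An image file or series is internally inconsistent (mixed series,
    missing spacing metadata, shape mismatch)."""


class DegeneratePolygonError(TrunkCompError):
    """An ROI polygon has fewer than three vertices."""


class BoundsError(TrunkCompError, IndexError):
    """A slice index is outside the volume."""


class EmptySegmentationError(TrunkCompError):
    """Raised only when the caller requires a non-empty mask; pipelines
    receive a flagged zero-area result instead."""


class DegenerateFitError(TrunkCompError):
    """The ROI histogram does not contain two separable populations."""


class FitFailureError(TrunkCompError):
    """Damped least squares did not converge; carries the last iterate."""

    def __init__(self, message, last_fit=None):
        super().__init__(message)
        self.last_fit = last_fit


class NoSeedError(TrunkCompError):
    """Region growing was started with an empty seed set."""


class InvalidPairsError(TrunkCompError):
    """Paired-method input lists have unequal length or fewer than 2 pairs."""


class ReferentialIntegrityError(TrunkCompError):
    """A segmentation result references an unknown subject."""


class DuplicateMeasurementError(TrunkCompError):
    """Two results share the same (subject, level, method) key."""


class ConfigError(TrunkCompError):
    """A run configuration failed validation before any compute."""
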
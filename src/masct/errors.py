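"""Exception hierarchy for the masct pipeline.

Every stage raises a subclass of :class:`MasctError` so callers can tag
failures with the stage they came from without string matching.
"""


class MasctError(Exception):
    """Base class for all masct errors."""


class GeometryError(MasctError):
    """Invalid or incompatible image geometry (spacing, orientation, grids)."""


class SegmentationError(MasctError):
    """A segmentation step produced an empty or degenerate result."""


class RegistrationError(MasctError):
    """Registration optimizer diverged or produced a non-finite objective."""


class InversionError(MasctError):
    """Deformation-field inversion failed to reach the residual tolerance."""

    def __init__(self, message: str, residual_mm: float | None = None):
        super().__init__(message)
        self.residual_mm = residual_mm


class UndefinedMetricError(MasctError):
    """A metric was requested on an empty/undefined domain (empty region,
    all voxels excluded by a dose floor, ...)."""


class UsageError(MasctError, ValueError):
    """Caller violated an interface contract (mismatched counts, bad config)."""


class SpecError(MasctError, ValueError):
    """A phantom or beam specification is internally inconsistent."""


class DataError(MasctError):
    """Input data contains values outside the declared domain."""
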
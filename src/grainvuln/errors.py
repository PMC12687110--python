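"""Exception hierarchy shared across the pipeline.

All errors derive from :class:`GrainVulnError` so callers can catch the
package's failures with one clause while letting programming errors
(``TypeError`` etc.) propagate.
"""


class GrainVulnError(Exception):
    """Base class for all errors raised by grainvuln."""


class InvalidArgumentError(GrainVulnError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(GrainVulnError):
    """Input data carry no usable signal (e.g. zero variance, no pairs)."""


class DegenerateNicheError(GrainVulnError):
    """The niche covariance matrix is singular or not positive definite."""


class InsufficientDataError(GrainVulnError):
    """Too few records/pixels/grains to proceed.

    Carries ``count`` so callers can report how much data was available.
    """

    def __init__(self, message: str, count: int | None = None):
        super().__init__(message)
        self.count = count


class MissingLayerError(GrainVulnError):
    """A required (variable, year, month) environmental layer is absent."""


class ScenarioMismatchError(GrainVulnError):
    """A virtual species cannot be sampled on the given landscape."""


class GridParseError(GrainVulnError):
    """A grid file does not conform to its declared format."""


class StageError(GrainVulnError):
    """A pipeline stage failed; wraps the cause with grain and stage tags."""

    def __init__(self, stage: str, grain_km: float, cause: Exception):
        super().__init__(f"stage {stage!r} failed at grain {grain_km} km: {cause}")
        self.stage = stage
        self.grain_km = grain_km
        self.cause = cause
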
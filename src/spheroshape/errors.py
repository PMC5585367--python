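"""Exception hierarchy for the spheroid analysis pipeline.

Every failure mode a batch driver needs to distinguish gets its own class;
``analyze`` tags exceptions with the pipeline stage that raised them so
per-image error rows can say where a well failed.
"""


class SpheroShapeError(Exception):
    """Base class for all pipeline errors.

    Attributes
    ----------
    stage : str or None
        Name of the pipeline stage that raised the error, filled in by
        :func:`spheroshape.morphometry.analyze`.
    """

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message)
        self.stage = stage

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        return f"[{self.stage}] {base}" if self.stage else base


class ValidationError(SpheroShapeError):
    """Input data violates a documented precondition or invariant."""


class NoSpheroidFoundError(SpheroShapeError):
    """Segmentation found no foreground component of sufficient size."""


class ClippedSpheroidError(SpheroShapeError):
    """The main component touches the image border; the spheroid is cut off."""


class DegenerateContourError(SpheroShapeError):
    """The component is too thin or its boundary self-intersects."""


class DegenerateCircleFitError(SpheroShapeError):
    """Circle fitting failed (e.g. collinear border points)."""


class InsufficientPointsError(SpheroShapeError):
    """Too few points for a discrepancy / correlation computation."""
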
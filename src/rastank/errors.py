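"""Exception hierarchy shared across the package."""


class RastankError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(RastankError, ValueError):
    """An argument violates a documented precondition."""


class InfeasibleGeometryError(RastankError):
    """The requested scene geometry cannot be populated (e.g. barrier fills the tank)."""


class InfeasibleConstraintError(RastankError):
    """A dataset constraint cannot be satisfied (e.g. not enough real images)."""


class NumericalFailureError(RastankError):
    """Non-finite values appeared during integration."""

    def __init__(self, message: str, fish_index: int | None = None):
        super().__init__(message)
        self.fish_index = fish_index


class FormatError(RastankError):
    """A file does not conform to the expected layered-image or COCO structure."""


class UnsupportedFormatError(RastankError):
    """A serialization format is recognised but not available in this build."""


class UndefinedMetricError(RastankError):
    """A metric is undefined for the given inputs (e.g. AP with zero ground truth)."""
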
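"""Exception hierarchy shared across the package."""


class GeoprevError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(GeoprevError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(GeoprevError, ValueError):
    """An input file does not conform to the expected schema."""


class GeometryError(GeoprevError, ValueError):
    """A geometry is invalid or unusable for the requested operation."""


class UnassignedChildError(GeoprevError, ValueError):
    """Child units could not be assigned to any parent unit."""

    def __init__(self, unit_ids):
        self.unit_ids = list(unit_ids)
        super().__init__(
            f"child centroids fall outside all parents: {self.unit_ids}"
        )


class DegenerateInputError(GeoprevError, ValueError):
    """Input has zero variance or is otherwise statistically degenerate."""


class UndefinedPrevalenceError(GeoprevError, ValueError):
    """Prevalence is undefined (non-positive population)."""
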
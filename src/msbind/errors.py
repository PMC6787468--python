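"""Exception types used across the package."""


class MSBindError(Exception):
    """Base class for all package-specific errors."""


class InputError(MSBindError, ValueError):
    """A parameter violates a precondition (negative concentration, Kd <= 0, ...)."""


class FitError(MSBindError, ValueError):
    """Calibration fit impossible (too few points, zero spread, non-positive slope)."""


class UndefinedRatioError(MSBindError, ZeroDivisionError):
    """A normalising denominator (control binding, control specific binding) is <= 0."""


class SchemaError(MSBindError, ValueError):
    """A measurement or library table violates the expected schema."""


class MissingConditionError(SchemaError):
    """A sublibrary lacks rows for a required assay condition."""

    def __init__(self, sublibrary_id: str, condition: str):
        self.sublibrary_id = sublibrary_id
        self.condition = condition
        super().__init__(
            f"sublibrary {sublibrary_id!r} has no rows for condition {condition!r}"
        )
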
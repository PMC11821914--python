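"""Exception types raised across the pipeline."""


class MemquantError(Exception):
    """Base class for all package errors."""


class UnitError(MemquantError, ValueError):
    """Missing, non-positive, or inconsistent physical-unit metadata."""


class SchemaError(MemquantError, ValueError):
    """A table, annotation, or config file does not match its documented schema."""


class UnsupportedROIError(SchemaError):
    """An ImageJ ROI that is not a polyline (polygon, point, oval, ...)."""


class ParameterError(MemquantError, ValueError):
    """An analysis parameter outside its valid range, or an infeasible request."""


class DegenerateInputError(MemquantError, ValueError):
    """Input carries no usable signal (all-zero image, empty mask, ...)."""


class NoSignalError(DegenerateInputError):
    """FRC curve already below threshold at the lowest frequency ring."""


class RegistrationError(MemquantError, RuntimeError):
    """Image registration failed to find a trustworthy transform."""


class UnresolvedWallsError(MemquantError, ValueError):
    """Transverse profile has no two distinct wall peaks (structure below resolution)."""
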
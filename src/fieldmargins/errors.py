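"""Exception hierarchy shared across the package."""


class FieldmarginsError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FieldmarginsError, ValueError):
    """A table is missing required columns or has unparseable values."""


class ValidationError(FieldmarginsError, ValueError):
    """Records violate an invariant (range, enum membership, uniqueness)."""


class ConfigError(FieldmarginsError, ValueError):
    """A simulation or analysis configuration is inconsistent."""


class EmptyInputError(FieldmarginsError, ValueError):
    """An operation received an empty record collection."""


class AlignmentError(FieldmarginsError, ValueError):
    """Two matrices that must share a sampling-point set do not."""


class DegenerateModelError(FieldmarginsError, ValueError):
    """A model cannot be fitted (constant response, zero-variance predictor)."""


class UndefinedDiversityError(FieldmarginsError, ValueError):
    """Diversity requested for a sample with no positive abundances."""
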
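"""Exception hierarchy for the heatstrain pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, data errors -> 3,
reproduction mismatch -> 4.
"""


class HeatstrainError(Exception):
    """Base class for all package-specific errors."""


class DomainError(HeatstrainError, ValueError):
    """Input outside the mathematical domain of an operation (e.g. NaN)."""


class EmptyInputError(HeatstrainError, ValueError):
    """An operation received an empty series or cohort."""


class OrderingError(HeatstrainError, ValueError):
    """Time-ordered input was not sorted or contained duplicates."""


class SchemaError(HeatstrainError, ValueError):
    """A CSV/config file did not match the expected schema."""


class ConfigError(HeatstrainError, ValueError):
    """A configuration value violated its invariants."""


class CoverageError(HeatstrainError, ValueError):
    """Weather data does not cover the window required by a case."""


class IncompleteCaseError(HeatstrainError, ValueError):
    """A worker case is missing a field required by the operation."""


class IntegrityError(HeatstrainError, RuntimeError):
    """A packaged fixture failed its checksum."""


class ReproductionMismatch(HeatstrainError, RuntimeError):
    """Recomputed cohort statistics disagree with the reference values."""
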
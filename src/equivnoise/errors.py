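"""Exception hierarchy shared across the package."""


class EquivNoiseError(Exception):
    """Base class for all package-specific errors."""


class ParameterDomainError(EquivNoiseError, ValueError):
    """A model parameter violates its mathematical domain."""


class ConfigurationError(EquivNoiseError, ValueError):
    """A task/staircase configuration is internally inconsistent."""


class NumericalDegeneracyError(EquivNoiseError, ArithmeticError):
    """A computation lost all numerical mass or rank."""


class IncompleteInputError(EquivNoiseError, ValueError):
    """Required inputs for an analysis stage are missing."""


class SchemaError(EquivNoiseError, ValueError):
    """A CSV/YAML document does not match the expected schema."""
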
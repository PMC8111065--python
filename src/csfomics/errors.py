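"""Exception hierarchy shared across the package."""


class CsfomicsError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CsfomicsError):
    """Invalid configuration (bad field values, unknown feature names)."""


class DomainError(CsfomicsError, ValueError):
    """Input outside the mathematical domain of an operation."""


class DegenerateLabelError(DomainError):
    """A two-class operation received labels from fewer than two classes."""


class RankError(DomainError):
    """More latent components requested than the data rank supports."""


class CoverageError(DomainError):
    """A spectrum does not cover the requested chemical-shift range."""


class SchemaError(CsfomicsError):
    """Tabular input does not match the expected schema."""


class DataError(CsfomicsError):
    """Malformed data file (missing cells, inconsistent dimensions)."""


class PipelineError(CsfomicsError):
    """A pipeline stage failed; partial outputs are retained."""
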
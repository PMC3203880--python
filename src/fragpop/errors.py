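"""Exception hierarchy shared across the package."""


class FragpopError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FragpopError):
    """Malformed input file (bad FASTA/TSV structure, duplicate ids, ...)."""


class AlignmentError(FragpopError):
    """Sequences that do not form a valid alignment (ragged lengths, empty)."""


class ValidationError(FragpopError):
    """Cross-object consistency failure (alignment ids vs sample table, ...)."""


class DegenerateInputError(FragpopError):
    """Input too small or too uniform for the requested statistic."""


class ConfigError(FragpopError):
    """Invalid simulation or pipeline configuration."""


class InsufficientAcceptanceError(FragpopError):
    """Rejection-ABC retained too few samples for a trustworthy posterior."""
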
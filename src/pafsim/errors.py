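"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (config 2, alignment 3, IO 4), so new
error types should subclass one of the classes below rather than raising
bare ValueError from public entry points.
"""


class PafsimError(Exception):
    """Base class for all package errors."""


class DomainError(PafsimError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class ConfigError(PafsimError, ValueError):
    """A run configuration is missing, malformed, or internally inconsistent."""


class AlignmentError(PafsimError, ValueError):
    """Stratified tables do not share the same sex/age strata."""


class CoverageError(PafsimError, ValueError):
    """A rate table does not cover every age group of the standard population."""


class EstimationError(PafsimError, ValueError):
    """A summary statistic cannot be estimated (e.g. an empty stratum)."""
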
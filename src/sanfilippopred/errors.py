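"""Exception hierarchy.

CLI exit-code mapping: ConfigError -> 2, DataError (and subclasses) -> 3,
NumericalError -> 4.
"""


class SanfilippoPredError(Exception):
    """Base class for all package errors."""


class ConfigError(SanfilippoPredError):
    """Invalid configuration (bad chain settings, unsupported K, ...)."""


class DataError(SanfilippoPredError):
    """Invalid or inconsistent input data."""


class SchemaError(DataError):
    """A required column is missing or a cell cannot be parsed."""


class RangeError(DataError):
    """A score value violates its admissible range."""


class StratificationError(DataError):
    """A stratified split was requested on single-class data."""


class ImputationError(DataError):
    """Imputation cannot proceed (e.g. a column with no observed values)."""


class NumericalError(SanfilippoPredError):
    """A numerical failure (singular covariance, failed factorization)."""
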
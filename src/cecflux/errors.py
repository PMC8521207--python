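"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataValidationError`` (and its
subclasses raised by parsers) to exit code 3.
"""


class CecfluxError(Exception):
    """Base class for all errors raised by cecflux."""


class ConfigError(CecfluxError):
    """Invalid configuration: bad parameter values, missing files, method
    requested without the wells/reads it needs."""


class DataValidationError(CecfluxError):
    """Input data violates the assay's structural contract."""


class PlateParseError(DataValidationError):
    """A plate-reader export could not be parsed; message carries the
    row/column location where parsing failed."""


class LayoutError(DataValidationError):
    """A plate layout violates the well-role contract (missing roles,
    wrong replicate counts, plate-id mismatches)."""
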
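"""Exception hierarchy.

User-facing errors (bad input files, bad configuration) derive from
:class:`UserInputError` so the CLI can map them to exit status 2;
everything else surfaces as an internal error (exit status 1).
"""


class AnnopipeError(Exception):
    """Base class for all package errors."""


class UserInputError(AnnopipeError):
    """Invalid input data or configuration supplied by the caller."""


class FormatError(UserInputError):
    """A file does not conform to its declared format."""


class AlphabetError(FormatError):
    """A sequence contains residues outside its declared alphabet."""


class DuplicateIdError(FormatError):
    """Two records in one file share an identifier."""


class ConfigError(UserInputError):
    """Invalid run configuration (flags, database specs, thresholds)."""


class ConsistencyError(AnnopipeError):
    """Two data structures that must agree (e.g. clusters vs queries) do not."""


class CalibrationError(AnnopipeError):
    """Score-statistics calibration failed (e.g. degenerate null scores)."""
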
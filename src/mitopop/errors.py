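"""Exception hierarchy shared across the pipeline stages.

Each stage raises a subclass of :class:`MitopopError` so the CLI can map
failures to exit codes per error class.
"""


class MitopopError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class AlignmentError(MitopopError):
    """Sequences of unequal length or otherwise malformed alignment."""

    exit_code = 2


class MetadataError(MitopopError):
    """Sample metadata missing, inconsistent, or carrying unknown labels."""

    exit_code = 3


class CoordinateError(MitopopError):
    """A requested window falls outside the reference span."""

    exit_code = 4


class InsufficientDataError(MitopopError):
    """Too few sequences/values for the requested statistic."""

    exit_code = 5


class ConfigurationError(MitopopError):
    """Invalid or missing configuration (motifs, weights, run config)."""

    exit_code = 6


class AssignmentError(MitopopError):
    """A haplotype or sample lacks a required group/clade assignment."""

    exit_code = 7


class DesignError(MitopopError):
    """An AMOVA design violates its structural preconditions."""

    exit_code = 8


class DomainError(MitopopError):
    """A numeric parameter outside its mathematical domain."""

    exit_code = 9


class FormatError(MitopopError):
    """Unknown export format or malformed input table."""

    exit_code = 10
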
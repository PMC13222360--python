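"""Exception hierarchy for the flyway pipeline.

Every stage raises a subclass of :class:`FlywayError` so callers (and the
CLI) can distinguish configuration problems, malformed inputs and
scientifically degenerate situations from programming errors.
"""


class FlywayError(Exception):
    """Base class for all package errors."""


class ConfigError(FlywayError):
    """A configuration field is invalid; the message names the field."""


class FormatError(FlywayError):
    """An input file does not conform to the expected dialect."""


class EmptyInputError(FlywayError):
    """An input file or table contains no usable rows."""


class InsufficientDataError(FlywayError):
    """Too few fixes/observations for the requested operation."""


class NoWinteringSiteError(FlywayError):
    """No residency longer than the minimum wintering stay was found."""


class NoMigrationError(FlywayError):
    """The bird never left the site buffer; no migration signal."""


class SegmentationError(FlywayError):
    """The annual cycle could not be resolved; message carries diagnostics."""


class DegenerateVarianceError(FlywayError):
    """The response is constant (or all-zero counts): variance ratio undefined."""


class AliasingError(FlywayError):
    """Rank-deficient fixed-effect design; message lists aliased columns."""


class InestimableError(FlywayError):
    """No individual has repeated observations: variance components inestimable."""


class ContrastError(FlywayError):
    """A contrast requires both factor levels to be present."""
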
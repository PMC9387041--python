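"""Exception hierarchy shared across the package.

The CLI maps :class:`ValidationError` to exit code 2 and
:class:`DegenerateDataError` to exit code 3.
"""


class ActiscoreError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ActiscoreError):
    """Invalid input: bad file contents, out-of-range values, wrong sizes."""


class ParseError(ValidationError):
    """A file could not be parsed; the message names the offending row."""


class AlignmentError(ValidationError):
    """Hypnogram and activity series do not share a start anchor."""


class DegenerateDataError(ActiscoreError):
    """Structurally valid data that the method cannot operate on
    (single-class training set, no sleep onset where one is required,
    non-rescalable discriminant)."""
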
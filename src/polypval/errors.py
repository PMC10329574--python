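"""Exception hierarchy.

Every error raised by the toolkit derives from :class:`PolypValError` and
carries an ``exit_code`` so the CLI can map failure classes to distinct
process exit codes.
"""


class PolypValError(Exception):
    """Base class for all toolkit errors."""

    exit_code = 1


class FormatError(PolypValError):
    """A file could not be parsed into the expected on-disk dialect."""

    exit_code = 3


class ReferentialIntegrityError(PolypValError):
    """A record points at an image/prediction that does not exist."""

    exit_code = 4


class ValidationError(PolypValError):
    """An in-memory object violates a data-model invariant."""

    exit_code = 5


class UndefinedValueError(PolypValError):
    """A metric is undefined on the given scope (e.g. PPV with no predictions)."""

    exit_code = 6


class UsageError(PolypValError):
    """The caller combined arguments in an unsupported way."""

    exit_code = 2


class GenerationError(PolypValError):
    """The synthetic generator cannot realize the requested configuration."""

    exit_code = 7
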
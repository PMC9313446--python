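"""Exception hierarchy shared across the package.

All errors derive from :class:`LaneLapseError` so callers can catch the
package's failures with a single except clause, while each class also
subclasses the closest builtin (ValueError, LookupError, KeyError) so that
generic handling keeps working.
"""


class LaneLapseError(Exception):
    """Base class for all lanelapse errors."""


class InvalidParameterError(LaneLapseError, ValueError):
    """A parameter violates its documented precondition."""


class OutOfRangeError(InvalidParameterError):
    """A time or index falls outside the valid interval."""


class SessionFormatError(LaneLapseError, ValueError):
    """A session or manifest file does not follow the on-disk contract."""


class EmptyGroupError(LaneLapseError, LookupError):
    """A requested age group contains no participants."""


class ParticipantNotFoundError(LaneLapseError, KeyError):
    """A participant id is not present in the cohort."""
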
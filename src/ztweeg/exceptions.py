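"""Exception hierarchy for the toolkit.

All toolkit errors derive from :class:`ZtweegError` so callers can catch one
base class at pipeline boundaries.
"""


class ZtweegError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(ZtweegError, ValueError):
    """An argument violates a documented precondition."""


class StoreLookupError(ZtweegError, KeyError):
    """A subject or emotion label is not present in the trial store."""


class FormatError(ZtweegError):
    """A file does not match the expected on-disk layout."""


class MissingBaselineError(ZtweegError):
    """A subject has no neutral trials, so no reference energy exists."""


class DegenerateBaselineError(ZtweegError):
    """A reference energy is zero (or negative), making relative change undefined."""


class TrainingError(ZtweegError):
    """A classifier could not be fit on the supplied data."""
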
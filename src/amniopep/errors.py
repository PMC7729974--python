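"""Exception hierarchy.

All package errors derive from :class:`AmniopepError` so callers can catch
one base class; the leaves distinguish malformed files (:class:`FormatError`),
inconsistent values (:class:`DataError`), misuse of an operation
(:class:`UsageError`) and invalid configuration (:class:`ConfigError`).
"""


class AmniopepError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(AmniopepError, ValueError):
    """A file does not have the expected layout (e.g. a missing column)."""


class DataError(AmniopepError, ValueError):
    """Values are inconsistent (duplicates, non-numeric abundance, bad IDs)."""


class UsageError(AmniopepError, ValueError):
    """An operation was called on inputs it is not defined for."""


class ConfigError(AmniopepError, ValueError):
    """A simulation or pipeline configuration is invalid."""


class GestationalAgeError(DataError):
    """Gestational ages fall outside the bin scheme; carries offending IDs."""

    def __init__(self, sample_ids):
        self.sample_ids = list(sample_ids)
        super().__init__(
            "gestational age outside the bin scheme for samples: "
            + ", ".join(map(str, self.sample_ids))
        )
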
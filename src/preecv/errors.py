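"""Exception hierarchy for preecv.

All package errors derive from :class:`PreEcvError` so callers can catch
everything the library raises with a single clause while still
distinguishing validation problems from model-fitting failures.
"""


class PreEcvError(Exception):
    """Base class for all preecv errors."""


class ValidationError(PreEcvError, ValueError):
    """An input record, field, or file violates the domain contract."""


class DegenerateOutcomeError(PreEcvError, ValueError):
    """Only one outcome class is present; the requested statistic is undefined."""


class SeparationError(PreEcvError, RuntimeError):
    """The logistic likelihood is monotone (perfect or quasi-separation)."""


class ConfigError(PreEcvError, ValueError):
    """A configuration object (strata, simulator settings, ...) is inconsistent."""
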
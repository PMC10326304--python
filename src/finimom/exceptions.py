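"""Exception hierarchy for finimom.

All errors raised by the library derive from :class:`FinimomError` so that
the CLI can catch one base class and translate it into a nonzero exit code
with an actionable message.
"""


class FinimomError(Exception):
    """Base class for all finimom errors."""


class ConfigurationError(FinimomError):
    """A required column, flag, or setting is missing or inconsistent."""


class ValidationError(FinimomError):
    """Input data violate a precondition (e.g. non-positive SE)."""


class FormatError(FinimomError):
    """A file could not be parsed as the declared format."""


class NumericalError(FinimomError):
    """A numerical routine failed beyond its fallbacks."""


class DegeneratePosteriorError(FinimomError):
    """The posterior sample is too degenerate to summarize as requested."""
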
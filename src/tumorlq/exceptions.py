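"""Exception hierarchy.

Everything raised on invalid user input derives from :class:`TumorLQError`
so callers (and the CLI) can catch one base class and report a clean message.
"""


class TumorLQError(Exception):
    """Base class for all errors raised by tumorlq."""


class DomainError(TumorLQError, ValueError):
    """A value violates a model precondition (negative dose, dt < 0, ...)."""


class ZeroVarianceError(TumorLQError, ValueError):
    """R-squared is undefined: the measured series has zero variance."""


class ParseError(TumorLQError, ValueError):
    """A CSV or config file failed validation; the message names the offender."""
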
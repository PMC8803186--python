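"""Exception hierarchy for the ctot package."""


class CtotError(Exception):
    """Base class for all ctot errors."""


class ConfigurationError(CtotError):
    """A required column, option, or input is missing or inconsistent."""


class ParseError(CtotError):
    """A cell could not be interpreted as a Cq value or known token."""


class ValidationError(CtotError):
    """A dataset violates a structural invariant."""
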
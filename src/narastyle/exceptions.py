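"""Exception hierarchy shared across the package."""


class NarastyleError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(NarastyleError, ValueError):
    """An operation received input violating its precondition."""


class ValidationError(NarastyleError, ValueError):
    """A record, lexicon row or configuration failed validation."""


class InvalidStructureError(NarastyleError, ValueError):
    """An annotation structure (chunk spans, dependency heads) is inconsistent."""


class InsufficientDataError(NarastyleError, ValueError):
    """Too few observations to carry out a statistical comparison."""
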
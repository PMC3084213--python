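"""Exception hierarchy shared across the package."""


class CinCatError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CinCatError):
    """A malformed input file (bad token, duplicate key, missing column)."""


class ValidationError(CinCatError):
    """Inputs parse but violate a documented precondition or invariant."""
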
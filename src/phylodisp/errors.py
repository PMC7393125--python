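"""Exception hierarchy shared across the package."""


class PhylodispError(Exception):
    """Base class for all package errors."""


class ParseError(PhylodispError):
    """A file or cell could not be parsed."""


class ValidationError(PhylodispError):
    """Parsed data violates a structural invariant."""


class DegenerateDataError(PhylodispError):
    """The data are too degenerate for the requested statistic
    (constant trait, all-tied ranks, too few groups, ...)."""
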
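"""Exception hierarchy used across the package."""


class PairedWGCNAError(Exception):
    """Base class for all package errors."""


class ValidationError(PairedWGCNAError):
    """An input object violates a structural invariant."""


class ParseError(PairedWGCNAError):
    """A file could not be parsed; message names the offending location."""


class FormatError(ParseError):
    """A file is not in the expected dialect (e.g. GEO series matrix)."""


class DomainError(PairedWGCNAError):
    """A numeric parameter is outside its mathematical domain."""


class DegenerateDataError(PairedWGCNAError):
    """The computation is undefined on this input (constant matrix, zero
    variance, all-zero connectivity, ...)."""


class InsufficientDataError(PairedWGCNAError):
    """Too few samples/pairs/genes remain for the requested computation."""


class ConvergenceError(PairedWGCNAError):
    """A model fit failed; carries diagnostics in the message."""
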
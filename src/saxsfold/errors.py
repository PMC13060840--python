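"""Exception hierarchy.

All package errors derive from :class:`SaxsfoldError` so callers can catch
one type; subclasses distinguish user-input problems from contract violations.
"""


class SaxsfoldError(Exception):
    """Base class for all errors raised by saxsfold."""


class InvalidGeometryError(SaxsfoldError):
    """Scattering geometry with non-positive wavelength or out-of-range angle."""


class InvalidParameterError(SaxsfoldError):
    """A numeric parameter (bin width, bandwidth, grid) violates its contract."""


class DegenerateInputError(SaxsfoldError):
    """Input too small or empty for the requested computation."""


class MissingScaleError(SaxsfoldError):
    """Absolute intensity requested from a normalized curve without a recorded total weight."""


class ContractViolationError(SaxsfoldError):
    """An input violates a documented precondition (e.g. unnormalized curve to the L1 loss)."""


class MissingTermError(SaxsfoldError):
    """A required loss component was not supplied."""


class DegenerateFitError(SaxsfoldError):
    """Profile fit against an identically zero model."""


class MalformedEnsembleError(SaxsfoldError):
    """Multi-model file whose models disagree in sequence or numbering."""


class FileFormatError(SaxsfoldError):
    """Malformed structure or profile file; message names the offending line."""
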
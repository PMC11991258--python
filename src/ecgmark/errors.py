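"""Exception hierarchy shared by all embedding methods."""


class EcgMarkError(Exception):
    """Base class for all package errors."""


class FormatError(EcgMarkError):
    """A WFDB header or data file is missing, truncated or malformed."""


class UnsupportedFormatError(FormatError):
    """The record uses a storage format the package does not handle."""


class RangeError(EcgMarkError):
    """A sample value falls outside the representable integer range."""


class ValidationError(EcgMarkError):
    """An argument violates a documented precondition."""


class InsufficientCapacityError(EcgMarkError):
    """The payload (plus framing and side information) does not fit.

    Carries ``required`` and ``available`` bit counts when known.
    """

    def __init__(self, message: str, required: int | None = None,
                 available: int | None = None):
        super().__init__(message)
        self.required = required
        self.available = available


class UnsupportedLeadError(EcgMarkError):
    """A predictor was asked for a lead it cannot predict.

    Physical (Einthoven/Goldberger) prediction only exists for the four
    derived limb leads III, aVR, aVL, aVF.
    """


class UnembeddablePairError(EcgMarkError):
    """No in-range substitute value exists for a skip-adjusted pair."""


class TamperError(EcgMarkError):
    """The watermark test failed: the record was modified after embedding.

    Raised on checksum mismatch, on a payload length header that exceeds
    the extracted bit budget, or on a corrupt compressed stream.  The CLI
    converts this into a ``tampered`` verdict rather than a traceback.
    """


class CorruptStreamError(TamperError):
    """A compressed bitstream ended early or decoded to an invalid path."""
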
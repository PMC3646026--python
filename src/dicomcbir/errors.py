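"""Exception hierarchy for the CBIR engine.

Every failure mode the engine can signal derives from :class:`CBIRError`
so callers can catch engine errors without masking programming errors.
"""


class CBIRError(Exception):
    """Base class for all engine errors."""


class DicomParseError(CBIRError):
    """File is not readable as a DICOM object with pixel data."""


class UnsupportedSyntaxError(CBIRError):
    """DICOM file uses a transfer syntax or layout the engine rejects
    (compressed, multi-frame, color)."""


class ValidationError(CBIRError):
    """A record, document or profile violates its invariants."""


class ContractError(CBIRError):
    """An operation was called with arguments outside its precondition."""


class MissingFieldError(CBIRError):
    """A feature document lacks a field required by the active profile."""

    def __init__(self, field: str, uid: str):
        self.field = field
        self.uid = uid
        super().__init__(
            f"profile/feature mismatch: document {uid!r} lacks field {field!r}"
        )


class PlacementError(CBIRError):
    """Phantom speckle placement could not satisfy the non-overlap rule."""


class IndexLoadError(CBIRError):
    """On-disk index store is missing or corrupt."""


class ProfileError(CBIRError):
    """Profile file failed validation; message lists every problem found."""
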
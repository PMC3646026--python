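"""Reading and writing single-frame grayscale DICOM files.

The engine only ever deals with uncompressed, single-frame, MONOCHROME2
images; anything else is rejected loudly rather than half-supported.
Pixel intensities are normalized to [0, 1] by min-max scaling after the
DICOM rescale transform, giving every feature extractor one common,
dataset-independent input contract (:class:`GrayImage`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

from .errors import DicomParseError, UnsupportedSyntaxError, ValidationError


@dataclass
class ImageRecord:
    """Decoded grayscale pixel matrix plus the DICOM identity the engine needs.

    Attributes
    ----------
    uid : str
        SOP Instance UID; non-empty, unique within one index.
    modality : str
        DICOM modality code, e.g. ``"MG"`` or ``"CT"``.
    pixels : ndarray of shape (rows, cols)
        Non-negative stored values, all ``< 2**bits_stored``.
    bits_stored : int
        Bit depth of the stored values.
    rescale_slope, rescale_intercept : float
        Modality rescale transform; default to the identity.
    source_path : str
        Path the record was read from, or ``""`` for in-memory records.
    """

    uid: str
    modality: str
    pixels: np.ndarray
    bits_stored: int
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    source_path: str = ""

    def validate(self) -> None:
        if not self.uid:
            raise ValidationError("ImageRecord.uid must be non-empty")
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("ImageRecord.pixels must be a non-empty 2-D matrix")
        if px.min() < 0 or px.max() >= 2 ** self.bits_stored:
            raise ValidationError(
                f"pixel values must lie in [0, 2^{self.bits_stored})"
            )


@dataclass
class GrayImage:
    """Normalized image: real values in [0, 1]."""

    values: np.ndarray
    shape: tuple = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.shape = tuple(self.values.shape)


def read_image(path: str | os.PathLike) -> ImageRecord:
    """Read a DICOM Part-10 file into an :class:`ImageRecord`.

    Raises
    ------
    DicomParseError
        If the file is not DICOM or carries no pixel data.
    UnsupportedSyntaxError
        For compressed transfer syntaxes, multi-frame or color images.
    """
    path = os.fspath(path)
    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # pydicom raises several unrelated types
        raise DicomParseError(f"cannot parse {path!r} as DICOM: {exc}") from exc

    ts = getattr(getattr(ds, "file_meta", None), "TransferSyntaxUID", None)
    if ts is not None and ts.is_compressed:
        raise UnsupportedSyntaxError(
            f"{path!r}: compressed transfer syntax {ts} is not supported"
        )
    if "PixelData" not in ds:
        raise DicomParseError(f"{path!r} contains no pixel data")
    if int(getattr(ds, "NumberOfFrames", 1)) != 1:
        raise UnsupportedSyntaxError(f"{path!r}: multi-frame DICOM is not supported")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise UnsupportedSyntaxError(f"{path!r}: color DICOM is not supported")

    try:
        pixels = ds.pixel_array
    except Exception as exc:
        raise DicomParseError(f"{path!r}: cannot decode pixel data: {exc}") from exc

    record = ImageRecord(
        uid=str(getattr(ds, "SOPInstanceUID", "")),
        modality=str(getattr(ds, "Modality", "")),
        pixels=np.asarray(pixels),
        bits_stored=int(ds.BitsStored),
        rescale_slope=float(getattr(ds, "RescaleSlope", 1.0)),
        rescale_intercept=float(getattr(ds, "RescaleIntercept", 0.0)),
        source_path=path,
    )
    record.validate()
    return record


def write_image(record: ImageRecord, path: str | os.PathLike) -> str:
    """Write ``record`` as a valid single-frame, uncompressed, MONOCHROME2
    DICOM Part-10 file (Explicit VR Little Endian).

    ``read_image(write_image(r))`` reproduces pixels, uid and modality
    exactly.
    """
    record.validate()
    path = os.fspath(path)

    bits_alloc = 8 if record.bits_stored <= 8 else 16
    dtype = np.uint8 if bits_alloc == 8 else np.uint16

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = record.uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = record.uid
    ds.Modality = record.modality
    ds.Rows, ds.Columns = record.pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = bits_alloc
    ds.BitsStored = record.bits_stored
    ds.HighBit = record.bits_stored - 1
    ds.PixelRepresentation = 0
    if record.rescale_slope != 1.0 or record.rescale_intercept != 0.0:
        ds.RescaleSlope = record.rescale_slope
        ds.RescaleIntercept = record.rescale_intercept
    ds.PixelData = np.ascontiguousarray(record.pixels, dtype=dtype).tobytes()

    ds.save_as(path, enforce_file_format=True)
    return path


def normalize_pixels(record: ImageRecord) -> GrayImage:
    """Rescale (slope·v + intercept) then min-max scale to [0, 1].

    A constant image maps to all zeros so downstream extractors never
    see NaN.  The result is invariant to adding a constant to all pixels.
    """
    record.validate()
    v = record.pixels.astype(np.float64) * record.rescale_slope + record.rescale_intercept
    lo, hi = v.min(), v.max()
    if hi == lo:
        return GrayImage(np.zeros_like(v))
    return GrayImage((v - lo) / (hi - lo))
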
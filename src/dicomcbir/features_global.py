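"""General-purpose image features, applicable to any modality.

These are the modality-independent descriptors every image gets when it
is indexed: an intensity histogram, an edge-orientation histogram, the
Shannon entropy of the intensity distribution, the largest connected
components of a binarized view (with area and center of mass) and the
moment set (raw, central and the seven Hu invariants) of the foreground
mask.

Conventions, stated once and tested everywhere: coordinates are
(row, col), 0-based, pixel centers at integer coordinates; edge
orientations are folded modulo 180 degrees (edge direction is
sign-ambiguous); entropy is reported in bits; connected components use
8-connectivity, ordered by area descending with ties broken by the
topmost-leftmost foreground pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .dicom_io import GrayImage, ImageRecord, normalize_pixels
from .errors import ContractError


@dataclass
class Histogram:
    weights: np.ndarray
    bin_edges: np.ndarray
    normalized: bool

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        if self.weights.ndim != 1 or len(self.bin_edges) != len(self.weights) + 1:
            raise ContractError("histogram needs B weights and B+1 bin edges")
        if np.any(self.weights < 0):
            raise ContractError("histogram weights must be non-negative")


@dataclass
class Segment:
    label: int
    area_px: int
    centroid: tuple[float, float]


@dataclass
class MomentSet:
    """Raw and central moments for p+q <= 3, plus the 7 Hu invariants.

    Raw moments follow m_pq = sum over foreground of row^p * col^q.
    """

    raw: dict
    central: dict
    hu: np.ndarray


@dataclass
class GlobalFeatures:
    intensity_hist: Histogram
    edge_hist: Histogram
    entropy_bits: float
    segments: list[Segment]
    moments: MomentSet | None


@dataclass
class ExtractionParams:
    """Engine-level extraction configuration (bin counts, K, segmentation)."""

    intensity_bins: int = 32
    edge_bins: int = 8
    k_segments: int = 5
    seg_method: str = "otsu"
    seg_threshold: float = 0.5


def intensity_histogram(img: GrayImage, bins: int) -> Histogram:
    """Equal-width histogram of intensities over [0, 1], normalized to sum 1.

    The last bin is right-closed so the value 1.0 is counted.
    """
    if bins < 2:
        raise ContractError("bins must be >= 2")
    counts, edges = np.histogram(img.values, bins=bins, range=(0.0, 1.0))
    return Histogram(counts / img.values.size, edges, normalized=True)


def entropy(h: Histogram) -> float:
    """Shannon entropy of a normalized histogram, in bits; 0*log(0) = 0."""
    if not h.normalized or abs(h.weights.sum() - 1.0) > 1e-9:
        raise ContractError("entropy requires a normalized histogram")
    w = h.weights[h.weights > 0]
    return float(-(w * np.log2(w)).sum())


def _sobel(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """3x3 Sobel gradients with replicate-border handling.

    gx is the derivative along columns, gy along rows.
    """
    p = np.pad(values, 1, mode="edge")
    gx = (
        (p[:-2, 2:] + 2 * p[1:-1, 2:] + p[2:, 2:])
        - (p[:-2, :-2] + 2 * p[1:-1, :-2] + p[2:, :-2])
    )
    gy = (
        (p[2:, :-2] + 2 * p[2:, 1:-1] + p[2:, 2:])
        - (p[:-2, :-2] + 2 * p[:-2, 1:-1] + p[:-2, 2:])
    )
    return gx, gy


def edge_histogram(img: GrayImage, bins: int) -> Histogram:
    """Gradient-orientation histogram over [0, 180) degrees.

    Orientations come from 3x3 Sobel gradients, folded modulo 180, and
    are weighted by gradient magnitude.  A gradient-free (constant)
    image yields all-zero weights with ``normalized=False``.
    """
    if bins < 2:
        raise ContractError("bins must be >= 2")
    if img.values.shape[0] < 3 or img.values.shape[1] < 3:
        raise ContractError("edge histogram needs an image of at least 3x3")
    gx, gy = _sobel(img.values)
    mag = np.hypot(gx, gy)
    theta = np.degrees(np.arctan2(gy, gx)) % 180.0
    theta[theta >= 180.0] -= 180.0

    edges = np.linspace(0.0, 180.0, bins + 1)
    idx = np.minimum((theta / 180.0 * bins).astype(int), bins - 1)
    weights = np.bincount(idx.ravel(), weights=mag.ravel(), minlength=bins)
    total = weights.sum()
    if total == 0:
        return Histogram(np.zeros(bins), edges, normalized=False)
    return Histogram(weights / total, edges, normalized=True)


def binarize(img: GrayImage, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Foreground mask: value strictly greater than the threshold."""
    v = img.values
    if method == "fixed":
        if threshold is None or not 0.0 < threshold < 1.0:
            raise ContractError("fixed method needs a threshold in (0, 1)")
        t = threshold
    elif method == "otsu":
        if v.min() == v.max():
            return np.zeros(v.shape, dtype=bool)
        t = threshold_otsu(v)
    else:
        raise ContractError(f"unknown segmentation method {method!r}")
    return v > t


def segment(img: GrayImage, method: str = "otsu", threshold: float | None = None) -> list[Segment]:
    """Connected components of the binarized image, largest first.

    8-connected labeling; ties in area break by the lexicographically
    smallest (row, col) foreground pixel.  No foreground -> empty list.
    """
    mask = binarize(img, method, threshold)
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=2)
    segs = []
    for rp in measure.regionprops(labels):
        coords = rp.coords  # (N, 2) row, col
        top = coords[np.lexsort((coords[:, 1], coords[:, 0]))[0]]
        segs.append((rp.area, int(top[0]), int(top[1]), rp))
    segs.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [
        Segment(label=i + 1, area_px=int(rp.area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])))
        for i, (_, _, _, rp) in enumerate(segs)
    ]


def moments(mask: np.ndarray) -> MomentSet:
    """Raw, central and Hu moments of a binary foreground mask."""
    mask = np.asarray(mask).astype(np.float64)
    if mask.sum() == 0:
        raise ContractError("moments require at least one foreground pixel")
    m = measure.moments(mask, order=3)
    mu = measure.moments_central(mask, order=3)
    nu = measure.moments_normalized(mu, order=3)
    hu = measure.moments_hu(nu)
    raw = {(p, q): float(m[p, q]) for p in range(4) for q in range(4) if p + q <= 3}
    central = {(p, q): float(mu[p, q]) for p in range(4) for q in range(4) if p + q <= 3}
    return MomentSet(raw=raw, central=central, hu=np.asarray(hu, dtype=np.float64))


def extract_global(record: ImageRecord, params: ExtractionParams | None = None) -> GlobalFeatures:
    """Compose the extractors above with the configured bin counts and K."""
    params = params or ExtractionParams()
    img = normalize_pixels(record)
    ih = intensity_histogram(img, params.intensity_bins)
    segs = segment(img, params.seg_method, params.seg_threshold)
    mask = binarize(img, params.seg_method, params.seg_threshold)
    mom = moments(mask) if mask.any() else None
    return GlobalFeatures(
        intensity_hist=ih,
        edge_hist=edge_histogram(img, params.edge_bins),
        entropy_bits=entropy(ih),
        segments=segs[: params.k_segments],
        moments=mom,
    )


def global_fields(gf: GlobalFeatures) -> dict[str, float]:
    """Flatten :class:`GlobalFeatures` into suffixed index fields.

    Multi-dimensional features become base name + 0-based suffix
    (``intensityHistogram0`` ...); segment attributes are suffixed by
    rank.  Absent features (no foreground) simply contribute no fields.
    """
    fields: dict[str, float] = {}
    for i, w in enumerate(gf.intensity_hist.weights):
        fields[f"intensityHistogram{i}"] = float(w)
    for i, w in enumerate(gf.edge_hist.weights):
        fields[f"edgeHistogram{i}"] = float(w)
    fields["entropy"] = float(gf.entropy_bits)
    for i, s in enumerate(gf.segments):
        fields[f"segmentArea{i}"] = float(s.area_px)
        fields[f"segmentRow{i}"] = float(s.centroid[0])
        fields[f"segmentCol{i}"] = float(s.centroid[1])
    if gf.moments is not None:
        for i, h in enumerate(gf.moments.hu):
            fields[f"huMoment{i}"] = float(h)
    return fields
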
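"""Mammogram-specific features.

On top of the general descriptors, mammograms get three more feature
groups: a breast segmentation (area, center of mass, and the average
edge angle to the center of mass — a rotation-invariant shape
regularity score), bright-spot calcification candidates, and Haralick
texture statistics computed inside the breast mask.

The calcification detector is classical bright-spot detection: a
morphological white top-hat with a disc structuring element isolates
small bright structures, an adaptive threshold at mean + k·stddev of
the top-hat response binarizes it, and a connected-component size
filter keeps blobs in a plausible area range.  It reports candidates,
not diagnoses.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import disk, white_tophat

from .dicom_io import GrayImage, ImageRecord, normalize_pixels
from .errors import ContractError
from .features_global import _sobel, binarize


@dataclass
class TextureDescriptor:
    """Four Haralick statistics of a symmetric, normalized GLCM."""

    contrast: float
    correlation: float
    energy: float
    homogeneity: float


@dataclass
class MammoFeatures:
    breast_area_px: int
    breast_centroid: tuple[float, float] | None
    avg_edge_angle_deg: float | None
    calc_count: int
    calc_centroids: list[tuple[float, float]]
    texture: TextureDescriptor | None


@dataclass
class MammoParams:
    tophat_radius_px: int = 5
    k_sigma: float = 3.0
    min_area_px: int = 2
    max_area_px: int = 50
    glcm_levels: int = 16
    glcm_offsets: tuple = ((0, 1), (1, 0))


def breast_segmentation(img: GrayImage):
    """Segment the breast as the largest 8-connected Otsu foreground blob.

    Returns ``(mask, area_px, centroid, avg_edge_angle_deg)``.  The
    average edge angle is the mean, over boundary pixels, of the acute
    angle (degrees, in [0, 90]) between the local intensity-gradient
    direction and the line from the boundary pixel to the mask
    centroid.  For a disc the gradient at the boundary is radial, so
    the angle is near 0.  With no foreground the area is 0 and the
    angle is ``None``.
    """
    if img.values.shape[0] < 16 or img.values.shape[1] < 16:
        raise ContractError("breast segmentation needs an image of at least 16x16")
    fg = binarize(img, "otsu")
    if not fg.any():
        return np.zeros_like(fg), 0, None, None
    labels = measure.label(fg, connectivity=2)
    largest = max(measure.regionprops(labels), key=lambda rp: rp.area)
    mask = labels == largest.label
    centroid = (float(largest.centroid[0]), float(largest.centroid[1]))

    boundary = mask & ~ndimage.binary_erosion(mask, structure=np.ones((3, 3)))
    gx, gy = _sobel(img.values)
    angles = []
    for r, c in zip(*np.nonzero(boundary)):
        g = np.array([gy[r, c], gx[r, c]])  # (d/drow, d/dcol)
        v = np.array([centroid[0] - r, centroid[1] - c])
        ng, nv = np.linalg.norm(g), np.linalg.norm(v)
        if ng == 0 or nv == 0:
            continue
        cosang = abs(float(g @ v)) / (ng * nv)
        angles.append(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    avg_angle = float(np.mean(angles)) if angles else None
    return mask, int(mask.sum()), centroid, avg_angle


def calcification_candidates(
    img: GrayImage, params: MammoParams | None = None
) -> list[tuple[float, float]]:
    """Detect small bright blobs as microcalcification candidates.

    White top-hat (disc of ``tophat_radius_px``), threshold at
    mean + k_sigma * stddev of the response, 8-connected components with
    area in [min_area_px, max_area_px].  Returns blob centroids sorted
    by (row, col); an empty list is a valid outcome.
    """
    p = params or MammoParams()
    if p.tophat_radius_px <= 0 or p.min_area_px <= 0 or p.max_area_px < p.min_area_px:
        raise ContractError("detector parameters must be positive with max_area >= min_area")
    response = white_tophat(img.values, footprint=disk(p.tophat_radius_px))
    thresh = response.mean() + p.k_sigma * response.std()
    blobs = measure.label(response > thresh, connectivity=2)
    centroids = [
        (float(rp.centroid[0]), float(rp.centroid[1]))
        for rp in measure.regionprops(blobs)
        if p.min_area_px <= rp.area <= p.max_area_px
    ]
    return sorted(centroids)


def glcm(
    img: GrayImage, mask: np.ndarray, levels: int, offsets
) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix inside a mask.

    Pixels are quantized to ``levels`` gray levels; only pairs with both
    pixels inside the mask are counted; counts are symmetrized and
    averaged over the offsets.
    """
    if levels < 2:
        raise ContractError("levels must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ContractError("GLCM requires a non-empty mask")
    q = np.minimum((img.values * levels).astype(int), levels - 1)
    nrows, ncols = q.shape
    P = np.zeros((levels, levels), dtype=np.float64)
    npairs = 0
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(nrows, nrows - dr)
        c0, c1 = max(0, -dc), min(ncols, ncols - dc)
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        np.add.at(P, (a[valid], b[valid]), 1.0)
        npairs += int(valid.sum())
    if npairs < 2:
        raise ContractError("fewer than 2 co-occurring pixel pairs inside the mask")
    P = P + P.T
    return P / P.sum()


def texture_descriptors(
    img: GrayImage, mask: np.ndarray, levels: int = 16, offsets=((0, 1), (1, 0))
) -> TextureDescriptor:
    """Haralick contrast, correlation, energy and homogeneity of the
    masked GLCM.

    Energy is the angular second moment (sum of squared GLCM entries);
    a constant region therefore has energy 1 and contrast 0.  When the
    GLCM marginal variance is zero, correlation is defined as 1.
    """
    P = glcm(img, mask, levels, offsets)
    i, j = np.indices(P.shape)
    contrast = float((P * (i - j) ** 2).sum())
    pi = P.sum(axis=1)
    mu = float((np.arange(levels) * pi).sum())
    var = float(((np.arange(levels) - mu) ** 2 * pi).sum())
    if var == 0:
        correlation = 1.0
    else:
        correlation = float((P * (i - mu) * (j - mu)).sum() / var)
    energy = float((P ** 2).sum())
    homogeneity = float((P / (1.0 + (i - j) ** 2)).sum())
    return TextureDescriptor(contrast, correlation, energy, homogeneity)


def extract_mammo(record: ImageRecord, params: MammoParams | None = None) -> MammoFeatures:
    """Compose breast segmentation, calcification detection and texture.

    Texture is computed within the breast mask; degenerate images (no
    foreground) yield area 0, no candidates and no texture.
    """
    p = params or MammoParams()
    img = normalize_pixels(record)
    mask, area, centroid, angle = breast_segmentation(img)
    calc = calcification_candidates(img, p) if area > 0 else []
    texture = None
    if area > 0:
        try:
            texture = texture_descriptors(img, mask, p.glcm_levels, p.glcm_offsets)
        except ContractError:
            texture = None
    return MammoFeatures(
        breast_area_px=area,
        breast_centroid=centroid,
        avg_edge_angle_deg=angle,
        calc_count=len(calc),
        calc_centroids=calc,
        texture=texture,
    )


def mammo_fields(mf: MammoFeatures) -> dict[str, float]:
    """Flatten :class:`MammoFeatures` into index fields; undefined
    attributes contribute no fields."""
    fields: dict[str, float] = {
        "calcCount": float(mf.calc_count),
        "breastArea": float(mf.breast_area_px),
    }
    if mf.breast_centroid is not None:
        fields["breastRow"] = float(mf.breast_centroid[0])
        fields["breastCol"] = float(mf.breast_centroid[1])
    if mf.avg_edge_angle_deg is not None:
        fields["breastEdgeAngle"] = float(mf.avg_edge_angle_deg)
    if mf.texture is not None:
        fields["textureContrast"] = mf.texture.contrast
        fields["textureCorrelation"] = mf.texture.correlation
        fields["textureEnergy"] = mf.texture.energy
        fields["textureHomogeneity"] = mf.texture.homogeneity
    return fields
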
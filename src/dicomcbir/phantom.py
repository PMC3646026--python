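"""Synthetic DICOM phantoms with analytically known feature ground truth.

Phantoms are flat-background images carrying simple geometric objects
(discs, rectangles, step edges), optional bright speckles standing in
for mammographic microcalcifications, and optional Gaussian noise.
Because every object is rasterized by pixel-center inclusion, areas,
centroids and speckle positions are known exactly, which is what makes
the extractor and retrieval tests sharp: a correct pipeline must
reproduce them bit-for-bit on noise-free inputs.

Pixels are quantized to 8 bits (levels 0-255); extractors must accept
any bit depth, but the fixture keeps its own ground truth exact.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .dicom_io import ImageRecord, write_image
from .errors import ContractError, PlacementError


@dataclass
class PhantomObject:
    """One geometric object painted on the background.

    kind ``disc``      params: center=(row, col), radius
    kind ``rectangle`` params: row0, row1, col0, col1 (inclusive bounds)
    kind ``step_edge`` params: col (columns >= col take the object level)
    """

    kind: str
    level: float
    params: dict

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = np.indices(shape)
        if self.kind == "disc":
            (cr, cc), r = self.params["center"], self.params["radius"]
            return (rows - cr) ** 2 + (cols - cc) ** 2 <= r ** 2
        if self.kind == "rectangle":
            p = self.params
            return (
                (rows >= p["row0"]) & (rows <= p["row1"])
                & (cols >= p["col0"]) & (cols <= p["col1"])
            )
        if self.kind == "step_edge":
            return cols >= self.params["col"]
        raise ContractError(f"unknown phantom object kind {self.kind!r}")


@dataclass
class PhantomSpec:
    shape: tuple[int, int] = (64, 64)
    background_level: float = 0.2
    objects: list[PhantomObject] = field(default_factory=list)
    speckle_count: int = 0
    speckle_radius_px: int = 2
    speckle_level: float = 0.9
    # optional disc (center, radius) the speckles must fall inside
    speckle_region: tuple[tuple[float, float], float] | None = None
    noise_sigma: float = 0.0
    modality: str = "CT"
    uid: str = "1.2.3.4"
    seed: int = 0


@dataclass
class GroundTruth:
    object_areas: list[int]
    object_centroids: list[tuple[float, float]]
    speckle_centers: list[tuple[int, int]]
    speckle_count: int

    def to_dict(self) -> dict:
        return {
            "object_areas": self.object_areas,
            "object_centroids": [list(c) for c in self.object_centroids],
            "speckle_centers": [list(c) for c in self.speckle_centers],
            "speckle_count": self.speckle_count,
        }


_MAX_PLACEMENT_TRIES = 2000


def _place_speckles(spec: PhantomSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Place non-overlapping speckle centers, bounded retries."""
    nrows, ncols = spec.shape
    r = spec.speckle_radius_px
    margin = r + 2
    centers: list[tuple[int, int]] = []
    min_sep2 = (2 * r + 2) ** 2
    tries = 0
    while len(centers) < spec.speckle_count:
        if tries >= _MAX_PLACEMENT_TRIES:
            raise PlacementError(
                f"could not place {spec.speckle_count} non-overlapping speckles "
                f"of radius {r} in a {nrows}x{ncols} image"
            )
        tries += 1
        cr = int(rng.integers(margin, nrows - margin))
        cc = int(rng.integers(margin, ncols - margin))
        if spec.speckle_region is not None:
            (rr, rc), rad = spec.speckle_region
            if math.hypot(cr - rr, cc - rc) > rad - margin:
                continue
        if any((cr - a) ** 2 + (cc - b) ** 2 < min_sep2 for a, b in centers):
            continue
        centers.append((cr, cc))
    return centers


def make_phantom(spec: PhantomSpec) -> tuple[ImageRecord, GroundTruth]:
    """Render a phantom deterministically for a fixed seed.

    Objects are painted in list order (later objects win on overlap),
    speckles are discs of ``speckle_radius_px``, then Gaussian noise of
    ``noise_sigma`` is added, the image clipped to [0, 1] and quantized
    to 8 bits.
    """
    if spec.speckle_count and spec.speckle_level <= spec.background_level:
        raise ContractError("speckle level must exceed the background level")
    rng = np.random.default_rng(spec.seed)
    img = np.full(spec.shape, spec.background_level, dtype=np.float64)

    areas, centroids = [], []
    for obj in spec.objects:
        m = obj.mask(spec.shape)
        img[m] = obj.level
        rows, cols = np.nonzero(m)
        areas.append(int(m.sum()))
        centroids.append((float(rows.mean()), float(cols.mean())))

    centers = _place_speckles(spec, rng) if spec.speckle_count else []
    rr, cc = np.indices(spec.shape)
    for cr, ccol in centers:
        m = (rr - cr) ** 2 + (cc - ccol) ** 2 <= spec.speckle_radius_px ** 2
        img[m] = spec.speckle_level

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    pixels = np.round(np.clip(img, 0.0, 1.0) * 255).astype(np.uint16)
    record = ImageRecord(
        uid=spec.uid, modality=spec.modality, pixels=pixels, bits_stored=8
    )
    truth = GroundTruth(areas, centroids, centers, len(centers))
    return record, truth


def _random_spec(i: int, mammo: bool, rng: np.random.Generator) -> PhantomSpec:
    """Randomized per-image spec used by :func:`write_dataset`.

    Mammography-like phantoms carry one large breast-like disc with
    bright speckles strictly inside it; the rest are CT-like phantoms
    with a couple of plain geometric objects.
    """
    seed = int(rng.integers(0, 2**31 - 1))
    if mammo:
        n = 128
        center = (n // 2 + int(rng.integers(-6, 7)), n // 2 + int(rng.integers(-6, 7)))
        radius = int(rng.integers(40, 52))
        breast = PhantomObject("disc", level=float(rng.uniform(0.45, 0.6)),
                               params={"center": center, "radius": radius})
        return PhantomSpec(
            shape=(n, n),
            background_level=0.05,
            objects=[breast],
            speckle_count=int(rng.integers(2, 7)),
            speckle_radius_px=2,
            speckle_level=0.9,
            speckle_region=(center, radius),
            noise_sigma=float(rng.uniform(0.0, 0.01)),
            modality="MG",
            seed=seed,
        )
    n = 96
    objs = []
    for _ in range(int(rng.integers(1, 3))):
        if rng.random() < 0.5:
            c = (int(rng.integers(24, n - 24)), int(rng.integers(24, n - 24)))
            objs.append(PhantomObject("disc", level=float(rng.uniform(0.5, 0.9)),
                                      params={"center": c, "radius": int(rng.integers(6, 16))}))
        else:
            r0 = int(rng.integers(8, n // 2)); c0 = int(rng.integers(8, n // 2))
            objs.append(PhantomObject(
                "rectangle", level=float(rng.uniform(0.5, 0.9)),
                params={"row0": r0, "row1": r0 + int(rng.integers(6, 24)),
                        "col0": c0, "col1": c0 + int(rng.integers(6, 24))}))
    return PhantomSpec(
        shape=(n, n),
        background_level=float(rng.uniform(0.1, 0.3)),
        objects=objs,
        noise_sigma=float(rng.uniform(0.0, 0.02)),
        modality="CT",
        seed=seed,
    )


def write_dataset(
    n: int, out_dir: str | os.PathLike, mammo_fraction: float = 0.5, seed: int = 0
) -> list[str]:
    """Write ``n`` phantom DICOM files plus a ground-truth JSON sidecar.

    ``ceil(mammo_fraction * n)`` files carry modality ``"MG"`` (breast
    disc + speckles), the remainder ``"CT"``.  Deterministic: the same
    call writes byte-identical files.
    """
    if n < 1:
        raise ContractError("n must be >= 1")
    if not 0.0 <= mammo_fraction <= 1.0:
        raise ContractError("mammo_fraction must lie in [0, 1]")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_mammo = math.ceil(mammo_fraction * n)

    paths, truths = [], {}
    for i in range(n):
        spec = _random_spec(i, i < n_mammo, rng)
        spec.uid = f"1.2.826.0.1.3680043.9590.{seed}.{i}"
        record, truth = make_phantom(spec)
        path = os.path.join(out_dir, f"phantom_{i:04d}.dcm")
        write_image(record, path)
        paths.append(path)
        truths[record.uid] = truth.to_dict()

    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(truths, fh, indent=1, sort_keys=True)
    return paths


def load_ground_truth(out_dir: str | os.PathLike) -> dict[str, GroundTruth]:
    """Load the sidecar written by :func:`write_dataset`, keyed by uid."""
    with open(os.path.join(os.fspath(out_dir), "ground_truth.json")) as fh:
        raw = json.load(fh)
    return {
        uid: GroundTruth(
            object_areas=d["object_areas"],
            object_centroids=[tuple(c) for c in d["object_centroids"]],
            speckle_centers=[tuple(c) for c in d["speckle_centers"]],
            speckle_count=d["speckle_count"],
        )
        for uid, d in raw.items()
    }
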
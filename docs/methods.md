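# Methods

This note records the engine's model, its tunable parameters, what the
synthetic phantoms do and do not exercise, and the design choices made
where the design was genuinely open.

## Retrieval model

The engine treats image similarity as a distance in a metric space: an
image is reduced to a flat document of named scalar features, a profile
names an ordered subset of those fields and a metric over them, and a
query-by-example ranks indexed documents by their distance to the
source document. Requiring the metric postulates (non-negativity,
symmetry, identity, triangle inequality) of every shipped distance
keeps the two-stage search sound and leaves the door open to proper
metric indexes (VP-/M-trees), which this engine deliberately does not
implement — its candidate pruning is the simpler per-dimension
bounding box.

Pruning is heuristic by construction: a true nearest neighbor can lie
outside the box, and no lower bound on the candidate count exists. The
engine therefore guarantees a weaker but testable property — culling
never changes a distance, only candidacy — and exposes the
aggressiveness as a profile parameter. With the `full_space` rule the
search degenerates to an exact sequential scan, which doubles as the
test oracle for the culled paths.

## Features

All extractors consume a common normalized view: DICOM stored values
pass through the modality rescale transform (slope·v + intercept) and
are then min–max scaled to [0, 1]. A constant image maps to all zeros
rather than NaN so extractors never see undefined input. Window
Center/Width tags are ignored: min–max is deterministic and
dataset-independent, at the cost of not matching radiologist display
conventions.

Global features (any modality): a 32-bin intensity histogram over
[0, 1] (last bin right-closed), its Shannon entropy in bits (bounded
by log₂ 32 = 5), an 8-bin edge-orientation histogram (3×3 Sobel,
orientation folded mod 180° because edge direction is sign-ambiguous,
magnitude-weighted; a gradient-free image yields an all-zero histogram
with an explicit unnormalized flag), the top K = 5 connected
components of the binarized image by area (8-connectivity; ties broken
by the topmost-leftmost pixel; Otsu threshold by default), and the
raw/central/Hu moment set of the foreground mask. Coordinates are
(row, col), 0-based, pixel centers at integer coordinates, everywhere.

Mammography features: the breast is the largest 8-connected Otsu
foreground component. The "average edge angle to center of mass" is
defined here as the mean over boundary pixels of the acute angle (in
degrees, range [0, 90]) between the local Sobel gradient direction and
the line from the boundary pixel to the mask centroid; for an ideal
disc the gradient is radial and the statistic approaches 0, so it acts
as a rotation-invariant shape-regularity score. Calcification
candidates come from classical bright-spot detection — white top-hat
with a disc structuring element (radius 5 px), adaptive threshold at
mean + k·σ of the response (k = 3), 8-connected components filtered to
areas in [2, 50] px. Texture is the four Haralick statistics
(contrast, correlation, energy = angular second moment, homogeneity)
of a symmetric, normalized gray-level co-occurrence matrix at 16 gray
levels and offsets {(0,1), (1,0)}, computed only over pixel pairs that
both lie inside the breast mask; when the GLCM marginal variance is
zero, correlation is defined as 1.

Bin counts, K, and all detector parameters are engine configuration,
not constants; the defaults above keep documents uniform and the index
compact.

## Metrics

Numerical choices: quadratic-form radicands in (−10⁻⁹, 0) arising from
PSD rounding are clamped to 0; the similarity matrix is validated
(symmetry, eigenvalues ≥ −10⁻⁹) when a profile loads, not per
evaluation. The Bhattacharyya distance uses the Hellinger-affinity
form √(1 − BC) and is evaluated as √(½ Σ (√pᵢ − √qᵢ)²) — algebraically
identical for normalized inputs, but exactly zero for identical
histograms and a plain Euclidean norm on √p vectors, so identity and
the triangle inequality hold to machine precision rather than to
√ε. EMD is restricted to same-binned 1-D histograms with unit ground
distance, where the CDF closed form is exact; the transportation
linear program remains in the test suite as the independent oracle.

## Index

The store is deliberately simple: an in-memory document map plus
per-field sorted postings of (encoded value, uid), rebuilt lazily
after writes, persisted as JSON-lines. The load-bearing contract is
the encoding: values snapped to 10⁻⁶ precision, shifted by 10¹⁵ and
zero-padded to 16 digits, so byte-wise string comparison is exactly
numeric comparison for |x| ≤ 10⁹. Range intervals are closed on both
ends so a box centered on a source value always contains value-equal
candidates. Re-adding a uid replaces the document (idempotent
re-indexing). Statistics used by the k·σ box rule are population
standard deviations over the documents that contain the field.

## Phantoms

The generator emulates what the retrieval contracts need, not
anatomy: flat backgrounds, rasterized discs/rectangles/step edges
(pixel-center inclusion, so areas and centroids are exact integers and
half-integers), small bright discs standing in for microcalcifications
(placed without overlap, bounded retries), optional Gaussian noise,
8-bit quantization. Mammography-like phantoms are a large mid-gray
disc on a dark background with speckles strictly inside the disc — the
speckle contrast and smooth surround make a reasonable detector's
ground truth unambiguous.

What passing tests therefore show: the pipeline reproduces analytic
ground truth exactly on noise-free inputs, retrieval is
self-consistent against sequential-scan oracles, and the detector
recovers unambiguous speckles at 100% recall. What they do not show:
performance on real mammograms — tissue texture, vendor-specific
intensity distributions, overlapping structures and realistic noise
are all absent, and the clinical validity of the shipped profiles'
field choices and weights is untested by construction.

## Problem sizes and determinism

The acceptance recomputation uses 200 random triples per metric for
the postulate sweep, 50 histogram pairs for the EMD/LP comparison, a
200-document index with 100 random boxes for range-query checks, 10⁴
values for the encoding order test, a 500-document index with 20 query
sources for scan-equivalence and culling soundness, 50 phantoms for
self-retrieval under both profiles, 10 noise-free mammography phantoms
(50 speckles) for detector recall, and 100–1000 documents for the
storage-scaling fit. All randomness flows from a single seed;
phantoms, feature extraction and queries are fully deterministic given
that seed.

## Known limitations

- Only uncompressed, single-frame, MONOCHROME2 DICOM is accepted;
  compressed transfer syntaxes, multi-frame and color objects are
  rejected loudly rather than partially supported.
- The per-dimension bounding box is a crude pre-selector; high-
  dimensional conjunctions (e.g. the general profile's 48 fields) can
  cull aggressively on heterogeneous data. This is inherent to the
  design, surfaced by `candidates_examined`, and the reason metric
  trees are the natural next step.
- The calcification detector is a candidate generator, not a CAD
  system; its parameters are tuned for phantom-style contrast.
- Profile expressiveness is limited to the four metrics and their
  declared parameters; arbitrary distance expressions are out of
  scope.
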
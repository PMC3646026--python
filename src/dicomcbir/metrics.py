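"""Distance functions available to retrieval profiles.

Similarity here is a proper metric: every function below satisfies
non-negativity, symmetry, identity of indiscernibles and the triangle
inequality, which is what makes bounding-box culling and (future)
metric indexes sound.  Four metrics are exposed to profiles under
bit-exact names: ``euclidean``, ``quadratic``, ``emd`` and
``bhattacharyya``.

The Bhattacharyya distance is implemented in its Hellinger-affinity
form sqrt(1 - BC) rather than -ln(BC): the logarithmic form violates
the triangle inequality and therefore cannot back a metric index.
The Earth Mover's Distance is restricted to same-binned 1-D histograms
with unit ground distance, where the transportation optimum has the
closed form sum_k |CDF_p(k) - CDF_q(k)|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, MissingFieldError
from .features_global import Histogram

METRIC_NAMES = ("euclidean", "quadratic", "emd", "bhattacharyya")


@dataclass
class FeatureVector:
    values: np.ndarray
    field_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or len(self.values) != len(self.field_names):
            raise ContractError("values and field_names must be parallel 1-D lists")
        if np.any(np.isnan(self.values)):
            raise ContractError("feature vectors must not contain NaN")


@dataclass
class SimilarityMatrix:
    """Bin-similarity matrix for the quadratic-form distance; must be
    symmetric positive semi-definite so the form is a metric."""

    entries: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.entries, dtype=np.float64)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ContractError("similarity matrix must be square")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ContractError("similarity matrix must be symmetric")
        if np.linalg.eigvalsh(A).min() < -1e-9:
            raise ContractError("similarity matrix must be positive semi-definite")
        self.entries = A


def _check_dims(x: FeatureVector, y: FeatureVector) -> None:
    if len(x.values) != len(y.values):
        raise ContractError(
            f"dimension mismatch: {x.field_names} vs {y.field_names}"
        )


def euclidean(x: FeatureVector, y: FeatureVector, weights=None) -> float:
    """Weighted Euclidean distance sqrt(sum w_i (x_i - y_i)^2); w defaults to 1."""
    _check_dims(x, y)
    d = x.values - y.values
    if weights is None:
        return float(np.sqrt(d @ d))
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != d.shape or np.any(w < 0):
        raise ContractError("weights must match dimension and be non-negative")
    return float(np.sqrt((w * d * d).sum()))


def quadratic_form(x: FeatureVector, y: FeatureVector, A: SimilarityMatrix) -> float:
    """Quadratic-form distance sqrt((x-y)^T A (x-y)) for PSD A.

    Tiny negative radicands from floating-point arithmetic are clamped
    to zero.
    """
    _check_dims(x, y)
    d = x.values - y.values
    if A.entries.shape[0] != len(d):
        raise ContractError("matrix dimension does not match the feature vectors")
    r = float(d @ A.entries @ d)
    if r < -1e-9:
        raise ContractError("negative quadratic form: matrix is not PSD")
    return float(np.sqrt(max(r, 0.0)))


def _check_hist_pair(p: Histogram, q: Histogram, same_edges: bool) -> None:
    if len(p.weights) != len(q.weights):
        raise ContractError("histograms have different lengths")
    if same_edges and not np.array_equal(p.bin_edges, q.bin_edges):
        raise ContractError("histograms have mismatched bin edges")
    for h in (p, q):
        if not h.normalized or abs(h.weights.sum() - 1.0) > 1e-9:
            raise ContractError("histogram metrics require normalized histograms")


def emd_1d(p: Histogram, q: Histogram) -> float:
    """Earth Mover's Distance between same-binned 1-D histograms.

    Ground distance is |i - j| in bin units; the closed form is the L1
    distance between the two CDFs, which equals the transportation
    linear-program optimum exactly in 1-D.
    """
    _check_hist_pair(p, q, same_edges=True)
    return float(np.abs(np.cumsum(p.weights - q.weights)).sum())


def bhattacharyya(p: Histogram, q: Histogram) -> float:
    """Hellinger-affinity Bhattacharyya distance sqrt(1 - sum sqrt(p_i q_i)).

    Evaluated as sqrt(0.5 * sum (sqrt(p_i) - sqrt(q_i))^2), which is
    algebraically identical for normalized inputs but exactly zero for
    identical histograms and numerically a plain Euclidean norm, so the
    triangle inequality holds to machine precision.
    """
    _check_hist_pair(p, q, same_edges=False)
    d2 = 0.5 * ((np.sqrt(p.weights) - np.sqrt(q.weights)) ** 2).sum()
    return float(np.sqrt(min(d2, 1.0)))


def _as_histogram(values: np.ndarray) -> Histogram:
    """View an ordered field subset as a unit-binned histogram."""
    edges = np.arange(len(values) + 1, dtype=np.float64)
    s = values.sum()
    return Histogram(values, edges, normalized=bool(abs(s - 1.0) <= 1e-9))


def evaluate_metric(name: str, params: dict, doc_a, doc_b, fields: list[str]) -> float:
    """Assemble feature vectors from two documents and dispatch a metric.

    ``doc_a``/``doc_b`` expose a ``fields`` mapping (field name -> real);
    ``fields`` gives the profile's ordered field subset.  A document
    lacking any requested field raises :class:`MissingFieldError`.
    """
    if name not in METRIC_NAMES:
        raise ContractError(f"unknown metric {name!r}; expected one of {METRIC_NAMES}")
    vecs = []
    for doc in (doc_a, doc_b):
        vals = []
        for f in fields:
            if f not in doc.fields:
                raise MissingFieldError(f, doc.uid)
            vals.append(doc.fields[f])
        vecs.append(FeatureVector(np.array(vals, dtype=np.float64), list(fields)))
    x, y = vecs
    params = params or {}
    if name == "euclidean":
        return euclidean(x, y, params.get("weights"))
    if name == "quadratic":
        A = params["matrix"]
        if not isinstance(A, SimilarityMatrix):
            A = SimilarityMatrix(np.asarray(A))
        return quadratic_form(x, y, A)
    if name == "emd":
        return emd_1d(_as_histogram(x.values), _as_histogram(y.values))
    return bhattacharyya(_as_histogram(x.values), _as_histogram(y.values))
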
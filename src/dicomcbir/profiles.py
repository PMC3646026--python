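"""Retrieval profiles: declarative recipes for profiled retrieval.

A profile bundles everything one query needs: the modalities it applies
to, the ordered feature fields the metric consumes, the metric and its
parameters, and the candidate bounding-box rule.  New retrieval
behaviors are added by writing a profile file — the engine core never
changes.

Profile files are YAML with exactly four blocks::

    name: general
    modalities: ["*"]            # or a list of DICOM modality codes
    features: [intensityHistogram, entropy, ...]   # base or scalar names
    metric:
      name: euclidean            # euclidean | quadratic | emd | bhattacharyya
      params: {}                 # weights / matrix, metric-specific
    box:
      kind: k_sigma              # k_sigma | explicit | full_space
      params: {k_sigma: 2.0}

Base names of multi-dimensional features are expanded to suffixed
fields using the engine's configured dimensions at load time, so a
mismatch between profile and extractors is caught before any query
runs.

Two profiles ship with the engine: ``general`` (any modality; intensity
histogram + entropy + edge histogram + Hu moments under an unweighted
Euclidean metric) and ``mammo`` (MG only; calcification count, breast
area and edge angle, texture and edge histogram under a weighted
Euclidean metric that rebalances the very different field scales).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dfield
from importlib import resources

import numpy as np
import yaml

from .errors import ProfileError
from .features_global import ExtractionParams
from .metrics import METRIC_NAMES, SimilarityMatrix

#: scalar fields the extractors can produce
SCALAR_FIELDS = {
    "entropy", "calcCount", "breastArea", "breastRow", "breastCol",
    "breastEdgeAngle", "textureContrast", "textureCorrelation",
    "textureEnergy", "textureHomogeneity",
}


def _base_dims(params: ExtractionParams) -> dict[str, int]:
    """Expandable base feature names and their configured dimensions."""
    return {
        "intensityHistogram": params.intensity_bins,
        "edgeHistogram": params.edge_bins,
        "huMoment": 7,
        "segmentArea": params.k_segments,
        "segmentRow": params.k_segments,
        "segmentCol": params.k_segments,
    }


@dataclass
class BoxRule:
    kind: str  # k_sigma | explicit | full_space
    k_sigma: float | None = None
    ranges: dict[str, tuple[float, float]] | None = None


@dataclass
class Profile:
    name: str
    modalities: list[str]
    feature_fields: list[str]  # fully expanded, metric order
    metric_name: str
    metric_params: dict
    box_rule: BoxRule

    def requires_mammo(self) -> bool:
        mammo_bases = {"calcCount", "breastArea", "breastRow", "breastCol",
                       "breastEdgeAngle", "textureContrast", "textureCorrelation",
                       "textureEnergy", "textureHomogeneity"}
        return any(f in mammo_bases for f in self.feature_fields)


def _expand_features(
    features: list[str], params: ExtractionParams, problems: list[str]
) -> list[str]:
    dims = _base_dims(params)
    expanded: list[str] = []
    for name in features:
        if name in dims:
            expanded.extend(f"{name}{i}" for i in range(dims[name]))
        elif name in SCALAR_FIELDS:
            expanded.append(name)
        else:
            problems.append(f"unknown feature name {name!r}")
    return expanded


def load_profile(
    path: str | os.PathLike, params: ExtractionParams | None = None
) -> Profile:
    """Load and validate one profile file.

    Raises :class:`ProfileError` listing *every* problem found, not just
    the first one.
    """
    params = params or ExtractionParams()
    with open(os.fspath(path)) as fh:
        raw = yaml.safe_load(fh)
    return _build_profile(raw, params, origin=os.fspath(path))


def _build_profile(raw: dict, params: ExtractionParams, origin: str) -> Profile:
    problems: list[str] = []
    name = raw.get("name") or ""
    if not name:
        problems.append("missing profile name")
    modalities = raw.get("modalities") or []
    if not modalities:
        problems.append("missing modalities list")

    expanded = _expand_features(list(raw.get("features") or []), params, problems)
    if not expanded:
        problems.append("profile lists no usable features")

    metric = raw.get("metric") or {}
    metric_name = metric.get("name", "")
    metric_params = dict(metric.get("params") or {})
    if metric_name not in METRIC_NAMES:
        problems.append(
            f"unknown metric {metric_name!r}; expected one of {METRIC_NAMES}")
    if metric_name == "quadratic":
        try:
            A = SimilarityMatrix(np.asarray(metric_params.get("matrix"), dtype=float))
            if A.entries.shape[0] != len(expanded):
                problems.append(
                    f"similarity matrix is {A.entries.shape[0]}x{A.entries.shape[0]} "
                    f"but the profile expands to {len(expanded)} fields")
            else:
                metric_params["matrix"] = A
        except Exception as exc:
            problems.append(f"invalid similarity matrix: {exc}")
    if metric_name == "euclidean" and "weights" in metric_params:
        w = metric_params["weights"]
        if isinstance(w, dict):
            dims = _base_dims(params)
            per_field = []
            for base in raw.get("features") or []:
                if base not in w:
                    problems.append(f"no weight given for feature {base!r}")
                    continue
                n = dims.get(base, 1)
                per_field.extend([float(w[base])] * n)
            metric_params["weights"] = per_field
        else:
            metric_params["weights"] = [float(v) for v in w]
        if not problems and len(metric_params["weights"]) != len(expanded):
            problems.append("weights length does not match expanded fields")

    box = raw.get("box") or {}
    kind = box.get("kind", "")
    box_params = box.get("params") or {}
    rule = BoxRule(kind=kind)
    if kind == "k_sigma":
        k = box_params.get("k_sigma")
        if k is None or float(k) <= 0:
            problems.append("k_sigma box rule needs k_sigma > 0")
        else:
            rule.k_sigma = float(k)
    elif kind == "explicit":
        try:
            rule.ranges = {
                f: (float(lo), float(hi))
                for f, (lo, hi) in dict(box_params.get("ranges")).items()
            }
            if any(lo > hi for lo, hi in rule.ranges.values()):
                problems.append("explicit box has a range with lo > hi")
        except Exception:
            problems.append("explicit box rule needs a ranges mapping field -> [lo, hi]")
    elif kind != "full_space":
        problems.append(f"unknown box kind {kind!r}")

    if problems:
        raise ProfileError(f"profile {origin!r} invalid: " + "; ".join(problems))
    return Profile(
        name=name,
        modalities=[str(m) for m in modalities],
        feature_fields=expanded,
        metric_name=metric_name,
        metric_params=metric_params,
        box_rule=rule,
    )


def load_registry(
    profile_dir: str | os.PathLike | None = None,
    params: ExtractionParams | None = None,
) -> list[Profile]:
    """Load every profile in a directory (sorted filename order).

    With no directory, the two shipped profiles are loaded from the
    package data.
    """
    params = params or ExtractionParams()
    if profile_dir is None:
        base = resources.files("dicomcbir").joinpath("profile_data")
        profiles = []
        for entry in sorted(base.iterdir(), key=lambda e: e.name):
            if entry.name.endswith(".yaml"):
                raw = yaml.safe_load(entry.read_text())
                profiles.append(_build_profile(raw, params, origin=entry.name))
        return profiles
    paths = sorted(
        os.path.join(os.fspath(profile_dir), f)
        for f in os.listdir(profile_dir) if f.endswith(".yaml")
    )
    return [load_profile(p, params) for p in paths]


def select_profile(modality: str, registry: list[Profile]) -> Profile:
    """First profile (registry order) whose modality list contains the
    modality; otherwise the catch-all ``"*"`` profile."""
    fallback = None
    for profile in registry:
        if modality in profile.modalities:
            return profile
        if "*" in profile.modalities and fallback is None:
            fallback = profile
    if fallback is None:
        raise ProfileError('registry contains no catch-all ("*") profile')
    return fallback
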
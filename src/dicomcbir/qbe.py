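"""Query-by-example execution.

The retrieval dataflow: make sure the source image's features are
indexed (extracting them on demand), build an n-dimensional bounding
box centered on the source document, cull candidates with a conjunctive
range query, then rank the candidates by the profile's metric.

The bounding box is a pre-selection heuristic, not part of the metric:
culling can only remove candidates, never change a distance, and with
the ``full_space`` rule the query degenerates to an exact sequential
scan of the whole index.  Aggressive boxes (small ``k_sigma``) trade
recall for candidate-set size; the choice lives in the profile.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Callable

from .dicom_io import ImageRecord
from .errors import ContractError, MissingFieldError
from .feature_index import FULL_RANGE, FeatureDocument, FeatureIndex
from .features_global import ExtractionParams, extract_global, global_fields
from .features_mammo import MammoParams, extract_mammo, mammo_fields
from .profiles import Profile

log = logging.getLogger(__name__)


@dataclass
class BoundingBox:
    """Per-field closed numeric ranges used to cull candidates."""

    ranges: dict[str, tuple[float, float]]


@dataclass
class RankedResult:
    """Ranked retrieval output: distances nondecreasing, ties broken by
    uid ascending; an indexed query image appears at distance 0."""

    entries: list[tuple[str, float]]
    profile_name: str
    candidates_examined: int


def default_extractor(
    record: ImageRecord,
    profile: Profile,
    params: ExtractionParams | None = None,
    mammo_params: MammoParams | None = None,
) -> dict[str, float]:
    """Extract the fields a record should be indexed with.

    Global features are always extracted; mammography features are added
    when the record is a mammogram or the profile demands them.
    """
    fields = global_fields(extract_global(record, params))
    if record.modality == "MG" or profile.requires_mammo():
        fields.update(mammo_fields(extract_mammo(record, mammo_params)))
    return fields


def ensure_indexed(
    record: ImageRecord,
    index: FeatureIndex,
    profile: Profile,
    extractor: Callable[..., dict[str, float]] | None = None,
    params: ExtractionParams | None = None,
    mammo_params: MammoParams | None = None,
) -> FeatureDocument:
    """Return the indexed document for the record, extracting it if absent."""
    if record.uid in index:
        return index.get(record.uid)
    extract = extractor or default_extractor
    fields = extract(record, profile, params, mammo_params)
    doc = FeatureDocument(
        uid=record.uid, fields=fields,
        modality=record.modality, source_path=record.source_path,
    )
    index.add_document(doc)
    return doc


def make_bounding_box(
    source: FeatureDocument, profile: Profile, index: FeatureIndex
) -> BoundingBox:
    """Build the candidate box centered on the source document.

    ``k_sigma`` rule: [v - k·σ, v + k·σ] per field, with σ the
    population standard deviation over the index; if σ is unavailable
    the field falls back to the full range (logged).  ``explicit`` rule:
    the profile's per-field range widths re-centered on the source
    values.  ``full_space``: sentinel full ranges.
    """
    for f in profile.feature_fields:
        if f not in source.fields:
            raise MissingFieldError(f, source.uid)
    rule = profile.box_rule
    ranges: dict[str, tuple[float, float]] = {}
    for f in profile.feature_fields:
        v = source.fields[f]
        if rule.kind == "full_space":
            ranges[f] = FULL_RANGE
        elif rule.kind == "k_sigma":
            try:
                sigma = index.field_stats(f).stddev
            except KeyError:
                log.warning("no samples for field %r; falling back to full range", f)
                ranges[f] = FULL_RANGE
                continue
            ranges[f] = (v - rule.k_sigma * sigma, v + rule.k_sigma * sigma)
        elif rule.kind == "explicit":
            lo, hi = (rule.ranges or {}).get(f, FULL_RANGE)
            half = (hi - lo) / 2.0
            ranges[f] = (v - half, v + half)
        else:
            raise ContractError(f"unknown box rule {rule.kind!r}")
    return BoundingBox(ranges)


def rank_candidates(
    source: FeatureDocument,
    candidates,
    profile: Profile,
    index: FeatureIndex,
    k: int | None = None,
) -> list[tuple[str, float]]:
    """Evaluate the profile metric source-vs-candidate and sort.

    Candidates missing a profile field are skipped with a warning —
    heterogeneous indices are supported, a sparse document is simply
    not comparable under this profile.
    """
    from .metrics import evaluate_metric

    scored = []
    for uid in candidates:
        try:
            d = evaluate_metric(
                profile.metric_name, profile.metric_params,
                source, index.get(uid), profile.feature_fields,
            )
        except MissingFieldError as exc:
            log.warning("skipping candidate %s: %s", uid, exc)
            continue
        scored.append((uid, d))
    scored.sort(key=lambda t: (t[1], t[0]))
    return scored[:k] if k is not None else scored


def query_by_example(
    source: ImageRecord | str,
    profile: Profile,
    k: int,
    index: FeatureIndex,
    params: ExtractionParams | None = None,
    mammo_params: MammoParams | None = None,
) -> RankedResult:
    """Run the full retrieval dataflow and return the top-k ranking.

    The source may be an :class:`ImageRecord` (indexed on demand) or the
    uid of an already-indexed image.  The source's own entry is returned
    at distance 0; callers may drop it.
    """
    if k < 1:
        raise ContractError("k must be >= 1")
    if isinstance(source, str):
        source_doc = index.get(source)
    else:
        source_doc = ensure_indexed(source, index, profile, None, params, mammo_params)
    box = make_bounding_box(source_doc, profile, index)
    candidates = index.range_query(box.ranges)
    entries = rank_candidates(source_doc, sorted(candidates), profile, index, k)
    return RankedResult(
        entries=entries,
        profile_name=profile.name,
        candidates_examined=len(candidates),
    )


def format_result(result: RankedResult, fmt: str = "tsv", drop_self: str | None = None) -> str:
    """Render a ranking as TSV (uid, distance, rank) or JSON."""
    entries = [(u, d) for u, d in result.entries if u != drop_self]
    if fmt == "tsv":
        lines = ["uid\tdistance\trank"]
        lines += [f"{u}\t{d:.6f}\t{i + 1}" for i, (u, d) in enumerate(entries)]
        return "\n".join(lines)
    if fmt == "json":
        return json.dumps(
            {
                "profile": result.profile_name,
                "candidates_examined": result.candidates_examined,
                "results": [
                    {"uid": u, "distance": d, "rank": i + 1}
                    for i, (u, d) in enumerate(entries)
                ],
            },
            indent=1,
        )
    raise ContractError(f"unknown output format {fmt!r}")
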
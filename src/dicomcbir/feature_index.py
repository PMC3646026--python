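"""Range-searchable feature document store.

Every indexed image becomes a flat document of named scalar fields;
multi-dimensional features are split into per-dimension fields with a
0-based numeric suffix (``edgeHistogram0`` ... ``edgeHistogram7``) so
candidate culling can discriminate on single dimensions.  Field values
are stored behind a lexicographically sortable string encoding: numbers
are shifted by a fixed offset and written as fixed-width fixed-point
decimals, so byte-wise string order coincides exactly with numeric
order.  Range queries are conjunctive closed-interval scans over
per-field sorted encodings; documents lacking a queried field never
match.

On-disk layout (one directory): ``schema.json`` (format tag, version,
encoding parameters) plus ``documents.jsonl`` (one JSON document per
line).  ``load(persist(idx))`` answers every range query identically.
"""

from __future__ import annotations

import json
import math
import os
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field as dfield

import numpy as np

from .errors import ContractError, IndexLoadError, ValidationError

#: encoded values are stored at this absolute precision
PRECISION = 1e-6
#: encodable magnitude bound
VALUE_MAX = 1e9
VALUE_MIN = -VALUE_MAX
#: sentinel full-space range for bounding boxes
FULL_RANGE = (VALUE_MIN, VALUE_MAX)

_OFFSET = 10 ** 15  # = VALUE_MAX / PRECISION, shifts negatives above zero
_WIDTH = 16

_SUFFIXED = re.compile(r"^(.*?[^0-9])([0-9]+)$")


def encode_number(x: float) -> str:
    """Encode a real to a fixed-width string preserving numeric order.

    The value is snapped to the fixed precision (1e-6), shifted by a
    constant offset so negatives sort below positives, and zero-padded
    to a fixed width: for any in-range a < b,
    ``encode_number(a) < encode_number(b)`` byte-wise.
    """
    if not math.isfinite(x) or abs(x) > VALUE_MAX:
        raise ContractError(f"value {x!r} outside encodable range ±{VALUE_MAX:g}")
    n = round(x / PRECISION) + _OFFSET
    return f"{n:0{_WIDTH}d}"


def decode_number(s: str) -> float:
    """Inverse of :func:`encode_number` up to the stored precision."""
    return (int(s) - _OFFSET) * PRECISION


@dataclass
class FeatureDocument:
    uid: str
    fields: dict[str, float]
    modality: str = ""
    source_path: str = ""

    def validate(self) -> None:
        if not self.uid:
            raise ValidationError("document uid must be non-empty")
        suffixes: dict[str, set[int]] = {}
        for name, value in self.fields.items():
            if not math.isfinite(value):
                raise ValidationError(f"field {name!r} of {self.uid!r} is not finite")
            m = _SUFFIXED.match(name)
            if m:
                suffixes.setdefault(m.group(1), set()).add(int(m.group(2)))
        for base, idx in suffixes.items():
            if idx != set(range(len(idx))):
                raise ValidationError(
                    f"suffixed field {base!r} of {self.uid!r} has gaps: {sorted(idx)}"
                )


@dataclass
class FieldStats:
    field: str
    count: int
    mean: float
    stddev: float  # population
    min: float
    max: float


class FeatureIndex:
    """In-memory document store with per-field sorted encoded postings."""

    def __init__(self):
        self._docs: dict[str, FeatureDocument] = {}
        self._postings: dict[str, list[tuple[str, str]]] | None = None

    def __len__(self) -> int:
        return len(self._docs)

    def __contains__(self, uid: str) -> bool:
        return uid in self._docs

    def uids(self) -> list[str]:
        return list(self._docs)

    def get(self, uid: str) -> FeatureDocument:
        if uid not in self._docs:
            raise KeyError(uid)
        return self._docs[uid]

    def add_document(self, doc: FeatureDocument) -> None:
        """Upsert by uid; the document is immediately visible to queries.

        Heterogeneous field sets are allowed — new fields may appear at
        any time without touching existing documents.
        """
        doc.validate()
        self._docs[doc.uid] = doc
        self._postings = None

    def _build_postings(self) -> dict[str, list[tuple[str, str]]]:
        if self._postings is None:
            postings: dict[str, list[tuple[str, str]]] = {}
            for uid, doc in self._docs.items():
                for name, value in doc.fields.items():
                    postings.setdefault(name, []).append((encode_number(value), uid))
            for lst in postings.values():
                lst.sort()
            self._postings = postings
        return self._postings

    def range_query(self, ranges: dict[str, tuple[float, float]]) -> set[str]:
        """Uids of documents with every queried field inside its closed
        interval (conjunction across fields)."""
        postings = self._build_postings()
        result: set[str] | None = None
        for name, (lo, hi) in ranges.items():
            if lo > hi:
                raise ContractError(f"range for {name!r} has lo > hi")
            lo = max(lo, VALUE_MIN)
            hi = min(hi, VALUE_MAX)
            lst = postings.get(name, [])
            i = bisect_left(lst, (encode_number(lo), ""))
            j = bisect_right(lst, (encode_number(hi), "\U0010ffff"))
            hits = {uid for _, uid in lst[i:j]}
            result = hits if result is None else (result & hits)
            if not result:
                return set()
        return result if result is not None else set()

    def field_stats(self, field: str) -> FieldStats:
        """Population statistics over all documents containing ``field``."""
        values = [d.fields[field] for d in self._docs.values() if field in d.fields]
        if not values:
            raise KeyError(f"field {field!r} appears in no document")
        arr = np.asarray(values, dtype=np.float64)
        return FieldStats(
            field=field,
            count=len(arr),
            mean=float(arr.mean()),
            stddev=float(arr.std()),  # population (ddof=0)
            min=float(arr.min()),
            max=float(arr.max()),
        )

    def field_names(self) -> set[str]:
        names: set[str] = set()
        for doc in self._docs.values():
            names.update(doc.fields)
        return names

    # ------------------------------------------------------------------
    # persistence

    def persist(self, path: str | os.PathLike) -> str:
        path = os.fspath(path)
        os.makedirs(path, exist_ok=True)
        with open(os.path.join(path, "schema.json"), "w") as fh:
            json.dump(
                {"format": "dicomcbir-index", "version": 1,
                 "precision": PRECISION, "value_max": VALUE_MAX},
                fh,
            )
        with open(os.path.join(path, "documents.jsonl"), "w") as fh:
            for uid in sorted(self._docs):
                d = self._docs[uid]
                fh.write(json.dumps(
                    {"uid": d.uid, "modality": d.modality,
                     "source_path": d.source_path, "fields": d.fields},
                    sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, path: str | os.PathLike) -> "FeatureIndex":
        path = os.fspath(path)
        schema_path = os.path.join(path, "schema.json")
        docs_path = os.path.join(path, "documents.jsonl")
        if not os.path.isfile(schema_path) or not os.path.isfile(docs_path):
            raise IndexLoadError(f"{path!r} is not an index directory")
        try:
            with open(schema_path) as fh:
                schema = json.load(fh)
            if schema.get("format") != "dicomcbir-index":
                raise IndexLoadError(f"{path!r}: unrecognized schema {schema!r}")
            idx = cls()
            with open(docs_path) as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    raw = json.loads(line)
                    idx.add_document(FeatureDocument(
                        uid=raw["uid"], fields=raw["fields"],
                        modality=raw.get("modality", ""),
                        source_path=raw.get("source_path", "")))
            return idx
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise IndexLoadError(f"corrupt index store at {path!r}: {exc}") from exc
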
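"""Polygon annotation parsing, cleaning, and per-annotator rasterization.

Annotators outline tissue regions as polygons on single-grade core images and
attach a free-text or ontology explanation to each polygon.  This module
applies the cleaning conventions used to turn those raw records into one
exhaustive label mask per (image, annotator):

* free text is matched to ontology terms through a synonym table;
* polygons whose explanation field is empty inherit the explanation of the
  next later polygon that has one (polygons are drawn first, explanations
  chosen afterwards);
* polygons carrying several explanations are duplicated, one copy per term;
* rasterization draws polygons grouped by Gleason-pattern context ascending
  (GP3, then GP4, then GP5), within a group by creation order, with later
  polygons overwriting earlier ones; uncovered pixels are benign.

Coordinates are 0-based with x rightward and y downward; the origin is the
center of the top-left pixel, and a pixel belongs to a polygon iff its center
lies inside it (nonzero winding rule).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from PIL import Image

from .ontology import IGNORE_LABEL, ExplanationOntology, Level

logger = logging.getLogger(__name__)

_CONTEXT_ORDER = {None: -1, "GP3": 0, "GP4": 1, "GP5": 2}


class AnnotationSchemaError(ValueError):
    """Raised when an annotation file violates the documented record schema."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One polygon drawn by one annotator on one core image."""

    image_id: str
    annotator_id: str
    polygon: tuple[tuple[float, float], ...]
    created_rank: int
    pattern_context: str | None = None
    explanation_text: str | None = None
    term_ids: tuple[str, ...] = ()

    @property
    def term_id(self) -> str | None:
        """Single resolved term, or None; multi-label records must be expanded first."""
        if len(self.term_ids) > 1:
            raise ValueError("record carries multiple terms; run expand_multi_label first")
        return self.term_ids[0] if self.term_ids else None


@dataclass
class AnnotatorMask:
    """Exhaustive per-pixel labeling of one image by one annotator.

    ``labels`` indexes ``ontology.class_index(level)``; pixels covered by no
    polygon are benign (always the last class).
    """

    image_id: str
    annotator_id: str
    labels: np.ndarray
    level: Level = Level.SUB_EXPLANATION


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _as_record(raw: Mapping, idx: int, default_rank: int) -> AnnotationRecord:
    for key in ("image_id", "annotator_id", "polygon"):
        if key not in raw:
            raise AnnotationSchemaError(f"record #{idx}: missing field {key!r}")
    poly = tuple((float(x), float(y)) for x, y in raw["polygon"])
    if len(poly) < 3:
        raise AnnotationSchemaError(f"record #{idx}: polygon has {len(poly)} < 3 vertices")
    tids = raw.get("term_id") or ()
    if isinstance(tids, str):
        tids = (tids,)
    rank = raw.get("created_rank")
    if rank is None and "timestamp" in raw:
        rank = raw["timestamp"]
    context = raw.get("pattern_context")
    if context is not None and context not in ("GP3", "GP4", "GP5"):
        raise AnnotationSchemaError(f"record #{idx}: bad pattern_context {context!r}")
    return AnnotationRecord(
        image_id=str(raw["image_id"]),
        annotator_id=str(raw["annotator_id"]),
        polygon=poly,
        created_rank=default_rank if rank is None else rank,  # re-ranked below
        pattern_context=context,
        explanation_text=raw.get("explanation_text"),
        term_ids=tuple(tids),
    )


def read_annotations(path) -> list[AnnotationRecord]:
    """Read a JSON array of annotation records.

    ``created_rank`` is rebuilt per (image, annotator) from timestamps when
    present (ties broken by file order), else from record order in the file.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, list):
        raise AnnotationSchemaError("annotation file must be a JSON array")
    records = [_as_record(raw, i, i) for i, raw in enumerate(doc)]
    # normalize ranks to dense integers within each (image, annotator)
    out: list[AnnotationRecord] = [None] * len(records)  # type: ignore[list-item]
    groups: dict[tuple[str, str], list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault((rec.image_id, rec.annotator_id), []).append(i)
    for idxs in groups.values():
        try:
            order = sorted(idxs, key=lambda i: (records[i].created_rank, i))
        except TypeError as exc:
            raise AnnotationSchemaError("non-orderable timestamps in annotation file") from exc
        for rank, i in enumerate(order):
            out[i] = replace(records[i], created_rank=rank)
    return [r for r in out if r is not None]


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def _normalize_text(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip()).lower()


def build_synonym_table(ontology: ExplanationOntology) -> dict[str, str]:
    """Identity synonym table: every term's own long text and short name."""
    table: dict[str, str] = {}
    for node in ontology.nodes.values():
        if node.level in (Level.SUB_EXPLANATION, Level.EXPLANATION):
            table[_normalize_text(node.long_text)] = node.term_id
            table[_normalize_text(node.short_name)] = node.term_id
    return table


def resolve_free_text(
    records: Sequence[AnnotationRecord],
    synonym_table: Mapping[str, str],
    strict: bool = False,
) -> tuple[list[AnnotationRecord], list[AnnotationRecord]]:
    """Resolve ``explanation_text`` to ontology terms via the synonym table.

    Matching is case-insensitive after whitespace normalization.  Records that
    already carry ``term_ids`` pass through.  Returns (records, unresolved);
    in strict mode unresolved raw strings raise instead.
    """
    table = {_normalize_text(k): v for k, v in synonym_table.items()}
    resolved: list[AnnotationRecord] = []
    unresolved: list[AnnotationRecord] = []
    for rec in records:
        if rec.term_ids:
            resolved.append(rec)
            continue
        if rec.explanation_text:
            hit = table.get(_normalize_text(rec.explanation_text))
            if hit is not None:
                resolved.append(replace(rec, term_ids=(hit,)))
                continue
            unresolved.append(rec)
        resolved.append(rec)  # left with empty term_ids for the fill step
    if strict and unresolved:
        raw = sorted({r.explanation_text for r in unresolved if r.explanation_text})
        raise AnnotationSchemaError(f"unresolved explanation texts: {raw}")
    return resolved, unresolved


def fill_missing_explanations(
    records: Sequence[AnnotationRecord],
) -> list[AnnotationRecord]:
    """Forward-fill empty explanations from the next later labeled polygon.

    Records must belong to one (image, annotator) pair.  Trailing empties with
    no later donor are dropped with a warning.
    """
    keys = {(r.image_id, r.annotator_id) for r in records}
    if len(keys) > 1:
        raise AnnotationSchemaError(f"records span multiple (image, annotator) pairs: {sorted(keys)}")
    ordered = sorted(records, key=lambda r: r.created_rank)
    # walk backwards so each empty record sees the nearest *later* donor
    next_terms: tuple[str, ...] | None = None
    filled_rev: list[AnnotationRecord | None] = []
    for rec in reversed(ordered):
        if rec.term_ids:
            next_terms = rec.term_ids
            filled_rev.append(rec)
        elif next_terms is not None:
            filled_rev.append(replace(rec, term_ids=next_terms))
        else:
            logger.warning(
                "dropping trailing unlabeled polygon (image=%s annotator=%s rank=%d): "
                "no later record provides an explanation",
                rec.image_id, rec.annotator_id, rec.created_rank,
            )
            filled_rev.append(None)
    return [r for r in reversed(filled_rev) if r is not None]


def expand_multi_label(records: Sequence[AnnotationRecord]) -> list[AnnotationRecord]:
    """Duplicate polygons carrying k > 1 explanations into k single-term copies."""
    out: list[AnnotationRecord] = []
    for rec in records:
        if len(rec.term_ids) <= 1:
            out.append(rec)
        else:
            out.extend(replace(rec, term_ids=(t,)) for t in rec.term_ids)
    return out


def clean_records(
    records: Sequence[AnnotationRecord],
    synonym_table: Mapping[str, str],
    strict: bool = False,
) -> list[AnnotationRecord]:
    """resolve → fill → expand, grouped per (image, annotator)."""
    resolved, _ = resolve_free_text(records, synonym_table, strict=strict)
    groups: dict[tuple[str, str], list[AnnotationRecord]] = {}
    for rec in resolved:
        groups.setdefault((rec.image_id, rec.annotator_id), []).append(rec)
    out: list[AnnotationRecord] = []
    for key in sorted(groups):
        out.extend(expand_multi_label(fill_missing_explanations(groups[key])))
    return out


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _polygon_mask(polygon: Sequence[tuple[float, float]], shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon.

    Vertices are clipped to image bounds; the point test is matplotlib's
    nonzero-winding ``contains_points`` on integer pixel centers.
    """
    h, w = shape
    verts = np.asarray(polygon, dtype=np.float64)
    verts[:, 0] = np.clip(verts[:, 0], 0.0, w - 1.0)
    verts[:, 1] = np.clip(verts[:, 1], 0.0, h - 1.0)
    x0 = int(np.floor(verts[:, 0].min()))
    x1 = int(np.ceil(verts[:, 0].max()))
    y0 = int(np.floor(verts[:, 1].min()))
    y1 = int(np.ceil(verts[:, 1].max()))
    if x1 < x0 or y1 < y0:
        return np.zeros(shape, dtype=bool)
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    ring = np.vstack([verts, verts[:1]])  # closed=True consumes the last vertex
    inside = MplPath(ring, closed=True).contains_points(pts)
    mask = np.zeros(shape, dtype=bool)
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside.reshape(ys.shape)
    return mask


def rasterize(
    records: Sequence[AnnotationRecord],
    shape: tuple[int, int],
    ontology: ExplanationOntology,
    level: Level | str = Level.SUB_EXPLANATION,
    clip_outline: Sequence[tuple[float, float]] | None = None,
) -> AnnotatorMask:
    """Rasterize one annotator's cleaned records into an exhaustive label mask.

    Draw order: pattern context ascending (records without a context first),
    then creation rank; later polygons overwrite earlier ones.  Pixels no
    polygon covers stay benign.  ``clip_outline`` optionally restricts all
    drawing to a predefined region polygon (e.g. a grade outline); off by
    default.
    """
    level = Level(level)
    index = ontology.class_index(level)
    benign_idx = len(index) - 1
    labels = np.full(shape, benign_idx, dtype=np.int64)
    if not records:
        return AnnotatorMask(image_id="", annotator_id="", labels=labels, level=level)
    keys = {(r.image_id, r.annotator_id) for r in records}
    if len(keys) > 1:
        raise AnnotationSchemaError(f"rasterize expects one (image, annotator); got {sorted(keys)}")
    image_id, annotator_id = next(iter(keys))
    region = _polygon_mask(clip_outline, shape) if clip_outline is not None else None
    ordered = sorted(records, key=lambda r: (_CONTEXT_ORDER[r.pattern_context], r.created_rank))
    for rec in ordered:
        if not rec.term_ids:
            raise AnnotationSchemaError(
                f"unresolved record (image={rec.image_id} rank={rec.created_rank}); clean first"
            )
        for term in rec.term_ids:
            cls = index.index(ontology.ancestor_at_level(term, level))
            covered = _polygon_mask(rec.polygon, shape)
            if region is not None:
                covered &= region
            labels[covered] = cls
    return AnnotatorMask(image_id=image_id, annotator_id=annotator_id, labels=labels, level=level)


def scale_polygons(
    records: Sequence[AnnotationRecord], factor: float
) -> list[AnnotationRecord]:
    """Scale polygon vertices (e.g., spacing_in / spacing_out before rasterizing)."""
    return [
        replace(r, polygon=tuple((x * factor, y * factor) for x, y in r.polygon))
        for r in records
    ]


# ---------------------------------------------------------------------------
# mask serialization (palette PNG + JSON sidecar)
# ---------------------------------------------------------------------------

def write_mask(mask: AnnotatorMask, ontology: ExplanationOntology, path) -> None:
    """Write a mask as single-channel PNG plus a ``.json`` palette sidecar."""
    labels = mask.labels.astype(np.uint8)
    Image.fromarray(labels, mode="L").save(path)
    index = ontology.class_index(mask.level)
    sidecar = {
        "image_id": mask.image_id,
        "annotator_id": mask.annotator_id,
        "level": mask.level.value,
        "classes": {str(i): t for i, t in enumerate(index)},
        "ignore": IGNORE_LABEL,
    }
    with open(str(path) + ".json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)


def read_mask(path) -> tuple[np.ndarray, dict]:
    labels = np.asarray(Image.open(path), dtype=np.int64)
    with open(str(path) + ".json", "r", encoding="utf-8") as fh:
        sidecar = json.load(fh)
    return labels, sidecar
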
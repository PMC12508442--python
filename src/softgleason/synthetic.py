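"""Synthetic TMA-like cohorts with simulated, disagreeing annotators.

Each synthetic core is a white slide background with a textured circular
tissue disk; lesions are non-overlapping star-convex polygons whose fill
texture (base color + oriented sinusoidal modulation) is distinctive per
sub-explanation class, so small models can learn the mapping.  R simulated
annotators re-annotate the ground-truth polygons with controllable boundary
jitter, class confusion, polygon drop-out, and occasional multi-label
records — exercising the full ingest → fusion → training pipeline with no
external data.

The textures are procedurally distinct rather than histologically realistic:
the cohort tests the mechanism (label fusion, losses, remapping), not
histology.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from shapely.geometry import Polygon as ShapelyPolygon

from .ingest import (
    AnnotationRecord,
    AnnotatorMask,
    build_synonym_table,
    clean_records,
    rasterize,
)
from .fusion import build_soft_labels, majority_vote
from .ontology import ExplanationOntology, Level, default_ontology
from .preprocessing import tissue_mask as compute_tissue_mask
from .training import ImageItem

DEFAULT_CLASSES = (
    "individual_glands_open",     # Gleason pattern 3
    "poorly_formed_incomplete",   # Gleason pattern 4
    "single_cells_infiltrating",  # Gleason pattern 5
)

#: six-class preset with confusable pairs at every ontology depth: two
#: sub-explanations of one explanation, two explanations of GP4, and two of GP5.
RICH_CLASSES = (
    "individual_glands_open",
    "individual_glands_small",
    "poorly_formed_incomplete",
    "fused_glands_chains",
    "single_cells_infiltrating",
    "solid_groups_nests",
)

# distinct (base RGB, modulation frequency, orientation) per class; benign last
_TEXTURES = {
    "individual_glands_open": ((110, 190, 110), 0.45, 0.0),
    "individual_glands_small": ((55, 160, 85), 0.30, 0.8),
    "poorly_formed_incomplete": ((100, 130, 220), 0.20, 1.2),
    "poorly_formed_clear_cells": ((135, 175, 235), 0.55, 0.4),
    "fused_glands_chains": ((90, 90, 180), 0.75, 1.6),
    "single_cells_infiltrating": ((220, 100, 100), 0.65, 2.0),
    "solid_groups_nests": ((190, 70, 130), 0.10, 2.4),
    "benign": ((214, 168, 196), 0.06, 0.5),
}


@dataclass
class AnnotatorProfile:
    """Noise model for one simulated annotator.

    ``confusion`` is a row-stochastic K×K matrix over the cohort's lesion
    classes (row = true class, column = emitted class); ``jitter_sigma`` is
    the per-vertex Gaussian boundary perturbation in pixels; ``drop_prob``
    drops whole polygons; ``multi_label_prob`` emits a second label for a
    polygon (duplicating it downstream).
    """

    confusion: np.ndarray
    jitter_sigma: float = 0.0
    drop_prob: float = 0.0
    multi_label_prob: float = 0.0

    def __post_init__(self):
        self.confusion = np.asarray(self.confusion, dtype=np.float64)
        if not np.allclose(self.confusion.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion rows must sum to 1")
        if self.jitter_sigma < 0 or not (0 <= self.drop_prob <= 1) or not (
            0 <= self.multi_label_prob <= 1
        ):
            raise ValueError("invalid profile parameters")


def identity_profile(n_classes: int) -> AnnotatorProfile:
    return AnnotatorProfile(confusion=np.eye(n_classes))


def mild_profile(n_classes: int, diag: float = 0.95, jitter: float = 0.75,
                 drop: float = 0.03, multi: float = 0.05) -> AnnotatorProfile:
    """Mild annotator noise: the cohort's default disagreement level.

    Calibrated so that disagreement is visible in the fused labels yet a
    perfect predictor of the ground truth still scores well on the soft
    metrics — boundary jitter must stay small relative to the small default
    lesion radii (4–8 px) or it dominates every lesion's mass.
    """
    off = (1.0 - diag) / max(n_classes - 1, 1)
    conf = np.full((n_classes, n_classes), off)
    np.fill_diagonal(conf, diag if n_classes > 1 else 1.0)
    return AnnotatorProfile(confusion=conf, jitter_sigma=jitter, drop_prob=drop,
                            multi_label_prob=multi)


@dataclass
class SyntheticCohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults describe the desk-scale cohort: 40 cores of 64×64 px at the
    working resolution, 3 lesion classes spanning the three Gleason
    patterns, 2–4 lesions per core, and three mildly noisy annotators.
    """

    n_images: int = 40
    side: int = 64
    spacing: float = 1.392
    classes: tuple[str, ...] = DEFAULT_CLASSES
    n_blobs_range: tuple[int, int] = (2, 4)
    blob_radius_range: tuple[float, float] = (0.07, 0.12)  # fraction of side
    n_annotators: int = 3
    profiles: list[AnnotatorProfile] | None = None
    seed: int = 0

    def resolved_profiles(self) -> list[AnnotatorProfile]:
        if self.profiles is not None:
            if len(self.profiles) != self.n_annotators:
                raise ValueError("one profile per annotator required")
            return self.profiles
        return [mild_profile(len(self.classes)) for _ in range(self.n_annotators)]

    def content_hash(self) -> str:
        payload = {
            "n_images": self.n_images, "side": self.side, "spacing": self.spacing,
            "classes": list(self.classes), "n_blobs_range": list(self.n_blobs_range),
            "blob_radius_range": list(self.blob_radius_range),
            "n_annotators": self.n_annotators, "seed": self.seed,
            "profiles": [
                {"confusion": p.confusion.tolist(), "jitter_sigma": p.jitter_sigma,
                 "drop_prob": p.drop_prob, "multi_label_prob": p.multi_label_prob}
                for p in self.resolved_profiles()
            ],
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _star_polygon(rng: np.random.Generator, center, radius: float,
                  n_vertices: int = 10, wobble: float = 0.18):
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = radius * rng.uniform(1 - wobble, 1 + wobble, n_vertices)
    xs = center[0] + radii * np.cos(angles)
    ys = center[1] + radii * np.sin(angles)
    return list(zip(xs.tolist(), ys.tolist()))


def _texture(term_id: str, shape, rng: np.random.Generator) -> np.ndarray:
    base, freq, theta = _TEXTURES.get(term_id, ((150, 150, 150), 0.3, 0.0))
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    wave = np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)) / 8.0)
    img = np.empty((h, w, 3))
    for c in range(3):
        img[..., c] = base[c] + 18.0 * wave + rng.normal(0, 6.0, (h, w))
    return np.clip(img, 0, 255)


def generate_ground_truth(
    spec: SyntheticCohortSpec, rng: np.random.Generator, max_attempts: int = 200
) -> tuple[np.ndarray, list[tuple[list[tuple[float, float]], str]]]:
    """One synthetic core: white slide, textured tissue disk, labeled lesions.

    Lesion polygons are star-convex, mutually non-overlapping, and placed
    fully inside the tissue disk.  Raises if the requested packing cannot be
    achieved within ``max_attempts`` placement attempts per lesion.
    """
    side = spec.side
    center = (side / 2.0, side / 2.0)
    disk_radius = 0.45 * side
    yy, xx = np.mgrid[0:side, 0:side]
    disk = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= disk_radius**2

    image = np.full((side, side, 3), 250.0) + rng.normal(0, 2.0, (side, side, 3))
    image[disk] = _texture("benign", (side, side), rng)[disk]

    n_blobs = int(rng.integers(spec.n_blobs_range[0], spec.n_blobs_range[1] + 1))
    # vertices extend to ~1.18×radius (star wobble), hence the safety margins
    placements = None
    for _ in range(20):  # whole-image retries
        # stratified class assignment (cycled shuffled list) keeps cohort
        # class shares near-uniform despite random lesion areas
        order = rng.permutation(len(spec.classes))
        placed: list[tuple[tuple[float, float], float, str]] = []
        feasible = True
        for b in range(n_blobs):
            radius = float(rng.uniform(*spec.blob_radius_range)) * side
            term = spec.classes[int(order[b % len(order)])]
            ok = False
            for _ in range(max_attempts):
                max_off = disk_radius - 1.25 * radius
                if max_off <= 0:
                    break
                ang = rng.uniform(0, 2 * np.pi)
                off = max_off * np.sqrt(rng.uniform())
                c = (center[0] + off * np.cos(ang), center[1] + off * np.sin(ang))
                if all(np.hypot(c[0] - pc[0], c[1] - pc[1]) > 1.2 * (radius + pr)
                       for pc, pr, _t in placed):
                    ok = True
                    break
            if not ok:
                feasible = False
                break
            placed.append((c, radius, term))
        if feasible:
            placements = placed
            break
    if placements is None:
        raise RuntimeError(
            f"could not pack {n_blobs} lesions of radius "
            f"~{spec.blob_radius_range[1] * side:.1f} px into a disk of radius "
            f"{disk_radius:.1f} px"
        )
    from .ingest import _polygon_mask

    polygons: list[tuple[list[tuple[float, float]], str]] = []
    for c, radius, term in placements:
        verts = _star_polygon(rng, c, radius)
        polygons.append((verts, term))
        pmask = _polygon_mask(verts, (side, side))
        image[pmask] = _texture(term, (side, side), rng)[pmask]
    return np.clip(image, 0, 255).astype(np.uint8), polygons


# ---------------------------------------------------------------------------
# annotators
# ---------------------------------------------------------------------------

def _repair(verts: list[tuple[float, float]]) -> list[tuple[float, float]]:
    poly = ShapelyPolygon(verts)
    if poly.is_valid:
        return verts
    hull = poly.convex_hull
    if hull.geom_type != "Polygon":
        return verts
    return [(float(x), float(y)) for x, y in list(hull.exterior.coords)[:-1]]


def simulate_annotator(
    polygons: Sequence[tuple[list[tuple[float, float]], str]],
    profile: AnnotatorProfile,
    rng: np.random.Generator,
    ontology: ExplanationOntology,
    classes: Sequence[str],
    image_id: str,
    annotator_id: str,
) -> list[AnnotationRecord]:
    """One annotator's noisy re-annotation of the ground-truth polygons.

    Single-label records carry the emitted term's long text (exercising the
    free-text resolution path); multi-label records carry resolved term ids.
    Ranks follow ground-truth order.
    """
    class_idx = {c: i for i, c in enumerate(classes)}
    records: list[AnnotationRecord] = []
    rank = 0
    for verts, true_term in polygons:
        if rng.random() < profile.drop_prob:
            continue
        if profile.jitter_sigma > 0:
            jit = rng.normal(0, profile.jitter_sigma, size=(len(verts), 2))
            verts = _repair([(x + dx, y + dy) for (x, y), (dx, dy) in zip(verts, jit)])
        row = profile.confusion[class_idx[true_term]]
        emitted = classes[int(rng.choice(len(classes), p=row))]
        terms = [emitted]
        if rng.random() < profile.multi_label_prob and len(classes) > 1:
            second = classes[int(rng.choice(len(classes), p=row))]
            if second != emitted:
                terms.append(second)
        context = ontology.ancestor_at_level(true_term, Level.PATTERN)
        if len(terms) == 1:
            rec = AnnotationRecord(
                image_id=image_id, annotator_id=annotator_id,
                polygon=tuple((float(x), float(y)) for x, y in verts),
                created_rank=rank, pattern_context=context,
                explanation_text=ontology.nodes[terms[0]].long_text,
            )
        else:
            rec = AnnotationRecord(
                image_id=image_id, annotator_id=annotator_id,
                polygon=tuple((float(x), float(y)) for x, y in verts),
                created_rank=rank, pattern_context=context,
                term_ids=tuple(terms),
            )
        records.append(rec)
        rank += 1
    return records


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort_data(
    spec: SyntheticCohortSpec, ontology: ExplanationOntology | None = None
) -> dict:
    """In-memory cohort: images, truth masks, per-annotator records and masks."""
    ontology = ontology or default_ontology()
    rng = np.random.default_rng(spec.seed)
    synonyms = build_synonym_table(ontology)
    profiles = spec.resolved_profiles()
    cohort = {"spec": spec, "ontology": ontology, "images": {}}
    for i in range(spec.n_images):
        image_id = f"core{i:03d}"
        image, polygons = generate_ground_truth(spec, rng)
        truth_records = [
            AnnotationRecord(
                image_id=image_id, annotator_id="truth",
                polygon=tuple((float(x), float(y)) for x, y in verts),
                created_rank=r,
                pattern_context=ontology.ancestor_at_level(term, Level.PATTERN),
                term_ids=(term,),
            )
            for r, (verts, term) in enumerate(polygons)
        ]
        truth_mask = rasterize(truth_records, (spec.side, spec.side), ontology)
        annotators = {}
        for a in range(spec.n_annotators):
            aid = f"annot{a}"
            records = simulate_annotator(
                polygons, profiles[a], rng, ontology, spec.classes, image_id, aid
            )
            cleaned = clean_records(records, synonyms)
            mask = rasterize(cleaned, (spec.side, spec.side), ontology)
            if not cleaned:
                mask.image_id, mask.annotator_id = image_id, aid
            annotators[aid] = {"records": records, "mask": mask}
        cohort["images"][image_id] = {
            "image": image,
            "polygons": polygons,
            "truth_mask": truth_mask,
            "annotators": annotators,
        }
    return cohort


def cohort_items(
    cohort: dict, level: Level | str = Level.EXPLANATION
) -> tuple[list[ImageItem], dict[str, AnnotatorMask]]:
    """Fuse a cohort into trainer-ready items plus ground-truth masks."""
    ontology = cohort["ontology"]
    level = Level(level)
    items = []
    truths = {}
    for image_id, entry in cohort["images"].items():
        masks = [a["mask"] for a in entry["annotators"].values()]
        tissue = compute_tissue_mask(entry["image"])
        soft = build_soft_labels(masks, ontology, level, tissue, image_id=image_id)
        hard = majority_vote(masks, ontology, level, image_id=image_id)
        items.append(ImageItem(image_id=image_id, image=entry["image"],
                               soft=soft, hard=hard, tissue=tissue))
        truths[image_id] = entry["truth_mask"]
    return items, truths


def generate_cohort(spec: SyntheticCohortSpec, out_dir) -> Path:
    """Write a cohort fixture tree: images/, annotations/, truth/, manifest.json.

    Regenerating with the manifest's seed reproduces the tree byte-for-byte;
    partial trees from failed runs are removed.
    """
    out = Path(out_dir)
    started = False
    try:
        cohort = generate_cohort_data(spec)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "annotations").mkdir(exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)
        started = True
        n_records = 0
        for image_id, entry in cohort["images"].items():
            Image.fromarray(entry["image"]).save(out / "images" / f"{image_id}.png")
            Image.fromarray(entry["truth_mask"].labels.astype(np.uint8), mode="L").save(
                out / "truth" / f"{image_id}.png"
            )
            for aid, a in entry["annotators"].items():
                recs = [
                    {
                        "image_id": r.image_id,
                        "annotator_id": r.annotator_id,
                        "pattern_context": r.pattern_context,
                        "polygon": [[x, y] for x, y in r.polygon],
                        "created_rank": r.created_rank,
                        "explanation_text": r.explanation_text,
                        "term_id": list(r.term_ids) if r.term_ids else None,
                    }
                    for r in a["records"]
                ]
                n_records += len(recs)
                with open(out / "annotations" / f"{image_id}_{aid}.json", "w") as fh:
                    json.dump(recs, fh, indent=1)
        manifest = {
            "n_images": spec.n_images,
            "n_annotators": spec.n_annotators,
            "n_records": n_records,
            "seed": spec.seed,
            "spec_hash": spec.content_hash(),
            "classes": list(spec.classes),
            "side": spec.side,
            "spacing": spec.spacing,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return out
    except Exception:
        if started:
            shutil.rmtree(out, ignore_errors=True)
        raise
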
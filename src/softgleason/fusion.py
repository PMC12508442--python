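"""Multi-annotator label fusion: soft labels, majority vote, STAPLE, agreement.

Soft labels keep the full annotation distribution: the per-pixel probability
of class *c* is the fraction of raters whose annotation maps to *c* at the
requested ontology level.  Majority voting collapses the distribution to the
unique modal class, marking pixels without one (ties, three-way disagreement)
with the ignore label.  STAPLE estimates a consensus segmentation together
with per-rater confusion matrices by expectation-maximization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ingest import AnnotatorMask
from .ontology import IGNORE_LABEL, ExplanationOntology, Level


@dataclass
class SoftLabelMap:
    """Per-pixel probability distribution over ``class_index(level)``.

    On foreground pixels each channel is a multiple of 1/R and channels sum
    to 1; off-foreground values are never read by losses or metrics.
    """

    image_id: str
    level: Level
    dist: np.ndarray  # H×W×C float32
    foreground: np.ndarray  # H×W bool
    n_raters: int


@dataclass
class HardLabelMap:
    image_id: str
    level: Level
    labels: np.ndarray  # H×W int, IGNORE_LABEL where no unique majority


@dataclass
class RaterPerformance:
    """Per-rater confusion matrices estimated by STAPLE (rows: true class)."""

    confusion: np.ndarray  # R×C×C, rows sum to 1
    iterations: int
    converged: bool


@dataclass
class PixelAgreementStats:
    """Foreground agreement fractions at each ontology level.

    ``per_level[level]`` holds ``unique_majority``, ``two_rater`` and
    ``three_rater`` fractions of foreground pixels; ``per_class[level]`` maps
    each term to the fraction of its annotated pixels marked by exactly
    1, 2, … R raters.
    """

    foreground_fraction: float
    per_level: dict[str, dict[str, float]] = field(default_factory=dict)
    per_class: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)


def _stacked_labels(
    masks: Sequence[AnnotatorMask], ontology: ExplanationOntology, level: Level
) -> np.ndarray:
    """R×H×W integer labels remapped from each mask's native level."""
    shapes = {m.labels.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"annotator masks disagree in shape: {sorted(shapes)}")
    out = []
    for m in masks:
        if Level(m.level) is Level(level):
            out.append(m.labels)
        else:
            out.append(ontology.remap_hard(m.labels, m.level, level))
    return np.stack(out)


def _vote_counts(stacked: np.ndarray, n_classes: int) -> np.ndarray:
    """H×W×C per-pixel vote counts from R×H×W labels."""
    r, h, w = stacked.shape
    counts = np.zeros((h * w, n_classes), dtype=np.int32)
    flat = stacked.reshape(r, -1)
    for i in range(r):
        np.add.at(counts, (np.arange(h * w), flat[i]), 1)
    return counts.reshape(h, w, n_classes)


def build_soft_labels(
    masks: Sequence[AnnotatorMask],
    ontology: ExplanationOntology,
    level: Level | str,
    foreground: np.ndarray,
    image_id: str = "",
) -> SoftLabelMap:
    """Fuse R annotator masks into a per-pixel annotation distribution."""
    level = Level(level)
    stacked = _stacked_labels(masks, ontology, level)
    counts = _vote_counts(stacked, ontology.n_classes(level))
    dist = (counts / float(len(masks))).astype(np.float32)
    return SoftLabelMap(
        image_id=image_id or masks[0].image_id,
        level=level,
        dist=dist,
        foreground=np.asarray(foreground, dtype=bool),
        n_raters=len(masks),
    )


def majority_vote(
    masks: Sequence[AnnotatorMask],
    ontology: ExplanationOntology,
    level: Level | str,
    image_id: str = "",
) -> HardLabelMap:
    """Unique modal class per pixel; any tie becomes the ignore label."""
    level = Level(level)
    stacked = _stacked_labels(masks, ontology, level)
    counts = _vote_counts(stacked, ontology.n_classes(level))
    top = counts.max(axis=-1)
    unique = (counts == top[..., None]).sum(axis=-1) == 1
    labels = np.where(unique, counts.argmax(axis=-1), IGNORE_LABEL).astype(np.int64)
    return HardLabelMap(image_id=image_id or masks[0].image_id, level=level, labels=labels)


# ---------------------------------------------------------------------------
# STAPLE
# ---------------------------------------------------------------------------

def staple_consensus(
    masks: Sequence[AnnotatorMask] | Sequence[np.ndarray],
    n_classes: int,
    max_iter: int = 100,
    tol: float = 1e-6,
    init_diagonal: float = 0.95,
    level: Level | str = Level.PATTERN,
    image_id: str = "",
) -> tuple[HardLabelMap, RaterPerformance]:
    """Multi-category STAPLE consensus by expectation-maximization.

    E-step: posterior over the latent true class per pixel from the current
    per-rater confusion matrices and the empirical class prior.  M-step:
    re-estimate each rater's confusion matrix from the posteriors.  Iterates
    until the largest confusion-matrix change falls below ``tol`` or
    ``max_iter`` is hit.  The consensus is the per-pixel argmax posterior
    (ties broken by class order); there is no ignore label.

    Classes never emitted by any rater are dropped from the estimation and
    restored afterwards as never-selected (identity confusion rows).
    """
    arrs = [m.labels if isinstance(m, AnnotatorMask) else np.asarray(m) for m in masks]
    if len(arrs) < 2:
        raise ValueError("STAPLE needs at least 2 raters")
    if n_classes < 2:
        raise ValueError("STAPLE needs at least 2 classes")
    stacked = np.stack(arrs)  # R×H×W
    r, h, w = stacked.shape
    used = np.zeros(n_classes, dtype=bool)
    used[np.unique(stacked)] = True
    active = np.flatnonzero(used)
    k = active.size
    compress = np.full(n_classes, -1, dtype=np.int64)
    compress[active] = np.arange(k)
    votes = compress[stacked.reshape(r, -1)]  # R×P in compressed space

    # compress identical vote patterns: EM cost scales with distinct patterns
    patterns, inverse, counts = np.unique(
        votes.T, axis=0, return_inverse=True, return_counts=True
    )
    m = patterns.shape[0]
    prior = np.bincount(votes.ravel(), minlength=k).astype(np.float64)
    prior /= prior.sum()

    theta = np.full((r, k, k), (1.0 - init_diagonal) / max(k - 1, 1))
    theta[:, np.arange(k), np.arange(k)] = init_diagonal if k > 1 else 1.0

    iterations = 0
    converged = False
    weights = np.empty((m, k))
    for iterations in range(1, max_iter + 1):
        # E-step on unique patterns
        log_w = np.log(np.maximum(prior, 1e-300))[None, :].repeat(m, axis=0)
        for j in range(r):
            log_w += np.log(np.maximum(theta[j][:, patterns[:, j]].T, 1e-300))
        log_w -= log_w.max(axis=1, keepdims=True)
        weights = np.exp(log_w)
        weights /= weights.sum(axis=1, keepdims=True)

        # M-step
        new_theta = np.empty_like(theta)
        weighted = weights * counts[:, None]  # m×k
        denom = weighted.sum(axis=0)  # k
        for j in range(r):
            num = np.zeros((k, k))
            np.add.at(num.T, patterns[:, j], weighted)
            new_theta[j] = num / np.maximum(denom[:, None], 1e-300)
        delta = np.abs(new_theta - theta).max()
        theta = new_theta
        if delta < tol:
            converged = True
            break

    consensus_small = weights.argmax(axis=1)
    consensus = active[consensus_small[inverse]].reshape(h, w)

    confusion = np.zeros((r, n_classes, n_classes))
    confusion[:, np.arange(n_classes), np.arange(n_classes)] = 1.0  # dropped classes
    for a, ca in enumerate(active):
        for b, cb in enumerate(active):
            confusion[:, ca, cb] = theta[:, a, b]
    hard = HardLabelMap(
        image_id=image_id or getattr(masks[0], "image_id", ""),
        level=Level(level),
        labels=consensus.astype(np.int64),
    )
    return hard, RaterPerformance(confusion=confusion, iterations=iterations, converged=converged)


# ---------------------------------------------------------------------------
# pixel agreement
# ---------------------------------------------------------------------------

def pixel_agreement(
    masks_per_image: Sequence[Sequence[AnnotatorMask]],
    ontology: ExplanationOntology,
    foregrounds: Sequence[np.ndarray],
) -> PixelAgreementStats:
    """Cohort-level pixel agreement fractions at all three ontology levels.

    Agreement is evaluated over foreground pixels only.  ``two_rater`` /
    ``three_rater`` are the fractions whose top vote count equals exactly
    2 or 3 (with a unique modal class); ``per_class`` stratifies each class's
    annotated pixels by how many raters marked them.
    """
    if not masks_per_image:
        raise ValueError("need at least one image")
    total_pixels = 0
    fg_pixels = 0
    level_acc: dict[str, dict[str, float]] = {}
    class_acc: dict[str, np.ndarray] = {}
    n_raters = len(masks_per_image[0])
    for lvl in (Level.PATTERN, Level.EXPLANATION, Level.SUB_EXPLANATION):
        level_acc[lvl.value] = {"unique_majority": 0.0, "two_rater": 0.0, "three_rater": 0.0}
        class_acc[lvl.value] = np.zeros((ontology.n_classes(lvl), n_raters))
    for masks, fg in zip(masks_per_image, foregrounds):
        fg = np.asarray(fg, dtype=bool)
        total_pixels += fg.size
        fg_pixels += int(fg.sum())
        for lvl in (Level.PATTERN, Level.EXPLANATION, Level.SUB_EXPLANATION):
            stacked = _stacked_labels(masks, ontology, lvl)
            counts = _vote_counts(stacked, ontology.n_classes(lvl))[fg]
            top = counts.max(axis=-1)
            unique = (counts == top[..., None]).sum(axis=-1) == 1
            d = level_acc[lvl.value]
            d["unique_majority"] += float(unique.sum())
            d["two_rater"] += float((unique & (top == 2)).sum())
            d["three_rater"] += float((top == len(masks)).sum())
            for c in range(counts.shape[-1]):
                marked = counts[:, c]
                class_acc[lvl.value][c] += np.bincount(
                    marked[marked > 0], minlength=n_raters + 1
                )[1:]
    if fg_pixels == 0:
        raise ValueError("empty foreground across the cohort")
    stats = PixelAgreementStats(foreground_fraction=fg_pixels / total_pixels)
    for lvl_name, d in level_acc.items():
        stats.per_level[lvl_name] = {k: v / fg_pixels for k, v in d.items()}
        totals = class_acc[lvl_name].sum(axis=1, keepdims=True)
        fractions = class_acc[lvl_name] / np.maximum(totals, 1.0)
        index = ontology.class_index(lvl_name)
        stats.per_class[lvl_name] = {t: fractions[i] for i, t in enumerate(index)}
    return stats


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_soft_labels(soft: SoftLabelMap, ontology: ExplanationOntology, path) -> None:
    """Write a soft-label map as a multi-channel TIFF plus a channel manifest.

    Channels follow ``class_index(level)``; the foreground mask is stored as
    an extra 0/1 channel after the class channels.
    """
    import tifffile

    stack = np.concatenate(
        [np.moveaxis(soft.dist, -1, 0), soft.foreground[None].astype(np.float32)]
    ).astype(np.float32)
    tifffile.imwrite(path, stack)
    manifest = {
        "image_id": soft.image_id,
        "level": Level(soft.level).value,
        "n_raters": soft.n_raters,
        "channels": list(ontology.class_index(soft.level)) + ["__foreground__"],
    }
    with open(str(path) + ".json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)


def read_soft_labels(path) -> SoftLabelMap:
    import tifffile

    stack = tifffile.imread(path)
    with open(str(path) + ".json", "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    dist = np.moveaxis(stack[:-1], 0, -1)
    return SoftLabelMap(
        image_id=manifest["image_id"],
        level=Level(manifest["level"]),
        dist=dist,
        foreground=stack[-1] > 0.5,
        n_raters=int(manifest["n_raters"]),
    )


def write_hard_labels(hard: HardLabelMap, ontology: ExplanationOntology, path) -> None:
    """Write a hard-label map as single-channel PNG (ignore = 255) + sidecar."""
    from PIL import Image

    Image.fromarray(hard.labels.astype(np.uint8), mode="L").save(path)
    sidecar = {
        "image_id": hard.image_id,
        "level": Level(hard.level).value,
        "classes": {str(i): t for i, t in enumerate(ontology.class_index(hard.level))},
        "ignore": IGNORE_LABEL,
    }
    with open(str(path) + ".json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)


def read_hard_labels(path) -> HardLabelMap:
    from PIL import Image

    with open(str(path) + ".json", "r", encoding="utf-8") as fh:
        sidecar = json.load(fh)
    labels = np.asarray(Image.open(path), dtype=np.int64)
    return HardLabelMap(
        image_id=sidecar["image_id"], level=Level(sidecar["level"]), labels=labels
    )
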
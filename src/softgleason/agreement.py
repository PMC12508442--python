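"""Image-level interobserver agreement: presence decisions and Fleiss' kappa.

Each annotator's mask is binarized per image into presence decisions — did
the annotator use any class mapping to a given label at the chosen ontology
level?  Benign is excluded from the label axis (with the canonical ontology
this yields nine decisions per image and annotator at the explanation
level).  Fleiss' kappa with categories {used, not used} then quantifies
chance-corrected agreement per label within each fixed group of raters, and
percentile bootstrap over images yields confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

from .ingest import AnnotatorMask
from .ontology import ExplanationOntology, Level


@dataclass
class PresenceDecisionTable:
    """Binary tensor images × annotators × labels ("used at least once")."""

    decisions: np.ndarray  # bool, I×R×L
    image_ids: tuple[str, ...]
    annotator_ids: tuple[str, ...]
    labels: tuple[str, ...]  # benign excluded
    level: Level
    group_id: str = ""


@dataclass
class KappaReport:
    per_label_per_group: dict[tuple[str, str], float]
    per_label_per_group_ci: dict[tuple[str, str], tuple[float, float]]
    per_group_overall: dict[str, float]
    per_label_overall: dict[str, float]
    group_sizes: dict[str, int]
    bootstrap: dict = field(default_factory=dict)


def presence_decisions(
    masks_per_image: Mapping[str, Sequence[AnnotatorMask]],
    ontology: ExplanationOntology,
    level: Level | str,
    group_id: str = "",
) -> PresenceDecisionTable:
    """Binarize each annotator's mask into per-label presence decisions."""
    level = Level(level)
    labels = ontology.class_index(level)[:-1]  # drop benign
    image_ids = tuple(sorted(masks_per_image))
    annotator_sets = {tuple(m.annotator_id for m in masks_per_image[i]) for i in image_ids}
    if len(annotator_sets) != 1:
        raise ValueError(f"annotator group differs across images: {sorted(annotator_sets)}")
    annotator_ids = next(iter(annotator_sets))
    dec = np.zeros((len(image_ids), len(annotator_ids), len(labels)), dtype=bool)
    for i, image_id in enumerate(image_ids):
        for r, mask in enumerate(masks_per_image[image_id]):
            lut = ontology.remap_lookup(mask.level, level)
            used = np.unique(lut[np.unique(mask.labels)])
            for c in used:
                if c < len(labels):
                    dec[i, r, c] = True
    return PresenceDecisionTable(
        decisions=dec,
        image_ids=image_ids,
        annotator_ids=tuple(annotator_ids),
        labels=labels,
        level=level,
        group_id=group_id,
    )


def fleiss_kappa(decisions: np.ndarray) -> float:
    """Fleiss' kappa for binary decisions (subjects × raters).

    κ = (P̄ − P̄ₑ)/(1 − P̄ₑ) with categories {used, not used}.  In the
    degenerate case P̄ₑ = 1 (every decision identical) with perfect observed
    agreement the convention is κ = 1.
    """
    decisions = np.asarray(decisions, dtype=bool)
    if decisions.ndim != 2:
        raise ValueError("decisions must be subjects × raters")
    n_subjects, n_raters = decisions.shape
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    used = decisions.sum(axis=1)
    table = np.column_stack([used, n_raters - used])
    if np.all(used == 0) or np.all(used == n_raters):
        return 1.0  # P̄ₑ = 1 and P̄ = 1
    return float(_sm_fleiss(table, method="fleiss"))


def _defined(decisions: np.ndarray) -> bool:
    """A label-in-group kappa cell is defined only if the label was used at
    least once by someone."""
    return bool(np.asarray(decisions).any())


def kappa_report(
    tables: Sequence[PresenceDecisionTable],
    B: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
    pool_labels: bool = True,
) -> KappaReport:
    """Kappa per label/group with bootstrap CIs, plus pooled summaries.

    * per-label-per-group: subjects are images (one binary decision each);
      a label never used by anyone in the group is reported as NaN and
      excluded from the summaries (the group count for that label shrinks).
    * per-group overall: all (image, label) decisions of the group pooled.
    * per-label overall: groups pooled by concatenating their image subjects
      (set ``pool_labels=False`` to average group kappas instead).
    * CIs: percentile bootstrap over images, ``B`` resamples, seeded; the
      interval is widened to contain the point estimate when the resampling
      distribution is one-sided.
    """
    rng = np.random.default_rng(seed)
    alpha = 1.0 - ci_level
    per_lg: dict[tuple[str, str], float] = {}
    per_lg_ci: dict[tuple[str, str], tuple[float, float]] = {}
    per_group: dict[str, float] = {}
    group_sizes: dict[str, int] = {}
    by_label: dict[str, list[np.ndarray]] = {}
    kappas_by_label: dict[str, list[float]] = {}
    for g, table in enumerate(tables):
        gid = table.group_id or f"group{g}"
        n_img = table.decisions.shape[0]
        group_sizes[gid] = n_img
        for li, label in enumerate(table.labels):
            dec = table.decisions[:, :, li]  # images × raters
            by_label.setdefault(label, []).append(dec)
            if not _defined(dec):
                per_lg[(label, gid)] = float("nan")
                per_lg_ci[(label, gid)] = (float("nan"), float("nan"))
                continue
            k = fleiss_kappa(dec)
            per_lg[(label, gid)] = k
            boot = []
            for _ in range(B):
                idx = rng.integers(0, n_img, size=n_img)
                sub = dec[idx]
                if _defined(sub):
                    boot.append(fleiss_kappa(sub))
            if boot:
                lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
                per_lg_ci[(label, gid)] = (min(float(lo), k), max(float(hi), k))
            else:
                per_lg_ci[(label, gid)] = (k, k)
            kappas_by_label.setdefault(label, []).append(k)
        # per-group overall: pool image×label pairs as subjects
        pooled = table.decisions.transpose(0, 2, 1).reshape(-1, table.decisions.shape[1])
        per_group[gid] = fleiss_kappa(pooled)
    per_label: dict[str, float] = {}
    for label, decs in by_label.items():
        if pool_labels:
            cat = np.concatenate(decs, axis=0)
            per_label[label] = fleiss_kappa(cat) if _defined(cat) else float("nan")
        else:
            ks = kappas_by_label.get(label, [])
            per_label[label] = float(np.mean(ks)) if ks else float("nan")
    return KappaReport(
        per_label_per_group=per_lg,
        per_label_per_group_ci=per_lg_ci,
        per_group_overall=per_group,
        per_label_overall=per_label,
        group_sizes=group_sizes,
        bootstrap={"B": B, "ci_level": ci_level, "seed": seed},
    )


def kappa_report_to_frame(report: KappaReport):
    """Flatten a kappa report into a tidy table (label, group, kappa, CI, n)."""
    import pandas as pd

    rows = []
    for (label, group), kappa in report.per_label_per_group.items():
        lo, hi = report.per_label_per_group_ci[(label, group)]
        rows.append({
            "label": label, "group": group, "kappa": kappa,
            "ci_low": lo, "ci_high": hi,
            "n_images": report.group_sizes.get(group, float("nan")),
        })
    return pd.DataFrame(rows)
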
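"""Soft- and hard-label segmentation losses and evaluation metrics.

Soft losses compare a predicted per-pixel distribution with the annotation
distribution over the tissue foreground; hard losses and metrics are
restricted to foreground pixels that possess an unambiguous majority vote
(the "hard population", a subset of the soft one).

The soft Dice family uses per-class mass overlaps.  The *loss* form is

    d_c = (2 Σ_p p_c y_c + ε) / (Σ_p p_c + Σ_p y_c + ε),   loss = 1 − mean_c d_c,

a direct extension of the Macro Dice loss to targets in [0, 1].  The *metric*
form (Macro SoftDice) is the L1-based semimetric

    D_c = (‖p‖₁ + ‖y‖₁ − ‖p−y‖₁) / (2 (α‖p‖₁ + β‖y‖₁)),

which equals 1 iff p = y on the evaluated pixels and reduces to the classical
per-class Dice on one-hot inputs.  The L1-norm calibration metric is

    L1 = 1/(2NCP) Σ_{n,c,p} |p − y|,

averaged per image over its masked pixels and then over images.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fusion import HardLabelMap, SoftLabelMap
from .ontology import IGNORE_LABEL


class ZeroSupportPolicy(str, enum.Enum):
    EXCLUDE_CLASS = "exclude_class"
    SCORE_ONE = "score_one"


@dataclass
class LossConfig:
    epsilon: float = 1e-6
    loss_kind: str = "soft_dice"  # soft_dice | soft_ce | hard_dice | hard_ce

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class MetricConfig:
    alpha: float = 0.5
    beta: float = 0.5
    zero_support_policy: ZeroSupportPolicy = ZeroSupportPolicy.EXCLUDE_CLASS

    def __post_init__(self):
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError("alpha + beta must equal 1")


@dataclass
class MetricReport:
    level: str
    macro_soft_dice: float
    l1_norm: float
    dice: float
    macro_dice: float
    per_class_dice: dict[str, float]
    confusion_counts: np.ndarray
    confusion_percent: np.ndarray
    n_pixels_soft: int
    n_pixels_hard: int

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "macro_soft_dice": self.macro_soft_dice,
            "l1_norm": self.l1_norm,
            "dice": self.dice,
            "macro_dice": self.macro_dice,
            "per_class_dice": self.per_class_dice,
            "n_pixels_soft": self.n_pixels_soft,
            "n_pixels_hard": self.n_pixels_hard,
        }


def _flatten(pred: np.ndarray, target: np.ndarray, mask: np.ndarray):
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty evaluation mask")
    return pred[mask], target[mask]


# ---------------------------------------------------------------------------
# losses (value + gradient in prediction space, for the numpy trainer)
# ---------------------------------------------------------------------------

def soft_dice_loss(
    pred: np.ndarray,
    target: np.ndarray | SoftLabelMap,
    mask: np.ndarray,
    cfg: LossConfig = LossConfig(),
    grad: bool = False,
):
    """Soft Dice loss: 1 − mean_c (2 Σ p·y + ε)/(Σ p + Σ y + ε) over masked pixels."""
    tgt = target.dist if isinstance(target, SoftLabelMap) else target
    p, y = _flatten(pred, tgt, mask)
    eps = cfg.epsilon
    inter = (p * y).sum(axis=0)
    psum = p.sum(axis=0)
    ysum = y.sum(axis=0)
    d = (2.0 * inter + eps) / (psum + ysum + eps)
    loss = float(1.0 - d.mean())
    if not grad:
        return loss
    c = p.shape[-1]
    # d(loss)/dp = -(1/C) * [2 y (den) - (2 inter + eps)] / den^2
    den = psum + ysum + eps
    gflat = -(2.0 * y * den - (2.0 * inter + eps)) / (den**2) / c
    g = np.zeros_like(pred)
    g[np.asarray(mask, dtype=bool)] = gflat
    return loss, g


def soft_cross_entropy(
    pred: np.ndarray,
    target: np.ndarray | SoftLabelMap,
    mask: np.ndarray,
    grad: bool = False,
    clamp: float = 1e-12,
):
    """Mean over masked pixels of −Σ_c y_c log p_c."""
    tgt = target.dist if isinstance(target, SoftLabelMap) else target
    p, y = _flatten(pred, tgt, mask)
    pc = np.maximum(p, clamp)
    loss = float(-(y * np.log(pc)).sum(axis=-1).mean())
    if not grad:
        return loss
    g = np.zeros_like(pred)
    g[np.asarray(mask, dtype=bool)] = -(y / pc) / p.shape[0]
    return loss, g


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros(labels.shape + (n_classes,), dtype=np.float64)
    valid = labels != IGNORE_LABEL
    out[valid, labels[valid]] = 1.0
    return out


def hard_dice_loss(
    pred: np.ndarray,
    target: np.ndarray | HardLabelMap,
    mask: np.ndarray,
    cfg: LossConfig = LossConfig(),
    grad: bool = False,
):
    """Class-averaged Dice loss against one-hot majority labels (ignore excluded)."""
    labels = target.labels if isinstance(target, HardLabelMap) else target
    eff = np.asarray(mask, dtype=bool) & (labels != IGNORE_LABEL)
    if not eff.any():
        raise ValueError("all pixels ignored or off-mask")
    onehot = _one_hot(labels, pred.shape[-1])
    return soft_dice_loss(pred, onehot, eff, cfg, grad=grad)


def hard_cross_entropy(
    pred: np.ndarray,
    target: np.ndarray | HardLabelMap,
    mask: np.ndarray,
    grad: bool = False,
):
    """Standard cross-entropy with ignore index, over masked non-ignore pixels."""
    labels = target.labels if isinstance(target, HardLabelMap) else target
    eff = np.asarray(mask, dtype=bool) & (labels != IGNORE_LABEL)
    if not eff.any():
        raise ValueError("all pixels ignored or off-mask")
    onehot = _one_hot(labels, pred.shape[-1])
    return soft_cross_entropy(pred, onehot, eff, grad=grad)


LOSSES = {
    "soft_dice": soft_dice_loss,
    "soft_ce": soft_cross_entropy,
    "hard_dice": hard_dice_loss,
    "hard_ce": hard_cross_entropy,
}


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def macro_soft_dice(
    pred: np.ndarray,
    target: np.ndarray | SoftLabelMap,
    mask: np.ndarray,
    cfg: MetricConfig = MetricConfig(),
) -> float:
    """L1-semimetric soft Dice, averaged over classes.

    Equals 1 iff pred == target on masked pixels; with α = β = 0.5 it is
    symmetric and reduces to the classical Dice on one-hot inputs.
    """
    tgt = target.dist if isinstance(target, SoftLabelMap) else target
    p, y = _flatten(pred, tgt, mask)
    pnorm = p.sum(axis=0)
    ynorm = y.sum(axis=0)
    l1 = np.abs(p - y).sum(axis=0)
    den = 2.0 * (cfg.alpha * pnorm + cfg.beta * ynorm)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (pnorm + ynorm - l1) / den
    empty = den == 0
    if empty.any():
        if cfg.zero_support_policy is ZeroSupportPolicy.SCORE_ONE:
            d = np.where(empty, 1.0, d)
        else:
            d = d[~empty]
    if d.size == 0:
        raise ValueError("no class has support in prediction or target")
    return float(d.mean())


def l1_metric(
    preds: Sequence[np.ndarray] | np.ndarray,
    targets: Sequence[np.ndarray | SoftLabelMap] | np.ndarray | SoftLabelMap,
    masks: Sequence[np.ndarray] | np.ndarray,
    normalizer: str = "2ncp",
) -> float:
    """Normalized L1 distance between predictive and target distributions.

    Default divides by 2·N·C·P (the printed form, bounded by 1/C); the
    alternative ``normalizer='2np'`` divides by 2·N·P so that fully disjoint
    one-hot distributions score 1.  P is the per-image masked-pixel count;
    per-image values are averaged over the N images.
    """
    if isinstance(preds, np.ndarray):
        preds, targets, masks = [preds], [targets], [masks]
    vals = []
    for pred, target, mask in zip(preds, targets, masks):
        tgt = target.dist if isinstance(target, SoftLabelMap) else target
        p, y = _flatten(pred, tgt, mask)
        c = p.shape[-1]
        denom = 2.0 * p.shape[0] * (c if normalizer == "2ncp" else 1.0)
        vals.append(np.abs(p - y).sum() / denom)
    return float(np.mean(vals))


def confusion(
    pred_labels: np.ndarray,
    target: np.ndarray | HardLabelMap,
    mask: np.ndarray,
    n_classes: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Confusion matrix (rows: majority label, cols: prediction) as counts
    and row-normalized percentages."""
    labels = target.labels if isinstance(target, HardLabelMap) else target
    eff = np.asarray(mask, dtype=bool) & (labels != IGNORE_LABEL)
    if not eff.any():
        raise ValueError("empty evaluation population")
    t = labels[eff].ravel()
    p = pred_labels[eff].ravel()
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    rows = counts.sum(axis=1, keepdims=True).astype(np.float64)
    with np.errstate(invalid="ignore"):
        percent = np.where(rows > 0, 100.0 * counts / rows, 0.0)
    return counts, percent


def hard_dice_metrics(
    pred_labels: np.ndarray,
    target: np.ndarray | HardLabelMap,
    mask: np.ndarray,
    n_classes: int,
    policy: ZeroSupportPolicy = ZeroSupportPolicy.EXCLUDE_CLASS,
) -> tuple[float, float, np.ndarray]:
    """(global Dice, Macro Dice, per-class Dice) over the hard population.

    Global Dice = 2ΣTP / (2ΣTP + ΣFP + ΣFN), which for exclusive per-pixel
    labels equals pixel accuracy; Macro Dice averages per-class Dice over
    classes with support (per ``policy``).
    """
    counts, _ = confusion(pred_labels, target, mask, n_classes)
    tp = np.diag(counts).astype(np.float64)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    global_dice = 2.0 * tp.sum() / (2.0 * tp.sum() + fp.sum() + fn.sum())
    den = 2.0 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(den > 0, 2.0 * tp / den, np.nan)
    supported = den > 0
    if policy is ZeroSupportPolicy.SCORE_ONE:
        macro_vals = np.where(supported, per_class, 1.0)
    else:
        macro_vals = per_class[supported]
    macro = float(np.mean(macro_vals)) if macro_vals.size else float("nan")
    return float(global_dice), macro, per_class


def metric_report(
    pred_dist: np.ndarray,
    soft_target: SoftLabelMap,
    hard_target: HardLabelMap,
    class_names: Sequence[str],
    level: str,
    metric_cfg: MetricConfig = MetricConfig(),
    l1_normalizer: str = "2ncp",
) -> MetricReport:
    """Full metric report for one image (or a stitched cohort)."""
    fg = soft_target.foreground
    pred_labels = pred_dist.argmax(axis=-1)
    hard_pop = fg & (hard_target.labels != IGNORE_LABEL)
    n_classes = len(class_names)
    dice, macro, per_class = hard_dice_metrics(pred_labels, hard_target, fg, n_classes)
    counts, percent = confusion(pred_labels, hard_target, fg, n_classes)
    return MetricReport(
        level=level,
        macro_soft_dice=macro_soft_dice(pred_dist, soft_target, fg, metric_cfg),
        l1_norm=l1_metric(pred_dist, soft_target, fg, normalizer=l1_normalizer),
        dice=dice,
        macro_dice=macro,
        per_class_dice={
            name: float(per_class[i]) for i, name in enumerate(class_names)
        },
        confusion_counts=counts,
        confusion_percent=percent,
        n_pixels_soft=int(fg.sum()),
        n_pixels_hard=int(hard_pop.sum()),
    )
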
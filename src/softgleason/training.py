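"""Model construction, training protocol, sliding-window inference, evaluation.

The segmentation model is a U-Net-style encoder–decoder emitting a per-pixel
softmax distribution over the classes of one ontology level.  Because the
final Gleason-pattern decision is obtained purely by summing the predicted
explanation probabilities upward through the ontology, the explanations act
as a concept bottleneck: every pattern call is traceable to interpretable
histological criteria.

Training follows a plateau schedule (learning rate × 1/3 after two
consecutive epochs without validation-loss improvement), AdamW with
decoupled weight decay, per-epoch checkpoint selection by validation loss,
and is fully seeded.  Inference tiles large images with 50%-overlapping
windows combined by Gaussian importance weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import metrics as M
from .fusion import HardLabelMap, SoftLabelMap
from .nn import AdamW, TinyUNet
from .ontology import IGNORE_LABEL, ExplanationOntology, Level
from .preprocessing import augment, central_patch, sample_training_patch

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    level: str = "explanation"
    loss_kind: str = "soft_dice"
    batch_size: int = 12
    epochs: int = 200
    lr: float = 5e-5
    plateau_factor: float = 1.0 / 3.0
    plateau_patience: int = 2
    weight_decay: float = 0.02
    betas: tuple[float, float] = (0.99, 0.9)
    conventional_betas: bool = False
    seed: int = 0
    encoder: dict = field(default_factory=lambda: {"name": "tiny", "base": 8, "depth": 2})
    patch_size: int = 512
    augment_policy: str = "light"
    #: epochs of cross-entropy warm-up before the configured loss takes over.
    #: Dice-family objectives optimized from random initialization are prone
    #: to irreversible per-class collapse (softmax gradients vanish once a
    #: class's predicted mass reaches zero); a brief CE warm-up avoids this.
    warmup_epochs: int = 0
    #: learning rate during warm-up (None = use ``lr``); cross-entropy
    #: tolerates a larger rate than the dice objective.
    warmup_lr: float | None = None

    def effective_betas(self) -> tuple[float, float]:
        return (0.9, 0.999) if self.conventional_betas else self.betas

    def __post_init__(self):
        for name in ("batch_size", "epochs", "lr", "plateau_factor", "weight_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PredictionMap:
    image_id: str
    level: Level
    dist: np.ndarray  # H×W×C, on-simplex
    provenance: dict = field(default_factory=dict)


@dataclass
class ImageItem:
    """One cohort image with its fused references, ready for the trainer."""

    image_id: str
    image: np.ndarray  # H×W×3
    soft: SoftLabelMap
    hard: HardLabelMap
    tissue: np.ndarray  # H×W bool


@dataclass
class TrainedRun:
    best_state: dict
    last_state: dict
    best_epoch: int
    train_losses: list[float]
    val_losses: list[float]
    lr_trace: list[float]
    config: TrainConfig


def desk_scale_config(loss_kind: str = "soft_dice", seed: int = 0,
                      epochs: int = 55) -> TrainConfig:
    """Training conditions for the desk-scale synthetic cohort (64×64 cores).

    A tiny randomly initialized encoder benefits from a larger learning rate
    than the full-scale protocol and from a cross-entropy warm-up before the
    dice objective; augmentation is off because the texture-coded synthetic
    classes need no photometric robustness.
    """
    return TrainConfig(
        level="explanation",
        loss_kind=loss_kind,
        batch_size=12,
        epochs=epochs,
        lr=1e-3,
        warmup_epochs=30,
        warmup_lr=3e-3,
        plateau_patience=10,
        conventional_betas=True,
        seed=seed,
        patch_size=64,
        augment_policy="identity",
        encoder={"name": "tiny", "base": 8, "depth": 2},
    )


def build_model(encoder_spec: Mapping, n_classes: int, seed: int = 0) -> TinyUNet:
    """Construct a segmentation model from an encoder spec.

    Currently one encoder family is provided ('tiny', a randomly initialized
    small U-Net encoder); the spec dict keeps the architecture configurable.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    name = encoder_spec.get("name", "tiny")
    if name != "tiny":
        raise ValueError(f"unknown encoder {name!r}")
    return TinyUNet(
        in_channels=3,
        n_classes=n_classes,
        base=int(encoder_spec.get("base", 8)),
        depth=int(encoder_spec.get("depth", 2)),
        seed=seed,
    )


def _to_float(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    return img / 255.0 if img.max() > 1.0 else img


def _batch_loss(model, images, targets, masks, loss_kind, epsilon=1e-6):
    """Forward + loss + gradient for one batch; returns loss or None if the
    batch has no evaluable pixel."""
    x = np.stack(images)
    probs = model.forward(x)
    tgt = np.stack(targets)
    msk = np.stack(masks)
    if loss_kind in ("hard_dice", "hard_ce"):
        msk = msk & (tgt != IGNORE_LABEL)
        if not msk.any():
            return None, None
        fn = M.hard_dice_loss if loss_kind == "hard_dice" else M.hard_cross_entropy
        loss, g = fn(probs, tgt, msk, grad=True) if loss_kind == "hard_ce" else fn(
            probs, tgt, msk, M.LossConfig(epsilon=epsilon), grad=True
        )
    else:
        if not msk.any():
            return None, None
        if loss_kind == "soft_dice":
            loss, g = M.soft_dice_loss(probs, tgt, msk, M.LossConfig(epsilon=epsilon), grad=True)
        elif loss_kind == "soft_ce":
            loss, g = M.soft_cross_entropy(probs, tgt, msk, grad=True)
        else:
            raise ValueError(f"unknown loss_kind {loss_kind!r}")
    return loss, g


def _val_loss(model, items: Sequence[ImageItem], cfg: TrainConfig) -> float:
    losses = []
    for item in items:
        p = central_patch(item.image, item.soft.dist, item.hard.labels, item.tissue,
                          size=cfg.patch_size)
        tgt = p.hard if cfg.loss_kind.startswith("hard") else p.soft
        loss, _ = _eval_only(model, p.image, tgt, p.tissue, cfg.loss_kind)
        if loss is not None:
            losses.append(loss)
    return float(np.mean(losses)) if losses else float("nan")


def _eval_only(model, image, target, mask, loss_kind):
    probs = model.forward(_to_float(image)[None])
    tgt = target[None]
    msk = np.asarray(mask, dtype=bool)[None]
    try:
        if loss_kind == "soft_dice":
            return M.soft_dice_loss(probs, tgt, msk), None
        if loss_kind == "soft_ce":
            return M.soft_cross_entropy(probs, tgt, msk), None
        if loss_kind == "hard_dice":
            return M.hard_dice_loss(probs, tgt, msk), None
        return M.hard_cross_entropy(probs, tgt, msk), None
    except ValueError:
        return None, None


def train(
    model: TinyUNet,
    train_items: Sequence[ImageItem],
    val_items: Sequence[ImageItem],
    cfg: TrainConfig,
) -> TrainedRun:
    """Run the training protocol and return the best-validation-loss checkpoint.

    Per epoch every training image contributes one randomly sampled,
    augmented patch; batches of ``cfg.batch_size`` are optimized with AdamW.
    The learning rate is multiplied by ``plateau_factor`` whenever the
    validation loss fails to improve for ``plateau_patience`` consecutive
    epochs.  A NaN loss aborts with diagnostics.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.params(), lr=cfg.lr, betas=cfg.effective_betas(),
                weight_decay=cfg.weight_decay)
    if cfg.warmup_epochs and cfg.warmup_lr is not None:
        opt.lr = cfg.warmup_lr
    train_losses: list[float] = []
    val_losses: list[float] = []
    lr_trace: list[float] = []
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    bad_epochs = 0
    for epoch in range(1, cfg.epochs + 1):
        if epoch == cfg.warmup_epochs + 1 and cfg.warmup_epochs:
            opt.lr = cfg.lr
        order = rng.permutation(len(train_items))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            images, targets, masks = [], [], []
            for idx in order[start : start + cfg.batch_size]:
                item = train_items[idx]
                p = sample_training_patch(item.image, item.soft.dist, item.hard.labels,
                                          item.tissue, rng, size=cfg.patch_size)
                p = augment(p, rng, policy=cfg.augment_policy)
                images.append(_to_float(p.image))
                targets.append(p.hard if cfg.loss_kind.startswith("hard") else p.soft)
                masks.append(p.tissue)
            kind = cfg.loss_kind
            if epoch <= cfg.warmup_epochs:
                kind = "hard_ce" if kind.startswith("hard") else "soft_ce"
            loss, g = _batch_loss(model, images, targets, masks, kind)
            if loss is None:
                continue
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch starting {start}; lr={opt.lr:g}"
                )
            model.zero_grad()
            model.backward(g)
            opt.step()
            epoch_losses.append(loss)
        train_losses.append(float(np.mean(epoch_losses)) if epoch_losses else float("nan"))
        vloss = _val_loss(model, val_items, cfg)
        val_losses.append(vloss)
        if vloss < best_val - 1e-12:
            best_val = vloss
            best_state = model.state_dict()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.plateau_patience and epoch > cfg.warmup_epochs:
                opt.lr *= cfg.plateau_factor
                bad_epochs = 0
                logger.info("epoch %d: plateau, lr -> %g", epoch, opt.lr)
        lr_trace.append(opt.lr)  # rate in force after this epoch's schedule step
    return TrainedRun(
        best_state=best_state,
        last_state=model.state_dict(),
        best_epoch=best_epoch,
        train_losses=train_losses,
        val_losses=val_losses,
        lr_trace=lr_trace,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _gaussian_window(window: int, sigma_scale: float) -> np.ndarray:
    center = (window - 1) / 2.0
    sigma = sigma_scale * window
    g = np.exp(-0.5 * ((np.arange(window) - center) / sigma) ** 2)
    w2 = np.outer(g, g)
    return np.maximum(w2, w2.max() * 1e-6)


def predict_sliding(
    model: TinyUNet,
    image: np.ndarray,
    level: Level | str,
    window: int = 512,
    overlap: float = 0.5,
    sigma_scale: float = 0.125,
    image_id: str = "",
) -> PredictionMap:
    """Tiled inference with Gaussian-weighted averaging of overlapping windows.

    Stride = window × (1 − overlap); edge tiles are handled by reflective
    padding of the image, and the combined distribution is renormalized to
    the simplex.  Images smaller than the window become a single padded tile.
    """
    img = _to_float(image)
    h, w = img.shape[:2]
    ph, pw = max(window - h, 0), max(window - w, 0)
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    hh, ww = img.shape[:2]
    stride = max(int(round(window * (1.0 - overlap))), 1)

    def positions(side):
        pos = list(range(0, side - window + 1, stride))
        if pos[-1] != side - window:
            pos.append(side - window)
        return pos

    weight = _gaussian_window(window, sigma_scale)
    acc = np.zeros((hh, ww, model.n_classes))
    wacc = np.zeros((hh, ww))
    for y0 in positions(hh):
        for x0 in positions(ww):
            tile = img[y0 : y0 + window, x0 : x0 + window]
            probs = model.forward(tile[None])[0]
            acc[y0 : y0 + window, x0 : x0 + window] += probs * weight[..., None]
            wacc[y0 : y0 + window, x0 : x0 + window] += weight
    dist = acc / wacc[..., None]
    dist = dist[:h, :w]
    dist = dist / dist.sum(axis=-1, keepdims=True)
    return PredictionMap(
        image_id=image_id,
        level=Level(level),
        dist=dist,
        provenance={"window": window, "overlap": overlap, "sigma_scale": sigma_scale},
    )


def ensemble_average(maps: Sequence[PredictionMap]) -> PredictionMap:
    """Arithmetic per-pixel mean of several prediction maps (stays on-simplex)."""
    if not maps:
        raise ValueError("empty ensemble")
    ref = maps[0]
    for m in maps[1:]:
        if m.dist.shape != ref.dist.shape or m.level is not ref.level:
            raise ValueError("ensemble members disagree in shape or level")
    dist = np.mean([m.dist for m in maps], axis=0)
    return PredictionMap(
        image_id=ref.image_id,
        level=ref.level,
        dist=dist,
        provenance={"ensemble_of": len(maps)},
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _hard_from_soft(soft: SoftLabelMap) -> HardLabelMap:
    """Majority-vote labels implied by a soft-label map (counts = dist × R)."""
    counts = np.rint(soft.dist * soft.n_raters).astype(np.int64)
    top = counts.max(axis=-1)
    unique = (counts == top[..., None]).sum(axis=-1) == 1
    labels = np.where(unique, counts.argmax(axis=-1), IGNORE_LABEL).astype(np.int64)
    return HardLabelMap(image_id=soft.image_id, level=soft.level, labels=labels)


def evaluate_run(
    maps: Mapping[str, PredictionMap],
    references: Mapping[str, tuple[SoftLabelMap, HardLabelMap]],
    ontology: ExplanationOntology,
    metric_cfg: M.MetricConfig = M.MetricConfig(),
) -> dict[str, M.MetricReport]:
    """Metric reports at the trained level and every level above it.

    Predictions and soft references are remapped upward by channel summing;
    the hard reference at each level is the majority vote implied by the
    remapped annotation distribution.  Hard metrics use only foreground
    pixels with an unambiguous majority; the foreground itself never changes
    with the level.
    """
    missing = sorted(set(references) - set(maps))
    if missing:
        raise ValueError(f"missing predictions for images: {missing}")
    native = next(iter(maps.values())).level
    levels = [lvl for lvl in (Level.SUB_EXPLANATION, Level.EXPLANATION, Level.PATTERN)
              if lvl.rank >= native.rank]
    reports: dict[str, M.MetricReport] = {}
    for lvl in levels:
        pooled_pred, pooled_tgt, pooled_hard = [], [], []
        l1_parts = []
        for image_id, (soft_ref, hard_ref) in references.items():
            pm = maps[image_id]
            pred = ontology.remap_soft(pm.dist, native, lvl)
            tgt_dist = ontology.remap_soft(soft_ref.dist, soft_ref.level, lvl)
            soft_lvl = SoftLabelMap(image_id, lvl, tgt_dist, soft_ref.foreground,
                                    soft_ref.n_raters)
            hard_lvl = _hard_from_soft(soft_lvl)
            fg = soft_ref.foreground
            pooled_pred.append(pred[fg])
            pooled_tgt.append(tgt_dist[fg])
            pooled_hard.append(hard_lvl.labels[fg])
            l1_parts.append(M.l1_metric(pred, tgt_dist, fg))
        pred_cat = np.concatenate(pooled_pred)
        tgt_cat = np.concatenate(pooled_tgt)
        hard_cat = np.concatenate(pooled_hard)
        ones = np.ones(len(pred_cat), dtype=bool)
        names = ontology.class_index(lvl)
        dice, macro, per_class = M.hard_dice_metrics(
            pred_cat.argmax(axis=-1), hard_cat, ones, len(names),
            policy=metric_cfg.zero_support_policy,
        )
        counts, percent = M.confusion(pred_cat.argmax(axis=-1), hard_cat, ones, len(names))
        reports[lvl.value] = M.MetricReport(
            level=lvl.value,
            macro_soft_dice=M.macro_soft_dice(pred_cat, tgt_cat, ones, metric_cfg),
            l1_norm=float(np.mean(l1_parts)),
            dice=dice,
            macro_dice=macro,
            per_class_dice={n: float(per_class[i]) for i, n in enumerate(names)},
            confusion_counts=counts,
            confusion_percent=percent,
            n_pixels_soft=len(pred_cat),
            n_pixels_hard=int((hard_cat != IGNORE_LABEL).sum()),
        )
    return reports


# ---------------------------------------------------------------------------
# visualization
# ---------------------------------------------------------------------------

def visualize(
    pmap: PredictionMap,
    image: np.ndarray,
    ontology: ExplanationOntology,
    tissue: np.ndarray,
    blend: float = 0.55,
) -> tuple[np.ndarray, list[tuple[str, str, tuple[int, int, int]]]]:
    """Overlay the argmax class in palette colors; background stays untouched.

    Returns an RGBA uint8 overlay (alpha 0 off tissue) and the legend of
    classes actually present, as (term_id, short_name, color) triples.
    """
    index = ontology.class_index(pmap.level)
    palette = ontology.palette(pmap.level)
    labels = pmap.dist.argmax(axis=-1)
    tissue = np.asarray(tissue, dtype=bool)
    base = _to_float(image) * 255.0
    rgba = np.zeros(labels.shape + (4,), dtype=np.uint8)
    colors = palette[labels]
    mixed = (1 - blend) * base + blend * colors
    rgba[..., :3] = np.where(tissue[..., None], mixed, base).astype(np.uint8)
    rgba[..., 3] = np.where(tissue, 255, 0).astype(np.uint8)
    present = np.unique(labels[tissue]) if tissue.any() else np.array([], dtype=int)
    legend = [
        (index[c], ontology.nodes[index[c]].short_name, tuple(int(v) for v in palette[c]))
        for c in present
    ]
    return rgba, legend
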
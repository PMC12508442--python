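"""Tissue masking, physical resampling, split optimization, patches, augmentation.

Core images sit on a bright slide background; the tissue foreground is found
by Otsu thresholding on the grayscale image (tissue = darker side) followed
by morphological closing and opening with a disk.  Images from scanners with
different pixel spacings are resampled bicubically to a common physical
resolution (default 1.392 µm/px); polygon vertices are scaled by the same
ratio instead of interpolating label rasters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skimage.color import rgb2gray, rgb2hsv, hsv2rgb
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, opening
from skimage.transform import resize, rescale

WORKING_SPACING = 1.392
"""Common physical pixel side length (µm/px) of the working resolution."""

PATCH_SIZE = 512


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# tissue mask
# ---------------------------------------------------------------------------

def tissue_mask(image: np.ndarray, disk_radius: int = 5) -> np.ndarray:
    """Boolean tissue-foreground mask (True = tissue).

    Grayscale → Otsu threshold → tissue is the darker side → binary closing
    then opening with a disk structuring element.  A constant image has no
    threshold: by convention it is all-background when bright (mean ≥ 0.5)
    and all-tissue when dark.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    gray = rgb2gray(img) if img.ndim == 3 else img.astype(np.float64)
    if gray.max() > 1.0:
        gray = gray / 255.0
    if np.ptp(gray) == 0:
        return np.full(gray.shape, gray.flat[0] < 0.5, dtype=bool)
    mask = gray < threshold_otsu(gray)
    selem = disk(disk_radius)
    return opening(closing(mask, selem), selem).astype(bool)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_image(
    image: np.ndarray, spacing_in: float, spacing_out: float = WORKING_SPACING
) -> np.ndarray:
    """Bicubic resampling to the working resolution.

    Output side = round-half-up(side_in × spacing_in / spacing_out).
    """
    if spacing_in <= 0 or spacing_out <= 0:
        raise ValueError("pixel spacings must be positive")
    ratio = spacing_in / spacing_out
    h, w = image.shape[:2]
    out_shape = (round_half_up(h * ratio), round_half_up(w * ratio))
    if out_shape == (h, w):
        return np.asarray(image, dtype=np.float64).copy()
    out = resize(
        np.asarray(image, dtype=np.float64),
        out_shape,
        order=3,
        anti_aliasing=ratio < 1.0,
        preserve_range=True,
    )
    return out


def resample_vertices(
    vertices: Sequence[tuple[float, float]],
    spacing_in: float,
    spacing_out: float = WORKING_SPACING,
) -> list[tuple[float, float]]:
    """Scale polygon vertices by spacing_in / spacing_out (exact, no interpolation)."""
    if spacing_in <= 0 or spacing_out <= 0:
        raise ValueError("pixel spacings must be positive")
    f = spacing_in / spacing_out
    return [(x * f, y * f) for x, y in vertices]


# ---------------------------------------------------------------------------
# split optimization
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    assignment: dict[str, str]  # image_id → train/val/test
    fractions: dict[str, float]
    objective: float


_SPLITS = ("train", "val", "test")


def _split_objective(hist: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """Mean pairwise L1 distance between the splits' normalized class-mass
    distributions, scaled to [0, 1] (0.5·Σ|a−b| per pair)."""
    dists = []
    for g in groups:
        mass = hist[g].sum(axis=0).astype(np.float64)
        total = mass.sum()
        dists.append(mass / total if total > 0 else np.full(hist.shape[1], 1.0 / hist.shape[1]))
    obj = 0.0
    n = 0
    for i in range(len(dists)):
        for j in range(i + 1, len(dists)):
            obj += 0.5 * np.abs(dists[i] - dists[j]).sum()
            n += 1
    return obj / n


def optimize_split(
    histograms: Mapping[str, np.ndarray],
    fractions: Sequence[float] = (0.70, 0.15, 0.15),
    n_restarts: int = 5,
    n_iter: int = 200,
    seed: int = 0,
) -> SplitAssignment:
    """Assign images to train/val/test minimizing class-distribution mismatch.

    The objective is the mean pairwise L1 distance between the three splits'
    normalized class-pixel distributions; optimization is random-restart
    hill climbing over pairwise swaps with fixed split sizes (largest
    remainder of the requested fractions).  Seeded and reproducible.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    ids = sorted(histograms)
    if len(ids) < 3:
        raise ValueError("need at least 3 images to form 3 splits")
    hist = np.stack([np.asarray(histograms[i], dtype=np.float64) for i in ids])
    n = len(ids)
    sizes = [int(math.floor(f * n)) for f in fractions]
    order = np.argsort([f * n - s for f, s in zip(fractions, sizes)])[::-1]
    for k in order[: n - sum(sizes)]:
        sizes[k] += 1

    rng = np.random.default_rng(seed)
    best_labels = None
    best_obj = np.inf
    for _ in range(max(n_restarts, 1)):
        perm = rng.permutation(n)
        labels = np.empty(n, dtype=np.int64)
        start = 0
        for s, size in enumerate(sizes):
            labels[perm[start : start + size]] = s
            start += size
        groups = [np.flatnonzero(labels == s) for s in range(3)]
        obj = _split_objective(hist, groups)
        for _ in range(n_iter):
            improved = False
            a, b = rng.integers(0, 3), rng.integers(0, 3)
            if a == b or not len(groups[a]) or not len(groups[b]):
                continue
            i = rng.choice(groups[a])
            j = rng.choice(groups[b])
            labels[i], labels[j] = labels[j], labels[i]
            cand_groups = [np.flatnonzero(labels == s) for s in range(3)]
            cand = _split_objective(hist, cand_groups)
            if cand < obj - 1e-15:
                obj, groups, improved = cand, cand_groups, True
            else:
                labels[i], labels[j] = labels[j], labels[i]
        if obj < best_obj:
            best_obj, best_labels = obj, labels.copy()
    assignment = {ids[i]: _SPLITS[best_labels[i]] for i in range(n)}
    achieved = {s: float(np.mean(best_labels == k)) for k, s in enumerate(_SPLITS)}
    return SplitAssignment(assignment=assignment, fractions=achieved, objective=float(best_obj))


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

@dataclass
class PatchSample:
    image: np.ndarray  # S×S×3 float
    soft: np.ndarray | None
    hard: np.ndarray | None
    tissue: np.ndarray
    y0: int
    x0: int
    min_foreground_met: bool = True


def _pad_to(arr: np.ndarray, size: int, value) -> np.ndarray:
    h, w = arr.shape[:2]
    ph, pw = max(size - h, 0), max(size - w, 0)
    if ph == 0 and pw == 0:
        return arr
    pads = [(ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)] + [(0, 0)] * (arr.ndim - 2)
    return np.pad(arr, pads, mode="constant", constant_values=value)


def _crop(arrs: dict, y0: int, x0: int, size: int) -> dict:
    return {
        k: (None if v is None else v[y0 : y0 + size, x0 : x0 + size])
        for k, v in arrs.items()
    }


def _prepare(image, soft, hard, tissue, size):
    from .ontology import IGNORE_LABEL

    image = _pad_to(np.asarray(image, dtype=np.float64), size, 255.0 if np.asarray(image).max() > 1 else 1.0)
    soft = None if soft is None else _pad_to(soft, size, 0.0)
    hard = None if hard is None else _pad_to(hard, size, IGNORE_LABEL)
    tissue = _pad_to(np.asarray(tissue, dtype=bool), size, False)
    return image, soft, hard, tissue


def sample_training_patch(
    image: np.ndarray,
    soft: np.ndarray | None,
    hard: np.ndarray | None,
    tissue: np.ndarray,
    rng: np.random.Generator,
    size: int = PATCH_SIZE,
    min_tissue: float = 0.05,
    max_tries: int = 50,
) -> PatchSample:
    """Uniform random patch, rejecting candidates with < ``min_tissue`` tissue.

    After ``max_tries`` rejections the best candidate seen is returned,
    flagged ``min_foreground_met=False``.  Images smaller than the patch are
    padded symmetrically with white/background.
    """
    image, soft, hard, tissue = _prepare(image, soft, hard, tissue, size)
    h, w = image.shape[:2]
    best = None
    best_frac = -1.0
    for _ in range(max_tries):
        y0 = int(rng.integers(0, h - size + 1))
        x0 = int(rng.integers(0, w - size + 1))
        frac = tissue[y0 : y0 + size, x0 : x0 + size].mean()
        if frac >= min_tissue:
            c = _crop({"image": image, "soft": soft, "hard": hard, "tissue": tissue}, y0, x0, size)
            return PatchSample(c["image"], c["soft"], c["hard"], c["tissue"], y0, x0, True)
        if frac > best_frac:
            best_frac, best = frac, (y0, x0)
    y0, x0 = best
    c = _crop({"image": image, "soft": soft, "hard": hard, "tissue": tissue}, y0, x0, size)
    return PatchSample(c["image"], c["soft"], c["hard"], c["tissue"], y0, x0, False)


def central_patch(
    image: np.ndarray,
    soft: np.ndarray | None,
    hard: np.ndarray | None,
    tissue: np.ndarray,
    size: int = PATCH_SIZE,
) -> PatchSample:
    """Patch centered on the image center (floor-based offset for odd remainders)."""
    image, soft, hard, tissue = _prepare(image, soft, hard, tissue, size)
    h, w = image.shape[:2]
    y0, x0 = (h - size) // 2, (w - size) // 2
    c = _crop({"image": image, "soft": soft, "hard": hard, "tissue": tissue}, y0, x0, size)
    return PatchSample(c["image"], c["soft"], c["hard"], c["tissue"], y0, x0, True)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(patch: PatchSample, rng: np.random.Generator, policy: str = "light") -> PatchSample:
    """Light geometric + photometric augmentation (no stain normalization).

    Geometric transforms (flips, 90° rotations, isotropic scaling in
    [0.8, 1.2]) are applied to image and labels in lockstep; photometric
    jitter (brightness/contrast ±0.2, hue/saturation ±0.1) touches the image
    only.  ``policy='identity'`` returns the patch unchanged.
    """
    if policy == "identity":
        return patch
    if policy != "light":
        raise ValueError(f"unknown augmentation policy {policy!r}")
    img = patch.image.astype(np.float64)
    scale01 = img.max() > 1.0
    if scale01:
        img = img / 255.0
    soft, hard, tissue = patch.soft, patch.hard, patch.tissue
    size = img.shape[0]

    def geom(f):
        nonlocal img, soft, hard, tissue
        img = f(img)
        soft = None if soft is None else f(soft)
        hard = None if hard is None else f(hard)
        tissue = f(tissue)

    if rng.random() < 0.5:
        geom(lambda a: a[:, ::-1].copy())
    if rng.random() < 0.5:
        geom(lambda a: a[::-1, :].copy())
    k = int(rng.integers(0, 4))
    if k:
        geom(lambda a: np.rot90(a, k, axes=(0, 1)).copy())

    factor = float(rng.uniform(0.8, 1.2))
    if abs(factor - 1.0) > 1e-3:
        img = _rescale_crop(img, factor, size, order=3)
        if soft is not None:
            soft = _rescale_crop(soft, factor, size, order=1)
            denom = np.maximum(soft.sum(axis=-1, keepdims=True), 1e-12)
            soft = soft / denom
        if hard is not None:
            hard = _rescale_crop(hard.astype(np.float64), factor, size, order=0).astype(np.int64)
        tissue = _rescale_crop(tissue.astype(np.float64), factor, size, order=0).astype(bool)

    # photometric (image only)
    img = img + rng.uniform(-0.2, 0.2)
    img = (img - 0.5) * (1.0 + rng.uniform(-0.2, 0.2)) + 0.5
    img = np.clip(img, 0.0, 1.0)
    hsv = rgb2hsv(img)
    hsv[..., 0] = (hsv[..., 0] + rng.uniform(-0.1, 0.1)) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * (1.0 + rng.uniform(-0.1, 0.1)), 0.0, 1.0)
    img = hsv2rgb(hsv)
    if scale01:
        img = img * 255.0
    return PatchSample(img, soft, hard, tissue, patch.y0, patch.x0, patch.min_foreground_met)


def _rescale_crop(arr: np.ndarray, factor: float, size: int, order: int) -> np.ndarray:
    scaled = rescale(
        arr,
        factor,
        order=order,
        channel_axis=-1 if arr.ndim == 3 else None,
        anti_aliasing=False,
        preserve_range=True,
    )
    h, w = scaled.shape[:2]
    if h < size or w < size:
        pads = [(0, max(size - h, 0)), (0, max(size - w, 0))] + [(0, 0)] * (arr.ndim - 2)
        scaled = np.pad(scaled, pads, mode="edge")
        h, w = scaled.shape[:2]
    y0, x0 = (h - size) // 2, (w - size) // 2
    return scaled[y0 : y0 + size, x0 : x0 + size]


def write_split_csv(split: SplitAssignment, path) -> None:
    """Persist a split assignment as a two-column CSV (image_id, split)."""
    import pandas as pd

    pd.DataFrame(
        sorted(split.assignment.items()), columns=["image_id", "split"]
    ).to_csv(path, index=False)


def read_split_csv(path) -> dict[str, str]:
    import pandas as pd

    df = pd.read_csv(path)
    return dict(zip(df["image_id"].astype(str), df["split"].astype(str)))
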
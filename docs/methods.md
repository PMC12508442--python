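# Methods

`softgleason` implements a soft-label, concept-bottleneck approach to
Gleason pattern segmentation on tissue-microarray (TMA) core images, plus
the surrounding machinery: a three-level explanation ontology, cleaning and
rasterization of multi-annotator polygon records, label fusion (soft
labels, majority vote, STAPLE), soft- and hard-label losses and metrics,
a training/inference protocol, interobserver agreement statistics, and a
synthetic multi-annotator cohort generator that makes every component
testable without external data.

## The model

Annotators outline regions with histological *explanations* (e.g. "poorly
formed glands") organized in a forest: each Gleason pattern (GP3/GP4/GP5)
owns a set of explanations, each explanation a set of finer
*sub-explanations*; a `benign` class exists at every level for unannotated
tissue. Rather than collapsing R disagreeing annotators into a single hard
label, the per-pixel *soft label* is the empirical vote distribution,

    y_c(p) = (# annotators labeling pixel p with a class mapping to c) / R,

so every channel value is a multiple of 1/R and disagreement is preserved
as probability mass. A fully convolutional encoder–decoder (U-Net
topology) predicts a per-pixel softmax distribution over the classes of one
ontology level. Gleason-pattern outputs are obtained purely by *summing*
predicted explanation probabilities upward through the ontology (the
concept bottleneck): every pattern decision is attributable to
interpretable concepts.

### Losses

With per-class sums over evaluated pixels, the soft Dice loss is

    d_c = (2 Σ_p p_c y_c + ε) / (Σ_p p_c + Σ_p y_c + ε),   L = 1 − mean_c d_c,

the direct extension of the class-averaged Dice loss to targets in [0, 1]
(ε = 1e-6, in numerator and denominator, config-exposed). Soft
cross-entropy is the mean of −Σ_c y_c log p_c. Hard variants use one-hot
majority-vote labels and exclude pixels without a unique majority
(ignore label 255).

### Metrics

* **Macro SoftDice** — the L1-based soft Dice semimetric,
  D_c = (‖p‖₁ + ‖y‖₁ − ‖p−y‖₁) / (2(α‖p‖₁ + β‖y‖₁)) with α = β = 0.5,
  class-averaged. It equals 1 iff p = y on the evaluated pixels and reduces
  to classical set-overlap Dice on one-hot inputs (both properties are
  asserted against a brute-force oracle in the tests). Classes with no
  support in either prediction or target are excluded from the mean by
  default (`zero_support_policy="exclude_class"`); exclusion avoids
  rewarding trivially absent classes.
* **L1-norm** — 1/(2NCP) Σ |p − y| over N images, C classes, and each
  image's P foreground pixels; per-image values are averaged over images
  (this matches the 1/(NP) structure when P varies). Note the 1/C factor
  bounds the value by 1/C, so fully disjoint one-hot distributions score
  0.5 at C = 2; a `/2NP` variant without the 1/C factor is available via
  `normalizer="2np"`.
* **Dice / Macro Dice / confusion matrices** — computed between the argmax
  prediction and the majority-vote label, restricted to foreground pixels
  with an unambiguous majority (the "hard population", always a subset of
  the soft one; both population sizes are reported).

## Pipeline conventions

* **Annotation cleaning.** Free-text explanations are matched
  case-insensitively after whitespace normalization via a synonym table.
  Polygons with empty explanation fields inherit the explanation of the
  nearest *later* polygon (annotators draw first, label afterwards);
  trailing unlabeled polygons have no donor and are dropped with a warning
  — a documented choice for an edge case the data-collection protocol does
  not define. Polygons carrying k explanations become k copies.
* **Rasterization.** Coordinates are 0-based, x rightward, y downward,
  with the origin at the center of the top-left pixel; a pixel belongs to a
  polygon iff its center lies inside (nonzero winding). Polygons are drawn
  grouped by Gleason-pattern context ascending, then by creation order;
  later polygons overwrite earlier ones, and uncovered pixels are benign.
  Masks are rasterized at the working resolution by scaling polygon
  vertices (exact) rather than interpolating label rasters.
* **Tissue masking.** Otsu threshold on grayscale (tissue = darker side),
  then binary closing and opening with a disk of radius 5 px at working
  resolution (config-exposed). Constant images have no threshold: bright →
  all background, dark → all tissue. Losses and metrics never read
  off-tissue pixels (tests NaN-poison them to enforce this).
* **Resampling.** Bicubic to 1.392 µm/px; output side =
  round-half-up(side × spacing_in/spacing_out). Round-half-up is pinned so
  shapes are byte-reproducible.
* **Split optimization.** Train/val/test sizes follow 70/15/15 by largest
  remainder; assignment minimizes the mean pairwise L1 distance between
  the splits' normalized class-pixel distributions by random-restart
  pairwise-swap hill climbing (seeded; objective non-increasing by
  construction). Class histograms default to the explanation level.
* **Patches and augmentation.** Random 512×512 training patches are
  accepted when ≥5% tissue (≤50 rejections, then the best candidate is
  returned, flagged); validation uses the central patch (floor-based
  offsets). "Light" augmentation: flips, 90° rotations, isotropic scaling
  in [0.8, 1.2], brightness/contrast jitter ±0.2, hue/saturation jitter
  ±0.1 — geometric transforms move labels in lockstep, photometric ones
  touch only the image; no stain normalization.
* **STAPLE.** Multi-category Warfield-style EM: posterior over the latent
  true class from per-rater confusion matrices and the empirical vote-
  frequency prior; confusion matrices re-estimated from posteriors;
  initialization 0.95 diagonal, tol 1e-6 on the largest confusion change,
  max 100 iterations, ties broken by class order. Classes no rater used
  are dropped from estimation and restored as never-selected. The EM runs
  on unique vote patterns weighted by their pixel counts, which makes it
  exact and fast.
* **Fleiss' kappa.** Image-level presence decisions (did the annotator use
  any class mapping to the label; benign excluded — nine decisions per
  image and annotator at the explanation level with the canonical
  ontology), κ = (P̄ − P̄ₑ)/(1 − P̄ₑ) with categories {used, not used},
  computed through statsmodels. Degenerate conventions: a label never used
  by anyone in a group is undefined (excluded from summaries, shrinking
  that label's group count); if every decision is identical and agreement
  is perfect, κ := 1. Confidence intervals are percentile bootstrap over
  images (B = 1000 by default, seeded); the interval is widened to contain
  the point estimate when resampling is one-sided. Pooled per-label kappas
  concatenate group subjects by default (`pool_labels=False` averages
  group kappas instead) — both are provided because the pooling rule is a
  genuine free choice.

## Training protocol

Batch size 12, 200 epochs, AdamW with decoupled weight decay λ = 0.02,
starting learning rate 5e-5, multiplied by 1/3 whenever the validation
loss fails to improve for two consecutive epochs; the checkpoint with the
lowest validation loss is kept (best + last retained by default). The
AdamW betas default to (β₁ = 0.99, β₂ = 0.9); these are unusual for AdamW,
so a `conventional_betas` flag switches to (0.9, 0.999) — neither mode is
asserted correct. Inference tiles images with 512 px windows at 50%
overlap combined by Gaussian importance weights (σ = 0.125 × window per
side) and renormalizes to the simplex; edge tiles use reflective padding.
Ensembling averages prediction maps arithmetically.

The network core is a compact numpy implementation (im2col convolutions,
manual backpropagation, AdamW) with a small configurable U-Net encoder;
it is exactly deterministic on CPU under a fixed seed. Pretrained encoders
are not required by any test.

**Warm-up.** Dice-family objectives optimized from random initialization
are prone to irreversible per-class collapse: once a class's predicted
mass reaches zero, its softmax gradients vanish and the class never
recovers (we observed exactly this on the synthetic cohorts). The trainer
therefore supports `warmup_epochs` of cross-entropy before the configured
loss takes over, optionally at a larger `warmup_lr`; checkpoint selection
always uses the configured loss.

### Desk-scale conditions

`desk_scale_config()` pins the scaled-down study conditions used by the
test suite and the acceptance script: 40 synthetic cores of 64×64 px,
three lesion classes spanning GP3/GP4/GP5 plus benign, three mildly noisy
annotators, a tiny U-Net (base width 8, depth 2), batch 12, learning rate
1e-3 with a 30-epoch cross-entropy warm-up at 3e-3, plateau patience 10,
conventional AdamW betas, 55 epochs, no augmentation (the texture-coded
synthetic classes need no photometric robustness). These problem sizes are
the package's choice of a configuration a single CPU core handles in about
a minute per training run.

## The synthetic cohort generator

Each synthetic core is a white slide background with a textured circular
tissue disk (45% of the side as radius); lesions are star-convex polygons
with stratified class assignment, packed without overlap inside the disk.
Class textures are procedurally distinct base colors with oriented
sinusoidal modulation — *not* histologically realistic; the cohorts test
the mechanism (fusion, losses, remapping, agreement), not histology, and
passing tests say nothing about stain variability, scanner domain shift,
or morphological ambiguity in real tissue. Simulated annotators re-annotate
ground-truth polygons with per-vertex Gaussian boundary jitter
(self-intersections repaired by convex-hull fallback), whole-polygon
drop-out, label confusion drawn from a row-stochastic matrix, and
occasional multi-label records. The "mild" default is a 0.95-diagonal
confusion, 0.75 px jitter, 3% drop, 5% multi-label — calibrated so a
perfect predictor of the ground truth still scores Macro SoftDice ≈ 0.87
on the fused 3-rater targets: boundary jitter must remain small relative
to the 4–8 px default lesion radii or it dominates every lesion's soft
mass. All randomness flows from the single cohort seed; regeneration is
byte-identical.

The shipped ontology file (`data/ontology_synthetic.yaml`) carries the
nine standard ISUP/WHO-aligned explanation classes under GP3/GP4/GP5; its
sub-explanation texts are this package's own paraphrases of the standard
histological criteria (hence "synthetic" in the filename) — term ids and
tree structure, not wording, are what the code relies on.

## Known limitations

* The numpy network core is single-threaded and meant for desk-scale
  experiments; training full-resolution cohorts requires swapping in a GPU
  framework behind the same module surfaces.
* Soft labels weight annotators uniformly; no reliability weighting.
* STAPLE here is the spatially homogeneous formulation (no MRF prior).
* The L1-norm's printed normalization bounds it by 1/C; comparisons across
  class counts should use the `/2NP` variant.
* Percentile bootstrap CIs are approximate for small image counts and for
  kappas near the degenerate boundary.
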
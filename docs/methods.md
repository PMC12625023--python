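# Methods

## Problem and model

Cervical cytology screening asks two coupled questions of each bright-field
Pap-smear image: *where* is abnormal epithelium (pixel-wise segmentation)
and *is this image abnormal at all* (binary classification, with the label
defined as positive iff the mask contains any foreground pixel). The
package implements a single multi-task network answering both in one
forward pass, on the premise that a shared representation benefits both
boundary delineation and global categorisation.

The network composes three ideas:

1. **Index-preserving encoder–decoder.** The encoder is a stack of blocks,
   each `[3×3 conv → batch norm → ReLU] × k` followed by non-overlapping
   2×2 max pooling that records the argmax position of every window (ties
   broken by first occurrence in row-major scan order, for determinism).
   The decoder mirrors the encoder: each stage first *unpools* — places
   each value at its recorded position, zeros elsewhere — then refines with
   conv–BN–ReLU layers; a final 1×1 convolution and sigmoid produce the
   per-pixel foreground probability. Unpooling with stored indices restores
   object boundaries more faithfully than learned upsampling at no
   parameter cost. An optional additive skip of the pre-pool feature maps
   exists behind `ModelConfig.use_additive_skips` (default off; the index
   mechanism is the operative skip path).
2. **Residual bottleneck bridge.** Between encoder and heads sit stride-1
   bottleneck stages (1×1 reduce → 3×3 → 1×1 expand, each conv followed by
   batch norm, ReLU after the shortcut addition; a 1×1 projection shortcut
   when channel counts differ). Default two stages; `bridge_stages`
   deepens the stack. The bridge output feeds *both* the decoder and the
   classifier, so the residual features are shared across tasks.
3. **Token transformer classifier.** The bridge map is cut into
   non-overlapping `patch_size × patch_size` patches (default 2 on the
   bridge lattice), linearly embedded, prepended with learnable class and
   distillation tokens, summed with learnable positional embeddings, and
   run through pre-norm transformer blocks (multi-head self-attention and
   a GELU MLP, each with a residual connection). An MLP head with dropout
   reads the class token; a second head reads the distillation token.

**Distillation without a teacher.** The distillation token is retained
architecturally but, with no teacher network available, it is supervised by
the same ground-truth label as the class token during training, and the two
logits are averaged before the sigmoid at inference (a hard-distillation
fallback). A teacher can be attached by replacing the supervision target of
the second head; nothing else changes.

**Ablation variants** (`build_model`): `segnet_mlp` (encoder only,
global-average-pool MLP classifier), `segnet_resnet_mlp` (adds the bridge),
`segnet_resnet_vit` (transformer head, class token only), `segresdeit`
(full model). All share the forward contract: mask probabilities of the
input's spatial size, one class probability per sample, both strictly
inside (0, 1).

## Objective

Per sample,

* segmentation: `L_seg = λ₁·L_BCE + λ₂·L_Dice`, where BCE is the mean
  pixel-wise binary cross-entropy (probabilities clamped to
  `[1e-7, 1−1e-7]` before logs) and the Dice loss is *soft* —
  `1 − (2Σpᵢgᵢ+ε)/(Σpᵢ+Σgᵢ+ε)` over the raw probability map, no
  thresholding — with smoothing `ε = 1e-6` so an empty prediction against an
  empty mask scores exactly 0.
* classification: `L_cls` is scalar BCE; with the distillation token active
  it is the *average* of the two token BCEs.
* total: `L_total = L_seg + α·L_cls`.

Defaults λ₁ = 0.6, λ₂ = 0.4, α = 1.0 — the optimum of a grid search over
λ₁ + λ₂ = 1 (grid {0.2/0.8, 0.4/0.6, 0.5/0.5, 0.6/0.4, 0.8/0.2}) and
α ∈ {0.5, 1.0, 1.5, 2.0}; `grid_search_weights` returns the argmax of a
caller-supplied validation scorer (default scorer in practice: validation
Dice), ties broken toward smaller α then larger λ₁.

Batched losses are means over per-sample losses (Dice is computed per
sample, then averaged). This makes the batch loss decomposable, which in
turn makes gradient accumulation over equal micro-batches *exactly*
equivalent to a full-batch step — verified to float precision in the tests.

## Data pipeline

* **Normalisation**: per-image, per-channel min–max to [0, 1]; a constant
  channel maps to zeros (degenerate-input convention). Per-image rather
  than dataset-global statistics, because the purpose is to equalise
  lighting/staining variation *between* samples.
* **Labels**: derived from the mask (any foreground ⇒ 1); masks binarised
  at > 0 on load; non-binary masks rejected.
* **Resizing**: bilinear for images, nearest-neighbour for masks (so masks
  stay binary); the label is re-derived after resizing since a one-pixel
  lesion can vanish under downscaling. Study-scale configuration: 2000×2000
  sources resized to 256×256 RGB.
* **Patch extraction**: origins advance by `stride` (0-based, (row, col),
  half-open windows); the last origin per axis is clamped to
  `dim − patch_size`, guaranteeing every pixel — in particular margin
  lesions — is covered. Patch size/stride are configuration (defaults
  128/64); the grid-coverage invariant is brute-force tested.
* **Augmentation** (train-time, per sample, seeded): horizontal/vertical
  flips, rotation ±15°, zoom 0.8–1.2×, brightness 0.8–1.2×. One affine warp
  applies rotation+zoom identically to image (bilinear) and mask
  (nearest-neighbour); out-of-bounds regions are zero-filled for both;
  brightness affects the image only and is clipped to [0, 1].
* **Split**: stratified on the label; the train set holds
  `round(fraction·n)` samples, allocated across classes by largest
  fractional remainder (each class split at the same fraction to within one
  sample). This rounding reproduces 1,782/445 from a 2,227-sample 80/20
  split. Classes with fewer than two members go to train with a warning.

## Synthetic fixtures

The generator emulates the geometry and contrast structure of bright-field
cytology at configurable size: a light pinkish background with
low-frequency texture, `background_cell_count` small round "normal cells"
(dark bluish nuclei inside faint halos), and — with probability
`lesion_probability` — 1..k compact "abnormal" regions drawn as radially
perturbed star-convex polygons (hence always connected) in a darker purple
with internal texture, plus clipped additive Gaussian pixel noise
(`noise_sd`, default 0.02). The mask is exactly the union of lesion
regions; generation is bit-reproducible from the seed.

Defaults are unit-test scale (64×64, lesion radii 7–13 px scaled with image
size, 12 background cells); fixtures carry learnable signal — a tiny full
model memorises 8 samples to training Dice > 0.95 and generalises to
held-out same-generator images at pixel Dice ≥ 0.9 (both exercised in the
acceptance tests). What passing these runs shows is that the architecture,
loss and trainer function correctly end to end; it does **not** show
clinical performance — real Pap smears have staining chemistry, overlapping
cell clusters and morphology the generator does not model.

## Training regimen

Adam (lr 1e-4, weight decay 1e-5 added to gradients), cosine-annealed
learning rate `floor + ½(lr₀−floor)(1+cos(πe/T))` with floor 0 and
`T = max_epochs`; micro-batch 8 with gradient accumulation over 2 steps
(effective batch 16); up to 30 epochs with early stopping on validation
loss (patience 10, strict-improvement rule, best weights restored);
dropout 0.3, active only in the decoder and the transformer head; He
initialisation for every conv/linear weight (tokens and positional
embeddings use N(0, 0.02), biases zero). One run seed drives weight
initialisation, shuffling, augmentation and dropout streams. "Validation
loss" for early stopping is the training objective (`L_total` with the run's
weights) evaluated in inference mode.

The implementation is a self-contained numpy reverse-mode autodiff engine
(float64; convolutions via im2col, batched matmul attention); analytic
gradients are verified against central finite differences and convolution
against an explicit sliding-window oracle in the test suite.

## Evaluation

All metrics derive from TP/TN/FP/FN: accuracy, precision, recall, F1, Dice
(= F1 on binary counts), IoU (Dice = 2·IoU/(1+IoU)); a zero denominator
yields 0 with a warning; report rounding is 4 decimals half-up. ROC sweeps
thresholds over unique scores with trapezoidal AUC and requires both
classes. `evaluate_model` reports pixel mode (confusion over all mask
pixels at threshold 0.5) and image mode (thresholded class probabilities) —
the published comparison tables are image-level counts, and the package
reproduces every such table row from its counts exactly; pixel-level
equivalents are always co-reported. AUC cannot be derived from confusion
counts alone (it needs per-sample scores), so published AUC figures are not
asserted anywhere.

## Numerical and design choices

* Probability clamp 1e-7 before logarithms; Dice ε = 1e-6.
* Pooling tie-break: first occurrence, row-major — makes unpooling and its
  tests deterministic. Pool∘unpool∘pool = pool holds on non-negative maps
  (the post-ReLU domain in which pooling operates here).
* Thresholds 0.5 for both mask and class decisions.
* Input is 3-channel 256×256 at study scale; test configurations shrink
  spatial size and channel widths, never the structure.
* The bridge is a compact bottleneck stack rather than a full 50-layer
  network: at a 32×32 bridge lattice the extra depth adds cost without a
  specified benefit, and the with/without-bridge ablation contrast is
  preserved; `bridge_stages` deepens it when wanted.
* Scaled-down problem sizes in tests and the acceptance script (64×64
  images, 8–40 samples, ≤200 epochs, tiny channel widths) are the package's
  chosen CPU-scale study conditions; the parameter count of any built model
  is reported by `num_parameters()`, and no particular total is targeted.

## Known limitations

* No pretrained weights, no teacher model, no multi-class masks, no
  whole-slide pyramids.
* The numpy engine is single-threaded per op and float64 — correct and
  CPU-testable, not performance-competitive with GPU frameworks.
* Synthetic fixtures validate mechanism, not clinical accuracy.
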
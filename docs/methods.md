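# Methods

## Problem and model

The enhanced arterial light reflex (EALR) is an early fundus sign of
systemic atherosclerosis: the central light reflex of retinal
arterioles widens and brightens toward a metallic copper tone.  The
package treats EALR screening as binary classification of color fundus
photographs and implements a dual-branch cross-scale vision transformer
with an attention-based multiple-instance-learning (MIL) head.

**Token sequences.** Each branch resizes the preprocessed image to its
input size s, cuts non-overlapping p×p patches, projects each linearly
to the branch width q, prepends a learned classification token, and
adds a learned position embedding to all n+1 tokens (once, before the
first cross-scale repetition).  Encoder blocks are pre-norm ViT blocks:
`y = x + MHSA(LN(x))`, `out = y + FFN(LN(y))`, with an FFN expansion of
4 and GELU.  Layer normalization is
`LN(x) = (x − E x)/√(Var x + ε)·γ + β` with ε = 1e-6, statistics over
the channel axis.

**Cross-scale fusion (MHCA).** After each repetition's per-branch
encoder stacks, each branch's cls token is layer-normalized, projected
to the other branch's width, concatenated in front of the other
branch's patch tokens, and used as the *only* attention query over that
sequence; the updated token is added residually to the projected cls
and back-projected (LN then linear) to its own width.  The attention
map therefore has exactly one row per head — fusion cost is linear in
the other branch's token count — and patch tokens pass through the
fusion unchanged.  Per-head scaling is the standard 1/√(q/t); the
fusion is a single MHCA layer per repetition.

**MIL head.** Per branch, the final patch tokens are the instances of
a bag (the image).  Each instance is embedded as
`h_i = ReLU(LN(W z_i))` (m-dimensional), scored by a gated two-layer
attention `e_i = w₂ᵀ ReLU(LN(W₁ h_i))`, softmax over the bag gives
weights α, and the bag representation `A = Σ α_i h_i` is classified by
a single linear layer to 2 scores.  The per-branch score pairs are
concatenated coarse-first into the 4-vector bag output.  Aggregation
is permutation-invariant in the instances (up to float summation
order) and α lies on the simplex.

**Loss and fusion.** Each branch contributes an MLP estimate (LN +
linear + softmax on the cls token) and a MIL estimate (softmax of the
bag scores).  Training minimizes, per branch,
`−η Σ_j y_j log y_j^mlp − (1−η) Σ_j y_j log y_j^mil`, summed over the
two branches and averaged over the batch; probabilities are floored at
1e-12 inside the log, and a zero-weight term (η = 0 or 1) is dropped
from the graph entirely so the unused head receives exactly no
gradient.  Inference fuses
`y = normalize(η·mean_b y^mlp_b + (1−η)·mean_b y^mil_b)`; class 1 is
EALR.  The inference-time combination rule is this package's own
choice, mirroring the loss weighting.  η defaults to 0.5.

## Reference configuration and open choices

Fine branch: patch 12, input 240 px, width 96, depth 1, 3 heads.
Coarse branch: patch 16, input 224 px, width 192, depth 4, 6 heads.
T = 3 repetitions; both branch inputs are resizes of the same
preprocessed image.  Where the architecture description leaves a knob
open, the package fixes it as follows and exposes it in the specs:

- input sizes 224/240 (224 is not divisible by 12; the dual-resize
  convention of cross-attention multi-scale ViTs is used);
- head width 32 (so 3/6 heads), FFN expansion 4 (vanilla ViT default);
- cross-branch projections are single linear layers with LN before
  projection, bias on;
- MIL dims m = 128, l = 64 (below the branch widths, config-overridable);
  the bag classifier consumes the m-dimensional aggregate;
- the final classification uses the per-branch layer-normalized cls;
- initialization: truncated normal (std 0.02, ±2 std) for weights,
  zeros for biases.

This configuration has ≈6.8 M trainable parameters.

## Preprocessing

1. **Border removal**: minimal crop containing every pixel whose
   maximum channel intensity exceeds the background threshold
   (default 10 of 255, tolerant of sensor noise); an image entirely
   below threshold raises an unusable-image error, the programmatic
   stand-in for manual quality screening (a hook, not a quality model).
2. **CLAHE** on the luma channel of a YCbCr decomposition (color
   handling is this package's choice), OpenCV convention: per-tile
   histograms clipped at `clip_limit` (default 7) times the mean bin
   count, excess redistributed uniformly (residual into the lowest
   bins), per-tile CDF lookup tables blended bilinearly between tile
   centers with clamping at borders; 6×6 tiles by default.
3. **Gaussian background subtraction**
   `x̃ = clip(κ·(x − G_σ∗x) + δ, 0, 255)` per channel, κ = 4, δ = 128,
   σ = (post-crop width)/30 — scale-adaptive blur matching common
   fundus practice.  `G_σ∗x` is the Gaussian-blurred image (weighted
   neighborhood average), reflective boundaries, so the operator
   commutes with flips.
4. **Balancing augmentation** of the minority (abnormal) class only:
   transformed copies (rotation ±30°, flips, scale 0.9–1.1, shifts
   ±10%, shear ±10°, fill) until class counts are equal; ranges are
   defaults, all overridable; deterministic under a seed.  Pipeline
   order: borders → CLAHE → Gaussian → augmentation.

## Synthetic data generator

The generator emulates the EALR phenotype only to the extent needed to
exercise the method: a circular orange-tinted disc (centered within
±2 px, radius 0.42–0.46 of the image) with radial shading and mild
sensor noise on black background; 6–10 dark vessels as random
quadratic Bezier curves radiating outward, width 2–4.5 px; in class-1
images a bright central stripe (half the vessel width) along a random
arterial subset (two-thirds of the vessels — sclerosis affects most
arterioles), rendered as a blend toward a metallic tone
(165, 110, 60) + `reflex_brightness`, i.e. ≈(255, 200, 150) at the
default 90 — a widened near-white reflex whose green channel clears
the disc's green ceiling, as in the clinical description of the
silver/copper-wire sheen.  Both classes receive a per-image global
brightness jitter of ±18, roughly ten times the mean-intensity shift
the stripes cause, so global brightness alone cannot separate the
classes; vessel geometry is drawn identically for both classes of a
given sample seed, so paired images differ only by the stripes.

What the generator does *not* model: optic disc and macula, real vessel
branching topology, arteriovenous distinction beyond the stripe flag,
camera vignetting/exposure artifacts, severity grades.  Passing the
learning-sanity check therefore shows the pipeline can learn a
localized brightness-on-vessel phenotype end to end; it says nothing
about clinical performance on real fundus photographs.

## Training protocol and problem sizes

Optimizer defaults follow the reference protocol: Adam, initial
learning rate 1e-3 with cosine decay to zero (the package's choice of
schedule), weight decay 5e-4 (classic L2-coupled), β₁ = 0.9, batch 32,
200 epochs, stratified five-fold cross-validation with balancing
applied to training folds only (train/test path disjointness is
asserted every fold).

Desk-scale runs use a reduced model (96-px inputs, widths 32/64, heads
1/2, depths 1/2, T = 1, MIL m = 32, l = 16, ≈215 k parameters), 100
generated images per class, an 80/20 stratified split, 50 epochs, and
deterministic 4× dihedral expansion (identity, h-flip, v-flip, 180°
rotation) of the training split only: a transformer trained from
scratch on 160 images underfits badly without it, and the reflex
phenotype is orientation-free.  These sizes are the package's chosen
demonstration scale; full-scale training (large fundus corpora,
GPU-class budgets) is out of scope.

## Evaluation

Per class c (one-vs-rest): PRE = TP/(TP+FP), SEN = TP/(TP+FN),
SPE = TN/(TN+FP); ACC is global; F1 is reported as the harmonic mean
of PRE and SEN (headline) and additionally as their arithmetic mean,
since both conventions appear in the screening literature; macro rows
are unweighted means over the two classes; zero-denominator ratios are
reported as NaN with a warning, never silently 0.  ROC curves sweep
the unique fused positive-class probabilities; AUC is the trapezoid
integral (equal to the pairwise-ranking probability with ties counted
half).  The confusion matrix thresholds at argmax of the fused
probability.  Cross-validated results are reported as mean ± standard
deviation across folds.

## Interpretability

Grad-CAM on the token grid: the hook point is the chosen branch's
final layer-normalized token sequence — the features the
classification heads actually consume (up to the final LN this equals
the last encoder-block output, since fusion passes patch tokens
through; hooking before the LN was tried and localized measurably
worse).  The target score is the log fused probability of the target
class (for two classes, every monotone variant — logit, class
contrast — yields the same map up to positive scaling); channel
weights are the grid-average of its gradient; the map is the ReLU of
the weighted channel sum, max-normalized (all-zero maps stay zero),
bilinearly upsampled, cls token excluded.  Maps are invariant to batch
composition.  Both branches are exposed; the fine branch has the finer
grid.  On the shallow desk-scale model the maps are directionally
informative but diffuse: for images whose reflex stripes are confined
to one quadrant, the map reliably puts more mass in that quadrant than
in the opposite one, but its global centroid does not always fall
inside the quadrant — attention mixing spreads attribution, a known
behavior of gradient-based maps on small transformers.

## Numerical choices and limitations

- All computation is float64 on a tape-based reverse-mode autodiff over
  numpy; gradients accumulate on intermediate nodes (needed for
  Grad-CAM).  Softmax is the numerically-stable fused form; GELU is
  exact (erf).
- Determinism: every stochastic component (init, shuffling, generator,
  augmentation) is driven by an explicit numpy Generator seed; repeated
  runs are bit-identical on a fixed platform.
- Degenerate inputs: empty bags, single-class manifests, images
  entirely below the background threshold, non-finite losses and
  invalid probability vectors all raise descriptive errors.
- The CLAHE residual-redistribution tie-break (excess remainder into
  the lowest bins) is a documented convention; implementations differ
  in this detail.
- Checkpoints store weights plus the full spec (npz with a JSON
  sidecar), so a checkpoint is self-describing.
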
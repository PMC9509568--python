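# Methods

This note documents the models and procedures implemented in `leafclar`, the
choices made where the design was genuinely open, and what the synthetic
study does and does not demonstrate.

## Retinex enhancement (AMSR)

An observed image is modelled as `S(x,y) = R(x,y) · L(x,y)`: a smooth
illumination field `L` multiplying an object-intrinsic reflectance `R`.
Working per colour channel in the log domain,

```
log R = log S − log L,      L ≈ G_σ ∗ S,
```

with `G_σ` a unit-sum Gaussian surround.  Three surrounds are used
(σ = 15, 80, 250 pixels by default — small preserves edges, large evens
global illumination; the classic multi-scale triple, configurable).  The
adaptive variant weights the three scales *per pixel* with a
frequency-comparison coefficient

```
A(x,y) = a1 · arccot(σ_local(x,y)) + a2,   clamped to [0, 1],
```

where `σ_local` is the population standard deviation of the 8-bit channel
over a 7×7 window.  `A` is 1 in perfectly flat regions and decreases with
local contrast; per-pixel scale weights blend an edge profile (0.5, 0.3, 0.2)
with a homogeneous profile (0.2, 0.3, 0.5) and therefore always sum to one.
Defaults `a1 = 2/π`, `a2 = 0` map `A` onto (0, 1].

The merged log reflectance is taken to display range by a per-channel
1st–99th percentile stretch.  Chromaticity is then restored: the enhanced
luminance is multiplied by the original channel ratios `I_j / I` (with `I`
the per-pixel channel mean) scaled by a brightness factor λ (default 1).
Pixels with `I ≤ 1/255` keep the enhanced luminance unmodified; pixels whose
compensated channels exceed 1 are rescaled by their maximum rather than
clipped channel-wise, which preserves hue exactly.

Numerical choices: reflect padding everywhere (zero padding darkens
borders); `ε = 1/255` inside both logarithms; frequency-domain convolution
for σ ≥ 8 and direct convolution below (the two agree to < 1e-6, which the
suite checks against a brute-force spatial oracle); surround radius
`min(⌈3σ⌉, min(H,W) − 1)` with renormalized taps, so very large scales act
as a near-global mean on small images.

## The classification network

Two feature roads feed one classifier.

**Main road.**  A ResNet50-layout backbone: 7×7/2 stem, 3×3/2 max-pool,
bottleneck stages of 3/4/6/3 blocks with widths 256/512/1024/2048 scaled by
a `width_multiplier`.  Every ReLU is replaced by ELU
(`f(x) = x` for `x > 0`, `α(eˣ − 1)` otherwise, α = 1), which keeps a
nonzero gradient `α eˣ` on negative inputs.  A residual attention module
(RAM) follows each stage: a trunk of two 3×3 convolutions and an hourglass
mask branch (3×3 conv + 2×2 max-pool per resolution down to the network's
7×7 minimum, then bilinear ×2 upsampling with additive skips, a 1×1 conv and
a sigmoid) combined as `H = (1 + M) · T`, so attention re-weights but never
attenuates.  With a zeroed mask head the block reduces to 1.5 × trunk, which
the suite uses to verify the wiring.

**Detail road.**  A feature-pyramid fusion path adapted from detection-style
pyramid augmentation to whole-image classification (no region proposals
exist here, so "ROI features" are the whole-image maps).  1×1 lateral
projections to a common width (256 × width_multiplier) give M1..M4.
Residual feature enhancement pools M4 at target sizes ⌈0.1s⌉, ⌈0.2s⌉,
⌈0.3s⌉, upsamples back and adds the contexts with weights 0.1/0.2/0.3
residually (a constant input `c` becomes exactly `1.6c`, a suite check).
A top-down pathway (`t_k = m_k + up(t_{k+1})`, 3×3 smoothing) produces
P1..P4; the levels are adaptively average-pooled to 7×7 and fused by
adaptive spatial fusion — per-level spatial weight maps from a small conv
head, softmax-normalized across levels per pixel.

**Head and loss.**  The globally pooled B4 descriptor is concatenated with
the pooled fused detail descriptor, batch-normalized, and mapped by one
fully connected layer to K = 6 logits.  Normalizing the descriptor before
the classifier is this package's choice (the head's internals are otherwise
unconstrained): without it the deep multiplicative paths (attention gating,
unbounded ELU) inflate the descriptor scale, the logits leave the
label-smoothing loss's natural range, and optimization oscillates; with it
the loss descends monotonically.  A shared auxiliary head (batch norm +
linear, one set of parameters applied to each pooled M_k) supplies
consistency supervision.  The training loss is

```
loss = sce(main) + λ_aux · mean_k sce(aux_k)
```

where `sce` is cross entropy against label-smoothed targets
(`1 − ε` on the true class, `ε/(K−1)` elsewhere; ε = 0.1, λ_aux = 0.25 by
default — the balance weight is a free parameter here).  Localization terms
enter the loss formula with a β factor but default to zero: a
classification task has no box targets.  `λ_aux = 0` recovers plain
label-smoothed cross entropy bit for bit.  Note the closed form of the
optimal smoothed-target logits (true-class logit `log((K−1)(1−ε)/ε) + α`
over a free baseline α) is an analytic statement only; nothing in the code
computes it.

**Tensor engine.**  No deep-learning framework is used: the package carries
a small reverse-mode autodiff engine over NumPy float32 arrays
(`leafclar.nn`) with im2col/GEMM convolution, fused batch norm, max-pool,
separable bilinear/adaptive-pool operators and Adam.  Every backward pass is
verified against central finite differences (tolerances reflect float32
forward noise, ~1–2% relative).  Large im2col column matrices are rebuilt
during the backward pass instead of cached, keeping peak memory modest.

## Data bookkeeping

Manifests are CSV tables (`path,label,condition,split,provenance`) over a
closed six-label set.  Amplification replaces each source record with one
augmented record per enabled family (rotate/flip/random-crop/brightness), so
the four-family mode multiplies counts by exactly 4 (2,525 → 10,100;
1,860 → 7,440).  Splits are stratified per class with largest-remainder
rounding, making 10,100 at 6:2:2 exactly 6,060/2,020/2,020.  The
amplify-then-split order reproduces the study's counts; because augmented
twins of one source can land in different splits, a source-grouped
(leakage-safe) split is the right choice when measuring generalization on
real data — the desk experiment sidesteps the issue by training on
unamplified synthetic images.  Augmentation parameters (rotation sampled
from {90°, 180°, 270°}, flip axis, crop fraction 0.8–1.0, brightness factor
0.7–1.3) are unspecified upstream and are seeded defaults here.

## Synthetic study and its limits

The generator paints a mottled green leaf background and overlays
class-specific lesions: none (healthy), large diffuse yellowing (greening
disease), many small dark scar-like particles vs fewer larger brown spots (a
deliberately similar pair), many small yellow-white pustules vs fewer larger
ringed ones (a second similar pair).  Acquisition conditions follow the
study's distribution (27.2% uniform sun, 20.8% cloudy, 30.0% fog, 22.1%
uneven illumination): cloudy multiplies luminance by 0.3–0.5, fog adds a
smooth white veil, uneven illumination applies a linear ramp.  A linear
discriminant on mean-channel + lesion features of enhanced images separates
the six classes at ≥ 80% — the classes are distinguishable but not trivial,
and the similar pairs carry most of the confusion.

Desk-scale study conditions: 120 images (20 per class), AMSR preprocessing,
6:2:2 split, width-0.25 network, batch 16, Adam (first moment 0.9, second
0.999, the study's "momentum 0.9" read as the first-moment coefficient),
weight decay 1e-4, at most 30 epochs with early stopping once a full
evaluation pass confirms ≥ 95% training accuracy and the epoch-mean loss has
halved from its pre-update initial value.  Two deliberate departures from
the full-scale training configuration: batch 16 rather than 32 keeps a
reasonable optimizer-step count on 72 training images at identical
arithmetic cost, and the learning rate steps down (0.001 for epochs 1–10,
0.0005 to 20, 0.00025 after) instead of following the default two-phase
schedule (0.001 for epochs 1–20, then 0.005, retained in `TrainConfig`):
the late increase, tolerable when each epoch has 190 steps, collapses the
fit when an epoch is 5 steps, and a flat rate leaves gradient-noise
oscillation just below the accuracy target that the decay lets the fit
escape.

What passing desk-scale tests shows: the full pipeline — generation,
enhancement, manifest handling, training, evaluation — is wired correctly,
optimizes stably, and has the capacity to fit its training distribution,
with noise robustness and enhancement effects measurable in the expected
directions.  What it does not show: real-photograph accuracy.  The cartoons
have no occlusion, no background clutter, no camera noise, and far less
intra-class variability than orchard photographs; accuracy numbers from the
synthetic study say nothing quantitative about performance on real data.

## Evaluation

Confusion matrices have actual classes in rows and predictions in columns;
ties in the probability vector break toward the lower class index.
Per-class precision `TP/(TP+FP)`, recall `TP/(TP+FN)` and
`F1 = 2PR/(P+R)` are macro-averaged (unweighted over the six classes).
Classes with no predicted (or no actual) samples contribute 0 with a
runtime warning.  Noise robustness adds seeded Gaussian noise (std on the
[0,1] scale) or white salt impulses to the test images only; a level-0
entry skips the noise step and therefore equals the clean accuracy exactly.
The ±AMSR ablation trains each variant on the same seeded dataset and
reports the comparison without asserting a direction.

## Known limitations

- CPU-only: full-width, full-dataset training (the study's 200-epoch
  configuration) is out of reach; all defaults are desk-scale.
- The engine implements exactly the operations this architecture needs; it
  is not a general framework (no GPU, no mixed precision, no graph-level
  optimization).
- Checkpoints store raw arrays plus the producing configuration and refuse
  to load into a mismatched architecture, but are not portable across
  package versions.
- The mask branch is built for its stage's fixed resolution; inputs of other
  sizes are rejected rather than handled dynamically.
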
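# Methods

## The idea

Convolutional networks almost always use one activation function — usually
ReLU — identically in every layer. This package implements an alternative
design procedure: keep the architecture and all trained weights, but
replace each activation layer independently with a function drawn at
random from a pool of ReLU variants. Because the learnable variants in the
pool start out as exact copies of ReLU, the surgery does not change what
the network computes at the moment of replacement; diversity emerges
during subsequent fine-tuning, as each layer's activation adapts along its
own learnable parameters. Repeating the draw N times yields N structurally
diverse networks that are natural ensemble members; their post-softmax
scores are summed and the argmax of the sum is the ensemble decision.

## The activation catalogue

All ten functions are rectifier-shaped: identity (or near-identity) for
positive inputs, with differently parameterized negative branches and,
for the basis families, localized bumps added on top. With per-element
input `x`:

* **ReLU** `f(x) = max(x, 0)`.
* **Leaky ReLU** `f(x) = x` for `x ≥ 0`, `a·x` otherwise. The slope
  defaults to `a = 0.01`, exposed as `leaky_a` (some presentations of this
  catalogue use 0.1; the knob covers both).
* **ELU** `f(x) = x` for `x ≥ 0`, `a·(exp(x) − 1)` otherwise, `a = 1`.
* **PReLU** Leaky ReLU whose slope `a_c` is learned, one per input
  channel; initialized to 0 (= ReLU).
* **SReLU** piecewise linear with four learnable knots `(a_l, t_l, a_r,
  t_r)`: slope `a_l` below `t_l`, identity between the thresholds, slope
  `a_r` above `t_r`. Initialized to `(0, 0, 1, maxInput)`, i.e. exactly
  ReLU. The knots are shared per layer (the function is defined by four
  scalars; per-channel knots would multiply parameters without a stated
  benefit).
* **APLU** `f(x) = ReLU(x) + Σ_c a_c · max(0, −x + b_c)` with `N = 3`
  hinges per channel. Slopes `a_c` start at 0; hinge positions `b_c` are
  drawn once, uniformly on `[0, maxInput]`, from the layer's seeded RNG,
  and are learnable. An L2 penalty `0.001 · Σ a_c²` is added to the
  training loss (never to plain forward evaluation). The hinge is written
  with `max` (not `min`): only that form has the gradient branches active
  for `x < b_c`, matching the adaptive-piecewise-linear construction.
* **MeLU / wMeLU** `f(x) = PReLU_{c₀}(x) + Σ_j c_j · φ_{α_j,λ_j}(x)` where
  `φ_{a,λ}(x) = max(λ·M − |x − a·M|, 0)` is a triangular "Mexican hat"
  bump (`M = maxInput`), nonnegative, compactly supported on
  `[(a−λ)M, (a+λ)M]`, peak `λ·M` at `a·M`. MeLU uses `k = 4`
  (`α = [2,1,3]`, `λ = [2,1,1]`): the first bump spans `[0, 4M]` peaking
  at `2M`, the next two bisect that interval. wMeLU (`k = 8`) adds four
  half-width bumps. All `c_j` start at 0, so both reduce exactly to ReLU.
* **GaLU / sGaLU** same construction over a bump/dip pair
  `φg_{a,λ}(x) = max(λM − |x − aM|, 0) + min(|x − aM − 2λM| − λM, 0)`,
  a piecewise-linear analogue of a Gaussian-derivative wavelet. GaLU:
  `k = 4`, `α = [1, 0.5, 2.5]`, `λ = [1, 0.5, 0.5]`; sGaLU: `k = 2`,
  `α = [1]`, `λ = [1]`.

`maxInput` (1 or 255) rescales the basis geometry to the input intensity
range; every basis-family output is positively homogeneous:
`f(s·x; maxInput = s·M) = s · f(x; maxInput = M)`.

### Gradients

Every function carries hand-derived gradients for the input and all
learnable parameters, verified against central finite differences
(float64, step 1e-6, relative tolerance 1e-4) at off-breakpoint points.
Two derivative conventions are fixed once: at a breakpoint the
`x ≥ threshold` branch applies, and the SReLU threshold gradients are the
true derivatives of the piecewise form — `∂f/∂t_l = 1 − a_l` on the left
branch and `∂f/∂t_r = 1 − a_r` on the right (several published summaries
drop the `1`, which fails any finite-difference check). Likewise APLU's
`∂f/∂b_c = +a_c` for `x < b_c`.

## Surgery and seeding

`ModelGraph` is an explicit layer stack; activation layers are
first-class, enumerable slots. `replace_all` swaps every slot for one
chosen spec; `stochastic_replacement` draws a spec per slot i.i.d.
uniformly (with replacement) from the pool — the draw law is the simplest
consistent with "drawn from a set" absent stated weights. The default pool
is the nine non-ReLU functions at one `maxInput`. A master seed spawns one
`SeedSequence` child per slot; the child seeds both the draw and any
randomness inside the new activation (APLU's hinge positions), making the
whole assignment a pure function of (model, pool, seed). Non-activation
weights are never touched (asserted by hashing all non-activation
parameter blobs before and after).

## Fusion

Classification members are fused by summing post-softmax score vectors
(never logits) and taking the argmax; ties resolve to the lowest class
index, deterministically. Segmentation members are fused per pixel the
same way; on hard one-hot masks this is exactly a per-pixel majority
vote, and a `hard=True` mode forces the vote interpretation for soft
scores too. Recipe helpers compose the standard ensembles: `FusAct` (one
member per catalogue function), `FusRan` (N stochastic members, optionally
at both `maxInput` values), `FusAR` (their concatenation).

## Training

The trainer is minibatch SGD with momentum 0.9 on a cross-entropy loss
(pixel-wise for segmentation, optionally weighted by inverse class
frequency computed on the training set), plus the APLU penalty where an
APLU layer is present. The fine-tuning defaults are batch size 32,
learning rate 1e-4 (classification) / 1e-3 (segmentation), 30 / 50 max
epochs, augmentation on (for segmentation, the first 30 epochs).
Augmentation is a random reflection on each axis (probability 1/2 each)
followed by two independent axis rescales with factors uniform on [1, 2],
bilinear, center-cropped back to the input shape; masks ride along with
identical draws and nearest-neighbor interpolation. The optimizer, loss
and crop convention are this package's choices where the recipe is
conventionally left unstated. Per-tensor gradient clipping (L2 cap 5.0,
configurable) keeps the learnable-activation parameters stable: their
gradients aggregate over every spatial position of a channel and can
otherwise overwhelm SGD at the step sizes the small networks need.

The whole stack — layers, backward passes, SGD — is implemented in numpy
with explicit analytic gradients. That is deliberate: the learnable
activations are the point of the package, and carrying their forward and
backward formulas explicitly is what the catalogue module exists to do.
Single-threaded numpy also makes training bit-reproducible under a fixed
seed. Convolutions are same-padded, stride 1, via im2col; pooling is 2×2
averaging (exact, deterministic backward). Models serialize to JSON
(float64 via repr round-trip, hence bit-exact).

## Evaluation statistics

* **accuracy** — correct / total.
* **pixel-level F1** — `2tp / (2tp + fn + fp)` with counts pooled over
  all pixels of all images of a dataset (not averaged per image), so the
  score is independent of image size. The degenerate all-empty case
  (tp = fp = fn = 0) is defined as 1.0. 
* **Wilcoxon signed-rank** — two-sided, zero differences dropped, tied
  absolute differences mid-ranked. For ≤ 12 nonzero differences the null
  distribution of the positive-rank sum is enumerated over all 2ⁿ sign
  assignments (exact even under ties); beyond that the normal
  approximation with continuity correction is used.
* Report tables carry per-dataset scores, their arithmetic mean (Avg) and
  the rank of each method by Avg, mirroring the usual comparison layout.

Images are resized bilinearly to the model input size (224×224 by default)
and predicted masks are resized back to the source geometry by nearest
neighbor.

## Synthetic fixtures and the desk benchmark

The generators stand in for real classification/segmentation corpora so
everything runs on one CPU:

* Classification: class `c` is a sinusoidal grating at spatial frequency
  `3(c+1)` cycles per image (random orientation and phase per image),
  equal across RGB channels, plus Gaussian pixel noise (`noise_sd`,
  default 0.2 on a [0, 1] scale). At zero noise the classes are exactly
  recoverable from the dominant radial Fourier frequency, which the tests
  use as an independent oracle.
* Segmentation: one random ellipse per image filled from a skin-like RGB
  cluster (mean (0.80, 0.60, 0.50), sd 0.05) over a cooler background
  cluster (mean (0.35, 0.45, 0.55), sd 0.08); the mask is exactly the
  painted pixel set. A nearest-cluster color threshold is the oracle.

These fixtures reproduce the *structure* of the two task types, not the
intensity statistics, class imbalance, label noise or scale variation of
any real medical or skin corpus — passing here demonstrates correctness
of the machinery, not expected field performance.

The desk benchmark (`desk_benchmark` / `stochact bench`) compares a single
all-ReLU tiny CNN against a 5-member stochastic-replacement ensemble on
the 3-class texture task: 20 images per class at 32×32×3, stratified 2:1
train/test split, 8 epochs. Because these models train from scratch
rather than fine-tune a pretrained backbone, the benchmark uses learning
rate 0.05 with batch size 8, and disables the rescale augmentation —
axis rescales of 1–2× shift the very frequencies that define the
synthetic classes. Sizes were chosen so a 10-repetition comparison
completes in about half a minute. The tiny CNN (3 conv–activation blocks
of width 8, two average-pool stages, dense softmax head, preceded by a
fixed input centering of −0.5) is a desk-scale stand-in exposing the same
activation-slot interface a real backbone would.

## Numerical and degenerate-input conventions

* Forward/backward in float64 throughout (the arrays are tiny; no reason
  to trade precision).
* Non-finite activation inputs are rejected with a descriptive error.
* `argmax` ties (fusion decisions) go to the lowest class index.
* SReLU construction requires `t_l ≤ t_r`.
* Empty pools, empty datasets, zero-sized resize targets, mismatched
  shapes and out-of-range labels are rejected before any computation.
* An all-zero difference vector in the signed-rank test returns p = 1.0
  with a warning.

## Known limitations

* The backbone is a toy CNN; hooks exist (any `ModelGraph`-conforming
  layer stack) but no pretrained weights are shipped, so conclusions
  about large pretrained models cannot be drawn from the desk benchmark.
* The trainer is plain SGD; adaptive optimizers often tame the learnable
  activation parameters better than gradient clipping does.
* Mask augmentation uses nearest-neighbor labels against a bilinear
  image, so image/mask agreement at object boundaries is approximate
  under rescaling (exact under flips).
* The uniform draw law and per-layer SReLU knot sharing are modeling
  choices; both are isolated behind `ActivationSpec`/pool arguments and
  easy to revisit.
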
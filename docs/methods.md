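# Methods

This note records the scientific and numerical choices behind `gidfe`:
what each stage computes, the parameters that matter, what the synthetic
data does and does not emulate, and the places where the design was
genuinely open.

## Network

The backbone is a bottleneck ResNet-50 layout: a stem (7×7 convolution,
stride 2, 64 filters, BN, ReLU, 3×3 max pool stride 2) followed by four
stages of 3/4/6/3 blocks with 256/512/1024/2048 output channels; stages
2–4 downsample by stride 2 in their first block.  For a 224×224×3 input
the spatial sides are 112 (stem conv), 56 (pool / stage 1), 28, 14, 7.
Each bottleneck is 1×1 → 3×3 → 1×1 with BN and ReLU between layers and
an internal width of a quarter of the output channels (the standard
ResNet-50 convention; the narrower widths are not independently
configurable).

Two modifications define the starred variant:

* **Convolution-based shortcuts.**  Every block's shortcut path is a 1×1
  convolution (stride matching the block) plus BN — including blocks
  where shapes would permit an identity.  The plain variant uses identity
  shortcuts wherever possible and projection shortcuts only on
  channel/stride changes.  BN is applied to the shortcut before the
  addition and the ReLU after it, the conventional placement.
* **Pooling attention.**  Stage outputs (56/28/14/7 grids) are
  average-pooled with sizes 8/4/2/1 onto the 7×7 grid, mapped to 2048
  channels by a biased 1×1 convolution, and passed through a sigmoid.
  The default *multiply* mode modulates the stage-4 map by the
  elementwise product of the four gates, which keeps the map size
  unchanged; an *add* mode (stage-4 map plus the sum of the gates) is
  available behind the same flag because the gating semantics admit
  either reading.  Pool sizes are derived from stage geometry, so any
  input size whose stages halve cleanly (e.g. 64, 128, 224) gets a
  consistent attention grid.

With the full geometry, the starred variant carries ≈22.4 M more
parameters than the plain one (the shortcut convolutions of the
non-transition blocks plus the four gate convolutions); the surplus is
recomputed, not assumed, by the acceptance script.

The network runs on a small reverse-mode autodiff engine written on
NumPy (`gidfe._nn`): im2col convolution, train/eval batch norm, max and
non-overlapping average pooling, GAP, dense layers, ReLU/sigmoid,
softmax cross-entropy, SGD with classical momentum and L2 penalty.
Analytic gradients are verified against central finite differences in
the test suite.  Weights are He-normal, BN starts at unit gain; every
source of randomness is an explicit seeded generator, so runs are
bit-reproducible.  The sigmoid clips its logits at ±15 so gates remain
strictly inside (0,1) at float32 precision (value error < 3·10⁻⁷).

### Training

SGD with momentum 0.9 (the momentum coefficient is not itself dictated
by the solver name; 0.9 is the near-universal default), initial learning
rate 0.01 held constant, batch size 128 (clipped to the training-set
size), 25 epochs, L2 10⁻⁴, stratified 80:20 train/validation split with
a recorded seed.  An optional augmenter applies horizontal/vertical
flips and 90° rotations only — a deliberately conservative, exactly
invertible set.  After each epoch the running BN statistics are
*finalized*: one training-mode pass over (up to 256 of) the training
images with momentum 1 replaces the exponential averages with population
statistics.  Without this, short runs report near-chance evaluation-mode
accuracy while the training-mode loss is already low, because the
averages lag the rapidly moving activations.

## Explanation and feature extraction

Grad-CAM is computed against the model's **predicted** class by default
(labels of the images being explained never leak into extraction), from
the final activated pre-GAP map — the map the GAP layer summarizes, i.e.
after the attention combination and head BN/ReLU.  Channel weights are
the spatial means of the class-score gradient; the map is the ReLU of
the weighted channel sum, bilinearly upsampled to image resolution.

The ROI is the set of pixels **strictly above** `mean(map)·√2`.  Two
consequences are handled explicitly: a constant map can never exceed its
own mean times √2, and an all-zero map has threshold zero with nothing
strictly above it; both produce an empty ROI, which falls back to the
full-image mask (logged and recorded per image rather than dropping the
sample).  The threshold is scale-invariant: multiplying a map by any
positive constant scales both sides of the inequality equally.

Masking semantics: pixels outside the ROI are zeroed at their native
position (default), preserving spatial registration with the GAP layer;
a crop-and-resize mode exists for comparison.  The feature vector is the
GAP activation of the masked image — length equal to the final stage's
channel count, 2048 at full geometry.

## Iterative feature selection

Each ranker produces a full best-first permutation of the columns; ties
break toward the lower column index, so a constant matrix yields the
identity order.

* **Diagonal NCA** — nonnegative per-feature weights `w` maximizing the
  expected leave-one-out accuracy of a stochastic nearest neighbor rule
  under the distance `d(i,j) = Σ_r w_r² |x_ir − x_jr|`, with an L2
  penalty on `w` scaled per sample, by 60 steps of projected gradient
  ascent (step 0.1, `w` initialized at 1, columns z-scored first).
* **χ²** — columns are min-shifted, discretized into 10 equal-width
  bins, and scored by the χ² statistic of the bin-by-class contingency
  table (empty bins dropped).
* **mRMR** — mutual-information difference: greedily pick the column
  maximizing `MI(x_j; y) − mean_{s∈S} MI(x_j; x_s)` over the selected
  set `S`, on 10-bin discretized columns, continued to a full
  permutation.
* **ReliefF** — multi-class formulation with 10 nearest hits/misses per
  class, every sample an anchor, miss contributions weighted by class
  priors, differences range-normalized.

The wrapper evaluates every prefix length `L ∈ [sv, fv]` (inclusive;
defaults 100 and 768, lowered to the column count for narrow matrices)
with `1 −` the stratified 10-fold CV accuracy of the pipeline's kNN.
One fold partition is drawn per selection run and shared across all
candidate lengths, so the argmin compares losses on identical splits;
the smallest `L` achieving the minimum wins, preferring parsimonious
feature sets.  The fold count drops below 10 only when the smallest
class is smaller than 10 (logged).  Equivalence with an exhaustive
re-evaluation at every candidate length is asserted by an oracle test.

## Classification and fusion

*kNN*: k = 10 (clipped to the training-fold size), Euclidean distance,
squared-inverse distance weights; an exact-match neighbor (zero
distance) receives all the weight in its row, the limit of 1/d².
*SVM*: third-degree polynomial kernel, box constraint 1, one-vs-all
coding, features z-scored inside each training fold (flag-controlled)
because polynomial kernels are scale-sensitive.  All 14 outcomes of a
run are judged on one shared stratified 10-fold partition, so the
accuracies being sorted are comparable.  Outcome accuracies are pooled
out-of-fold accuracies, in percent.

Iterative majority voting sorts the 8 classifier outcomes by descending
accuracy (stable sort, preserving the kNN-then-SVM input order on ties)
and, for i = 3…8, takes the per-sample mode of the top-i predictions.
Mode ties — certain to occur for even i — go to the smallest class
label, matching the conventional numeric mode.  The greedy step selects
the maximal-accuracy outcome among all 14, first index on ties.

Metrics: accuracy `100·trace(C)/D`; macro F1; geometric mean
`100·(Π_k recall_k)^{1/K}` over the K classes present in the labels
(an absent class has no recall and is excluded with a warning).  Note
the geometric mean of recalls can never exceed the best per-class
recall; reported values above the paired accuracy in external tables
are arithmetically impossible under this definition.

## Synthetic data

`make_images` emulates the *structure* of endoscopy datasets — balanced
class folders of RGB images whose class evidence is a localized lesion —
not their appearance.  Each class's signature is a Gaussian blob
(σ = radius/2, radius 0.16 of the image side) of a class-specific hue
with a class-specific sinusoidal texture, placed on a ring around the
image center at a half-step angular offset so no signature straddles the
principal axes, where coarse pooling grids cannot resolve it; per-image
position jitter is ±3%.  Backgrounds are gray Gaussian noise.  Blob
centers and radius are exported so attribution maps can be scored
against ground truth.  `make_features` plants informative columns as
class-mean-shifted Gaussians whose class means are equally spaced with
total span `effect` (in units of the unit noise SD), with a random sign
per column; all other columns are label-independent noise.  Both
generators are pure functions of their arguments including the seed.

What passing tests on these fixtures show: the pipeline's mechanics —
counts, orderings, oracle equivalences, localization of a known planted
signal — behave as specified.  What they do not show: performance on
real endoscopic imagery, which involves texture statistics, lighting,
specular highlights and class overlap the fixtures do not model.

A degeneracy worth knowing: with only two classes and a 3σ effect, two
or three planted columns already drive the CV loss to zero, and the
first-minimum tie rule then (correctly) stops before collecting all
planted columns.  Planted-recovery checks therefore use a 4-class
fixture with ≥ 40 samples per class, where per-feature class separation
is weaker and full recovery is the reproducible outcome.

## Problem sizes

Desk-scale runs use a scaled network (`ArchitectureSpec.tiny`: identical
topology, stem width 8, one block per stage at 32/64/128/256 channels,
64- or 128-pixel inputs) and small selection ranges (sv = 2, fv = 20).
These sizes are the package's chosen study conditions for CPU
reproducibility; the full 224-input geometry is built and exercised
directly for shape, parameter and feature-length checks.  Grad-CAM
localization checks use 128-pixel inputs, where the final map is 4×4 —
at 64 pixels the 2×2 map's receptive fields are too coarse for peak
localization (mask-coverage comparisons still pass there).

## Known limitations

* The NumPy engine is single-threaded and eager; full-geometry
  *training* is out of reach — the full model is only built and run
  forward/backward for structural checks.
* Whether attention gates should also feed stages 1–3 into the head is
  ambiguous in the architecture's description; only stage-4 gating is
  implemented.
* The exact BN/ReLU placement around the shortcut convolution follows
  ResNet convention; alternatives were not ablated.
* mRMR's full-permutation greedy is O(p²) mutual-information updates;
  at p = 2048 this is the slowest ranker by a wide margin.
* The DFE stage evaluates classifiers by cross-validation on the
  extracted features themselves; a disjoint train/test protocol for the
  shallow stage is supported by the module surfaces (fit/predict via
  scikit-learn estimators) but is not the pipeline default.
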
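# Methods

This note documents the models, procedures, numerical choices and known
limitations of `sksformer`. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

The package classifies short windows of tri-axial inertial data (waist-worn
accelerometer, optionally gyroscope/attitude) into activity classes — both
coarse daily activities (walking, stairs, standing …) and fine-grained
motion-quality categories (e.g. swing-error types). It covers the full
path from the sensor's binary wire format to cross-validated metrics.

## Sensor frame protocol

JY61-family modules emit three sequential 11-byte frames per sample
(acceleration 0x51, angular velocity 0x52, attitude angle 0x53), each
`0x55 | type | 8 payload bytes | checksum`, the payload being four
little-endian signed shorts (x, y, z, temperature). Physical scaling is
range-based: `raw / 32768 × full_range` with full ranges ±16 g,
±2000 °/s and ±180°; temperature is `raw / 100` °C. The angle range is
the attitude-output convention of this sensor family (configurable); it
is not dictated by the wire format.

The module datasheet also quotes sensitivities of 16,384 LSB/g and
131 LSB/(°/s). These cannot both hold with the stated ±16 g / ±2000 °/s
ranges on a 16-bit word (16,384 LSB/g fills 16 bits at ±2 g). The codec
therefore uses the range-based convention throughout; the
sensitivity-derived resolutions (1/16384 ≈ 6.1·10⁻⁵ g,
1/131 ≈ 7.6·10⁻³ °/s) are exposed by `sensitivity_resolution()` as
documented constants only.

Corrupted streams never raise: the parser scans forward to the next
header byte and reports checksum failures, skipped bytes and incomplete
triples in a diagnostics record. Ten consecutive samples aggregate into
one transmission packet (100 Hz sampling → 10 packets/s).

## Preprocessing

1. **Low-pass** — 4th-order Butterworth, cutoff 2.5 Hz (human-activity
   energy concentrates below ~3 Hz), applied forward-backward for zero
   phase with odd-reflection padding of length 3·(order+1)=15 per end.
   Exact reversal symmetry consequently holds away from the edges; the
   finite padding leaves ~10⁻² transients in the outermost samples.
2. **Savitzky–Golay** — window 11, polynomial order 3, polynomial edge
   fitting (`mode="interp"`), hence exact on cubic signals everywhere.
   Order fixed: low-pass first, then smoothing.
3. **Windowing** — half-open, 0-based windows of T=200 steps, stride 100;
   trailing remainders are dropped. Two sampling-rate presets exist,
   `hardware` (100 Hz → 2 s windows) and `benchmark` (20 Hz → 10 s); the
   rate is a required configuration choice, not an assumption.
4. **Label filtering** — windows straddling an activity transition are
   dropped; survivors carry their constant label. Per-record-labeled
   inputs (one short recording = one label) pass unchanged and are
   center-cropped / edge-padded to T.
5. **z-scoring** — per-axis mean/std over all timesteps of the *training*
   portion only (std clamped at 10⁻⁸ with a warning for constant axes).
   Fitting on the full dataset leaks validation information into the
   transform; a `norm_scope: global` switch restores whole-dataset
   fitting for compatibility experiments, but the leak-free scope is the
   default and is what the cross-validation harness enforces per fold.

## Classifier

Input `X ∈ R^{T×D}` (default 200×3, z-scored) flows through:

1. **Input projection** `H0 = X·Wp + bp` into a `d_model`-wide latent
   sequence (default 128). No positional encoding by default — the
   encoder equations contain none; an optional sinusoidal table exists
   for experimentation.
2. **Post-norm transformer encoder**, two layers:
   `H' = LN(H + MHSA(H))`, `H1 = LN(H' + FFN(H'))`, multi-head scaled
   dot-product attention (h=4 heads, scale 1/√d_k) and a ReLU FFN of
   width `d_ff` (default 256). Post-norm order (LayerNorm *after* the
   residual addition) is deliberate, not the more common pre-norm.
3. **Selective-kernel (SK) branch**: grouped temporal convolutions with
   kernel sizes {1,3,5,7} (groups 4, same padding) → batch-norm → ReLU
   per branch; the branch sum is pooled over time into a context vector
   `z`, compressed to `s = ReLU(W1 z)` (width `d_s = d_model/4`), and a
   per-branch softmax over `w_k·s` yields scalar mixing weights
   `α_k` (Σα_k = 1), giving `V_SK = Σ α_k U_k`. Branch weights are
   scalar per sample — not per-channel as in the image-domain original —
   matching the formula this architecture family states.
4. **Squeeze-enhanced axial (SEA) branch**: `H1` is reshaped to a 4-axis
   map `(B, C_attn, H=T, W=d_model/C_attn)` (default `C_attn=8`), so row
   attention is temporal and column attention spans feature sub-bands.
   Depthwise temporal convolutions (k=3) produce Q/K/V; each axis is
   *squeezed* by mean-pooling the other axis before its softmax
   (scale 1/√C_attn), with learnable additive positional vectors of
   lengths T and W; attended values pass depthwise conv encoders and are
   broadcast-added back onto V; a pointwise projection and a sigmoid
   produce `V_SEA ∈ (0,1)`. The sigmoid is applied literally (it is
   unusual but part of the design); a flag disables it for experiments.
   A degenerate `W=1` reading (`c_attn = d_model`) is expressible for
   comparison; the sub-band reshape is the default because with `W=1`
   the column softmax is over a singleton.
5. **Gated fusion**: `G = sigmoid(Conv1×1(H1))` with one output channel,
   broadcast over channels; `V = G·V_SK + (1−G)·V_SEA` — an elementwise
   convex combination, so `V` always lies between the branches.
6. **Head**: temporal global average pooling, a fully connected layer to
   K logits, softmax probabilities; training minimizes categorical
   cross-entropy.

Weights are initialized fan-in uniform (normalization layers ones/zeros);
a single integer seed fixes every draw, and evaluation is bit-reproducible
(inference disables graph recording and dropout).

### Ablation variants

`FullModel`; `No_SK` / `No_SEA` (fusion bypassed, head consumes the
remaining branch — minimal surgery, no gate on a single branch);
`No_Gate` (both branches kept, fixed 0.5/0.5 average, gate parameters
absent); `No_Filter` (denoising skipped, everything else identical);
`No_Attn` (encoder output pooled straight into the head). Parameter
counts are strictly ordered: FullModel > single removals > No_Attn.

## Numerical engine

The network runs on a small reverse-mode automatic-differentiation engine
over float32 NumPy arrays (`sksformer.nn`): broadcasting arithmetic,
batched matmul, reductions, grouped 1-D convolution (im2col), a fused
scaled-dot-product attention primitive with an analytic backward (the
(B,h,T,T) intermediates dominate runtime, so they are materialized once),
layer/batch normalization, dropout, and Adam. Gradients are verified
against central finite differences in the test suite; the computation
graph is freed immediately after each backward pass and inference runs
under a no-grad context, keeping peak memory well under 1 GiB at the
default benchmark sizes. The SEA output is made memory-contiguous before
fusion so that pooling sums in the same order along both branch paths;
this is what makes the forced-gate path equivalence bit-exact rather
than merely close.

## Training and evaluation

Adam (lr 0.001), batch 64, categorical cross-entropy, up to 100 epochs
with early stopping (patience 10) on a 10% validation split; among
epochs with equal best validation accuracy the *latest* checkpoint is
kept — on small validation splits long plateaus at the same score are
common and the first-tie checkpoint is systematically under-trained.
Cross-validation is stratified, window-wise, 5 folds; normalization is
fitted per fold on training windows only; fold averages are unweighted
means. Precision/recall/F1 are macro-averaged by default (the averaging
scheme is switchable to support-weighted); note macro averaging can
legitimately place F1 above accuracy on imbalanced folds.

## Synthetic data generator

Each class is a harmonic series (three partials, amplitudes 1/0.4/0.2)
at a class-specific fundamental, modulated by a slow amplitude envelope,
mixed across axes by a class-specific orthonormal rotation, plus slow
sinusoidal baseline drift (0.1 g, 60 s period) and white Gaussian noise
(σ = 0.15 g). The rotation acts on the *body-frame* signal including the
1 g gravity vector, emulating activity-dependent device orientation: in
real waist-worn accelerometer data the gravity projection is the
dominant postural cue, and here it guarantees directional class
separability (rotated-gravity directions sit on a Fibonacci sphere
lattice, pairwise angles ≳ 40° at K=6). Fundamentals are spread evenly
over 0.5–2.4 Hz, below the 2.5 Hz low-pass cutoff, ~0.4 Hz apart — four
frequency bins of a 10 s window.

Defaults (the package's study conditions): 6 classes, 20 Hz, 12 sessions
of 3 segments of 25–35 s each, giving ≈150 label-consistent windows of
200×3 after preprocessing with near-equal class shares. Sessions derive
per-session seeds from the master seed by fixed offsets. A per-record
mode emulates short single-label recordings (4 swing-quality classes ×
30 records of 8–12 s).

What the generator *does* emulate: quasi-periodicity, directional
structure, posture offsets, drift, additive noise, activity transitions,
class imbalance at segment granularity. What it does *not*: inter-subject
variability, non-stationary tempo, sensor saturation and dropouts,
correlated (non-white) noise, or realistic biomechanics of any specific
sport. Passing benchmarks on this data therefore demonstrates that the
pipeline and optimizer work end-to-end on learnable signals with the
stated structure — not benchmark-level performance on real recordings.

By construction a trivial spectral-peak classifier (summed periodogram,
nearest fundamental) reaches ≥95% window accuracy on the defaults, so
the dataset is certifiably learnable and model-accuracy tests are
meaningful rather than vacuous.

## Benchmark protocols and problem sizes

Two standard experiments (`sksformer.benchmark`) run on the default
dataset; the sizes are the package's own choice to keep the experiments
desk-scale on one CPU:

* **Cross-validation benchmark** — reduced architecture (d_model 32,
  d_ff 64, d_s 8, otherwise defaults), Adam 1e-3, batch 64, ≤30 epochs,
  early stopping as above, stratified 5-fold. Completes in a few
  minutes; the suite asserts ≥95% mean accuracy.
* **Ablation benchmark** — all six variants × three seeds on a 75/25
  holdout, each trained to convergence (batch 32, Adam 3e-3, ≤50 epochs,
  patience 12 on a 15% split). The smaller batch and larger step size
  are deliberate: every variant, including the slower-optimizing
  single-branch ones, must reach its own ceiling, otherwise variant
  differences measure optimization budget rather than architecture. The
  suite asserts the qualitative ordering: full model ≥ each single
  removal, and the attention-free variant weakest (ties allowed — on
  strongly separable synthetic data several variants saturate).

## Known limitations

* The NumPy engine is single-threaded and 5–10× slower than a compiled
  framework; the default widths (d_model 128) train slowly on CPU, which
  is why the benchmarks use the reduced architecture.
* Subject-wise (leave-one-subject-out) evaluation is not implemented;
  folds are window-wise, so windows from one session can appear on both
  sides of a split — fine for the synthetic benchmark, optimistic for
  real multi-subject data.
* The UCI-style and PAMAP2-style adapters make documented channel and
  resampling choices (chest 16 g accelerometer columns 21–23, linear
  interpolation of gaps ≤10 samples, linear record resampling); exact
  parity with any published benchmark protocol is out of scope.
* Axial attention is single-head; the head split is configurable ground
  left unexplored.
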
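# Methods

`ctgrp` screens for intrapartum fetal hypoxia from the fetal heart rate
(FHR) channel of a cardiotocogram. The pipeline is: rule-based signal
cleaning → time-delay embedding → recurrence-plot (RP) imaging with
per-point k-nearest-neighbour thresholds → a compact convolutional
classifier → 10-fold cross-validated evaluation. This note records the
model, the parameters that matter, the numerical choices, and what the
synthetic data generator does and does not establish.

## Signal model and preprocessing

Input is a uniformly sampled FHR trace in beats per minute (4 Hz in the
CTU-UHB database), with `0` encoding transducer signal loss. Cleaning
applies three ordered rules:

1. **Gaps.** Maximal zero-runs longer than 15 s (strictly) are spliced
   out; shorter runs are bridged linearly between the flanking valid
   samples. A run of exactly 15 s is interpolated.
2. **Stability.** Where two adjacent samples differ by more than 25 bpm,
   the stretch up to the next *stable part* is replaced by linear
   interpolation between the last stable sample and the first sample of
   the next stable part. A stable part is operationalised as at least
   `stable_run_samples` (default 8 samples = 2 s at 4 Hz) consecutive
   samples whose adjacent differences all stay within 25 bpm; the value
   is exposed in `PreprocessConfig` because any shorter anchor would let
   isolated pairs of artifact samples count as "stable".
3. **Extremes.** Samples outside 50–200 bpm are refilled by monotone
   piecewise-cubic Hermite (PCHIP) interpolation through the surrounding
   in-range samples; monotone interpolation cannot overshoot its
   anchors, so outputs stay in range without clamping heuristics.

Runs of invalid samples touching either record end have no interpolation
anchor and are trimmed. The pipeline classifies the **final**
`segment_length_min` minutes (default 13) of the cleaned trace: the
recording ends at delivery, which is when the umbilical-artery pH — the
ground-truth label — is measured, so the end-anchored window is the one
causally closest to the outcome. Preprocessing is idempotent and
length-monotone (property-tested).

## Recurrence-plot imaging

A scalar window `u_1..u_L` is delay-embedded with dimension `m ≥ 2` and
delay `τ ≥ 1` into `N = L − (m−1)τ` points
`x_i = (u_i, u_{i+τ}, …, u_{i+(m−1)τ})`. The binary recurrence matrix is

    R[i,j] = Θ(ε_i − ‖x_i − x_j‖),   Θ(x) = 1 if x > 0 else 0,

with the Euclidean norm and per-point thresholds chosen by the fixed
amount of nearest neighbours (FAN) rule: `ε_i` is the distance from
`x_i` to its k-th nearest neighbour, self excluded. Consequences worth
stating explicitly:

* With all pairwise distances distinct, every row holds exactly `k`
  ones (`k−1` neighbours plus the diagonal), so the global recurrence
  *rate* is `k/N` regardless of the signal — FAN RPs carry class
  information only in the *arrangement* of recurrences, never in their
  count, and they are invariant to amplitude scaling of the trace.
* The step function is strict: `Θ(0) = 0`. A point whose k-th
  neighbour is at distance exactly `ε_i` — which is every point, by
  construction — does not recur with it, and a point set with zero
  threshold (e.g. a constant signal, or a run of identical quantized
  samples) produces an all-zero row *including the diagonal*.

Because the threshold sits exactly on a computed distance, the threshold
and matrix stages must share one floating-point distance arithmetic: a
BLAS-style `‖a‖²+‖b‖²−2ab` kernel differs from a plain
difference-square-sum by an ulp, which is enough to flip the strict
comparison. Both stages therefore accumulate squared coordinate
differences in coordinate order (chunked to bound memory at ~100 MB);
the test oracles check them against exact rational arithmetic on squared
distances.

### Rendering

The N×N matrix (N ≈ 3,100 for a 13-min window) is mapped to a 64×64
grayscale image, recurrences white on black. The default mode,
`raster`, emulates what a plotting device does when it draws an RP
figure: a pixel is white when **any** recurrence falls inside its
N/64 × N/64 block. The alternative `mean` mode is an exact area average
(mean pixel intensity equals the recurrence rate to machine precision;
property-tested).

Rasterisation is the default because of the row-sum fact above: with the
rate pinned at `k/N`, an area average of a ~50× downsampled FAN matrix
approaches the same flat gray for every signal, whereas the block-OR
preserves *clumping* — smooth, low-complexity traces concentrate their
recurrences into lines and blocks (fewer pixels covered), noisy traces
scatter them (most pixels covered). Measured on the synthetic cohort,
area-averaged images of the two classes are statistically
indistinguishable while rasterised images separate cleanly, so the mean
mode is kept for density analysis, not classification.

The CNN input is 64×64×3 with the grayscale plane replicated across the
three channels.

## Synthetic cardiotocography generator

The generator produces the study conditions for every test; no external
data is required. A record is

    baseline + STV + LTV + accelerations − decelerations,

clipped to [baseline−30, baseline+30] ∩ [50, 200] bpm, overwritten with
artifacts (zero dropout runs of 2–30 s, then isolated ±35–90 bpm
spikes), and finally quantized to 0.25 bpm — the storage resolution of
the CTU-UHB acquisition chain.

* **Baseline**: drawn uniformly from 110–160 bpm unless fixed.
* **STV** (short-term variability): Gaussian noise smoothed to a
  correlation time of `stv_corr_s` (0.15 s default — genuine
  beat-to-beat fluctuation at 4 Hz), scaled to `stv_bpm` (7 bpm).
* **LTV** (long-term variability): the slow oscillation, correlation
  time 2 s, amplitude 5 bpm.
* **Accelerations**: Gaussian bumps, +10–25 bpm over 15–60 s, Poisson
  at 15/h.
* **Decelerations (normal)**: sporadic Poisson events at 1/h, 10–40 bpm
  over 20–90 s.

The pathological (hypoxia) preset encodes the clinical picture of the
distressed fetus as *temporal structure*, not merely amplitude — a
deliberate choice, because FAN recurrence plots are amplitude-invariant
(see above) and the discriminative content must live in trace
complexity:

* variability halved in amplitude (STV 3.5, LTV 2.5 bpm) **and**
  slowed: STV correlation ×20 (3 s — suppressed beat-to-beat autonomic
  modulation), LTV correlation 15 s (slow wander);
* accelerations ×¼;
* **recurrent late-type decelerations**: contraction-coupled rather
  than Poisson — one uterine-contraction slot every 150–210 s, each
  producing a deceleration with probability 0.9, shallow (8–16 bpm) and
  gradual (60–120 s). "Recurrent" decelerations accompanying most
  contractions is the textbook intrapartum hypoxia pattern; the
  coupling also means essentially every 13-min window of a pathological
  record contains events.

Two mechanisms make the classes separable in RP images: the smooth
pathological trace often slews less than the 0.25 bpm quantum, so
quantization creates runs of identical samples whose zero FAN thresholds
blank entire matrix rows (dark images), and each deceleration is an
excursion whose points recur only within the event, drawing black
cross-stripes. On the default cohort the per-grid-cell white fractions
of the two classes do not overlap, and a single per-record variance
threshold separates ≥ 90% of a 200-record cohort (tested).

**What passing tests do and do not show.** The generator reproduces the
qualitative FIGO-pattern vocabulary (baseline, variability,
accelerations, decelerations, artifacts) and the acquisition
quantization, but it is not a physiologically validated simulator: real
traces carry maternal-heart-rate confusion, transducer displacement
drift, autocorrelation-method quantization artifacts, and a continuum of
intermediate fetal states. Perfect or near-perfect synthetic
cross-validation scores certify that the pipeline's machinery works end
to end, not that comparable accuracy would be obtained on clinical data.

## Dataset assembly

Labels come solely from umbilical-artery pH: `pH ≥ 7.15` → normal,
otherwise pathological. The majority class is subsampled without
replacement (seeded) to the minority size. Each record is expanded into
one RP image per cell of the augmentation grid — default
`m ∈ {2,3} × τ ∈ 1..10 × k ∈ 1..10` = 200 images — so a balanced
105 + 105 cohort yields 21,000 images per class.

Folds are stratified and can be built at image level (the historical
protocol: images assigned independently, so augmented views of one
record land in both train and test — this leaks record identity and
inflates accuracy) or at record level (all images of a record share a
fold; the honest generalisation estimate and the default here). Within
the nine training folds a seeded 90/10 train/validation split is made;
the proportion is a package choice.

## The classifier

The default 8-layer network (input, 2 convolution blocks, 2 average
pools, 2 dense layers, softmax output; batch-norm/ReLU/dropout ride
with their hosts):

    64×64×3 → conv 5×5×8 (s1, p0) → BN → ReLU → avgpool 3×3 (s2)
            → conv 5×5×8 → BN → ReLU → avgpool 3×3 (s2)
            → dense 144 → dropout 0.8 → dense 2 → softmax

giving feature maps 60×60×8 → 29×29×8 → 25×25×8 → 12×12×8 → 144 → 2.
The first dense layer maps the flattened 12·12·8 = 1,152 features to
144 units. A 5–12-layer family (`architecture_from_code`) supports
capacity comparisons; members whose windows no longer fit (the
12-layer's last convolution on a 3×3 map) raise a shape error at build
time.

Training: cross-entropy, mini-batch 64, 10 epochs, learning rate 1e-3,
L2 1e-4 on weights (not biases or norm parameters), dropout 0.8
(inverted), optimizer Adam / SGD-momentum 0.8 / RMSProp. Choices the
source material leaves open, fixed here:

* **Adam decay factors.** The "gradient decay factor 0.6" is read with
  the original training toolbox's parameter naming, where it denotes the
  *first-moment* decay: β₁ = 0.6, β₂ = 0.999, ε = 1e-6 (all exposed).
  RMSProp uses squared-gradient decay 0.6.
* **Initialization**: seeded scaled-uniform with fan-in limit
  `√(6/fan_in)`; the classifier head is additionally scaled by 0.01 so
  early softmax outputs stay near-uniform and the first gradient steps
  carry feature signal rather than head noise.
* **Batch-norm statistics**: training uses batch moments; for
  evaluation, exact moments over (up to 1,024 of) the training images
  are recomputed after every epoch. With only tens of optimizer steps,
  momentum-style running averages still carry their initialization and
  skew evaluation-mode outputs; the exact recomputation is deterministic
  and removes that bias.
* **Input normalization**: zero-centering by the training-set mean
  pixel value.
* **Ties** in argmax prediction go to the first class (normal).
* **Epoch** = one full pass over the training images.

Prediction is deterministic (dropout off, fixed statistics); training is
bit-reproducible for a fixed (data, config, seed). Checkpoints are
single `.npz` files embedding the architecture, parameters, statistics
and history.

## Evaluation

The **positive class is the normal fetus** — sensitivity is the
detection rate of normal fetuses, specificity of hypoxic ones; this
mirrors the convention of the original study and is the opposite of the
usual disease-positive clinical convention (`positive_class` overrides
it everywhere). Acc/Se/Sp are reported in percent at full precision,
with half-up rounding to 2 decimals for display. AUC is the trapezoidal
area under the empirical ROC (equal to the Mann–Whitney concordance
probability; cross-checked in tests against an exhaustive pairwise
count), with a seeded stratified bootstrap (2,000 resamples) for its
confidence interval.

`cross_validate` trains a fresh seeded model per fold (optionally
`n_restarts` multi-start fits selected by final training loss) and
averages fold metrics arithmetically. A single master seed derives all
stage seeds via SHA-256 of `"{seed}:{label}"`, so identical runs are
byte-identical.

## Problem sizes used in the shipped checks

The cross-validated learning check runs a 30 + 30 record cohort of
13-min records over the reduced grid `m=2, τ∈{1,2}, k∈{2,6}` (240
images) with record-level 10-fold CV — chosen as the smallest cohort
that exercises every pipeline stage at full 13-min window length.
Augmentation accounting uses 105 records per class over the full
200-cell grid on 90-s records, since the image count is
length-independent. Recurrence oracles run on ~100 random trajectories
with N ≤ 50 where exact rational arithmetic is cheap.

## Known limitations

* The synthetic generator is a statistical stand-in (see above), and the
  pathological preset intentionally makes the two classes separable; it
  measures pipeline correctness, not clinical performance.
* The WFDB reader supports the CTU-UHB layout only (format-16 signals,
  `#key value` clinical notes); it is not a general WFDB implementation.
* How the original study resized an N×N matrix to 64×64, what its three
  input channels carried, and its exact toolbox defaults
  (initialization, batch-norm epsilon) are unrecoverable; results on
  real data are expected to be reproduced in distribution, not
  bit-exactly.
* Image-level folds reproduce the historical protocol but leak record
  identity across the train/test boundary; numbers obtained that way
  should be read as upper bounds.
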
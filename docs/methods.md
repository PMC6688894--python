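# Methods

`cineqc` implements a complete, self-contained study of motion-artefact
detection in cine cardiac MR: a physics-based k-space corruption simulator, a
ventricle ROI localiser, two spatio-temporal neural classifiers, and a
severity-ordered curriculum training scheme, all exercised on synthetic
beating-ventricle phantoms.  This note records the models, the parameters
that matter, the numerical choices, and what the synthetic setting does and
does not show about real data.

## Phantom model

A phantom is a 2D+time magnitude sequence containing a bright annulus
("myocardium", intensity 0.9) around a mid-grey disk ("blood pool", 0.5) on a
dark background (0.1) — enough bSSFP-like contrast for edge detection and
convolutional features; the exact levels are configurable and immaterial.
The inner radius follows

    r(t) = r_min + (r_max - r_min) * (1 - cos(2*pi*c*t/(T-1))) / 2,

so an integral number of beat cycles `c` closes periodically (first and last
frames coincide in the noise-free case).  Edges use one-pixel linear ramps to
avoid gridding artefacts.  Noise is additive Gaussian clipped at zero;
Rician noise, multi-slice geometry, coil/phase effects and anatomical realism
are explicitly out of scope.  Dataset generation jitters centres uniformly
within the valid-centre region and scales radii by a random factor in
[0.85, 1], so localisation is not trivially solvable.

What the phantom does **not** emulate: anatomical background structure
(chest wall, liver), through-plane motion, intensity inhomogeneity, and the
visual variability of real artefacts.  Consequences for interpreting results
are discussed under *Limitations*.

## K-space corruption

Cartesian cine acquisition fills k-space line by line over multiple
heartbeats; the simulator reproduces the two dominant failure modes in the
frequency domain of each frame (centred unnormalised 2D DFT).

**Mistriggering.** Every z-th phase-encode row (stride comb with a seeded
random phase r ∈ [0, z)) of frame *i* is replaced by the same rows of frame
(i + j) mod T.  The offset j is drawn per frame, uniform on {1, ..., T-1}
(`offset_mode="fixed"` pins it).  Smaller z corrupts more lines: more severe.
A `random_subset` selection mode replaces ⌊N/z⌋ random rows instead of a
comb.

**Breathing.** Each k-space row ℓ is taken from the frame translated along
the phase-encode axis by a sinusoidal displacement

    d(ℓ) = offset + A * sin(2*pi*cycles*s/n_samples + phi),

sampled at 256 points over 4 cycles (the acquisition-length breathing
pattern) and linearly resampled onto the frame's N rows.  The translation is
applied by the Fourier shift theorem (row with centred frequency f is
multiplied by exp(-2i*pi*f*d/N)), which is exact for subpixel shifts and
reduces to a circular shift for constant integer d.  The phase phi is seeded
uniform on [0, 2*pi) so samples do not share a breathing phase; amplitude A
controls severity.

Only magnitude images exist upstream, so corruption operates on the DFT of
the magnitude image and reconstructs the magnitude of the complex inverse.
Corruption is applied at native image size, before ROI cropping, mirroring
the acquisition-then-preprocessing order.

**Severity schedules.** Level 1 is most severe.  Defaults: mistriggering
z ∈ {2, ..., b+1}; breathing amplitudes log-spaced from 8 px down to 0.8 px.
The expected image deviation is strictly monotone across levels (verified by
exact enumeration over comb phases and offsets); because a single random
draw's deviation depends heavily on whether the comb hits the
energy-dominant central k-space rows, monotonicity *tests* use common random
numbers across levels (same comb-phase quantile and frame offset per draw) —
the standard variance-reduction design for comparing levels of one factor.

## ROI localisation

Each slice sequence spans one heartbeat, so the per-pixel magnitude of the
first-harmonic temporal Fourier coefficient (DC excluded; bin configurable
for multi-beat data) concentrates on the moving annulus.  On this activity
image, circular Hough candidates are collected — best circle per radius over
a configurable range (default 5–40 px at 1.8 mm spacing), top 10 overall,
ties broken by smaller radius then row-major order for determinism.  Each
candidate centre contributes an isotropic Gaussian kernel (sigma 5 px)
scaled by its Hough score; the likelihood-surface argmax is the ROI centre.
The voting operation accepts one or many candidate sets, so single-slice
phantoms and multi-slice stacks use the same code path.

Edge detection defaults to Canny (sigma 1) rather than plain
gradient-magnitude thresholding: thresholding produces thick edge bands in
which small spurious circles saturate the circumference-normalised Hough
accumulator at score 1.0 anywhere inside the band, biasing the kernel vote
by 2–3 px; Canny's non-maximum suppression yields one-pixel edges and
restores sub-2-px recovery.  The percentile-threshold variant remains
available (`edge_method="percentile"`).

Crops are 80 × 80 by default (half-open windows, clamped inside the image);
sequences are then z-score normalised (zero mean, unit variance over the
whole sequence).

## Classifiers

Two video-classification architectures, built on a small numpy layer engine
written for this package (stride-1 shape-preserving 2D/3D convolution via
sliding-window views, 2× max pooling with odd-remainder trimming, ReLU,
inverted dropout, LSTM, dense layers; every gradient is validated against
finite differences in the test suite):

* **3D CNN** — 6 convolutional layers (3×3×3), 4 pooling layers, two
  fully-connected layers (1024 units, then one per class), softmax readout;
  dropout (p = 0.5) after each convolutional layer and the first dense layer.
* **LRCN** — a per-frame feature extractor of 6 convolutional and 3 pooling
  layers whose vectorised output feeds a single-layer LSTM; the prediction is
  read from the final LSTM step.

Filter counts (16, 32, 32, 64, 64, 128), kernel sizes and the LSTM width
(128) follow the C3D-style convention for spatio-temporal nets and are fully
configurable; `ModelSpec.tiny` (channels (2, 2, 4, 4, 8, 8), LSTM 16, no
dropout) is the CPU-scale preset used throughout the tests and benchmarks.

**Optimisation.** SGD with momentum 0.90, learning rate 1e-4, batch size 50
by default (desk-scale runs use larger rates and smaller batches, passed
explicitly).  Loss is softmax cross-entropy, optionally weighted per class;
inverse-frequency weights normalised to the majority class reproduce the
22.4 : 1 ratio of a 224 : 10 split.  Weight initialisation is zero-mean
Gaussian with He (fan-in) scaling — literal unit-variance initialisation
makes six-layer ReLU stacks overflow in float32, so it is exposed as
`init="unit"` but not the default.  Gradients are clipped to a global L2
norm of 5.0, the standard guard against exploding LSTM gradients (observed
as float32 sigmoid overflow before clipping was added).  All randomness
(init, shuffling, dropout) flows from explicit seeds; bitwise
reproducibility across BLAS builds is not promised, statistical
reproducibility is.

**Early stopping and checkpointing.** Training stops when `patience`
consecutive epochs pass without a relative validation improvement of at
least 0.5% (patience 100 by default; `patience=0` runs exactly one epoch),
and returns the weights of the best validation epoch.  The
selection/stopping metric is the standard balanced accuracy
(sensitivity + specificity)/2: the (precision + recall)/2 variant used for
*reporting* (below) is undefined whenever a model predicts no positives,
which happens routinely in early epochs on imbalanced pools.

**Augmentation.** Random integer translations up to ±W/5 per axis
(zero-filled, constant across frames, label-preserving) and per-frame
spatial Gaussian blur (sigma 0 = identity) are available for class
balancing and robustness experiments.

## Curriculum training

Baby-step curriculum: the training pool starts as the original labelled set
and cumulatively gains synthetic stages D^1..D^b — freshly corrupted copies
of good-quality training samples at each stage's severity — most severe
("easy") first.  Each stage trains k epochs (k = 4 at desk scale; the
reference protocol leaves k unstated); after each stage the best validation
checkpoint so far is retained, and the optimiser state, RNG stream and log
persist across stages, so a b = 1 curriculum is exactly plain training on
the pooled set.  Original artefact cases, whose severity is unknown, stay in
the pool at every stage.  Baselines: *anti* reverses the stage order;
*control* randomly partitions the pooled synthetic samples into b equal
stages.  Fresh corruptions are generated per stage rather than splitting one
corrupted pool; with per-stage severity parameters the two constructions
coincide in distribution.

## Evaluation

Artefact is the positive class.  Reported balanced accuracy defaults to
(precision + recall)/2 to match the reference protocol's tables; the
standard (sensitivity + specificity)/2 is behind a flag.  Recall is
TP/(TP + FN) (the protocol's printed formula TP/(TP + FP) duplicates its
precision definition and contradicts its own prose).  AUC is the trapezoidal
area under the ROC curve from a full threshold sweep, equal to the
probability that a positive outscores a negative with ties at 1/2 (the
test suite checks this equivalence exhaustively).  Zero-denominator metrics
are reported as undefined (`None`), never as 0.  Cross-validation is
repeated stratified k-fold (k = 10 by default) with per-fold class counts
within one sample of proportional.  The variance-of-Laplacian blur score
(mean over frames of the variance of the discrete Laplacian response)
provides a no-reference baseline; on a ±1 checkerboard under periodic
boundaries its response is -8x everywhere, giving variance exactly 64.

## Desk-scale benchmark conditions

All experiments run on one CPU in minutes; problem sizes are the package's
own choices and are stated here once:

* **Separability benchmark** — tiny LRCN, 160 training sequences (80 clean /
  80 mistriggered at z = 2), 40 × 40 crops, 16 frames, disjoint validation
  and 40-sequence hold-out, early stopping (patience 5, ≤ 30 epochs),
  learning rate 0.02, batch 16.  Median hold-out AUC over 3 seeds is the
  reported number.
* **Curriculum benchmark** — 180 good : 20 artefact originals (artefact
  severities drawn uniformly over all levels, emulating real cases of
  unknown severity), b = 5 stages of 16 synthetic samples each, 32 × 32
  crops, 10 frames, tiny LRCN, k = 4 epochs/stage; data, model seed and
  splits are identical across the three orderings for a given seed, so
  differences isolate the stage order.  Mean hold-out AUC over 5 seeds per
  ordering is the reported number.

## Limitations

The phantom-vs-corrupted-phantom task is markedly easier than real
quality control: real artefacts vary in appearance and severity, and real
"good" images contain anatomy the phantom lacks.  Two consequences follow.
First, passing classifiers here demonstrates that the pipeline learns
k-space corruption signatures end to end, not that it would reach the same
accuracy on clinical data.  Second, the curriculum benchmark saturates —
most seeds reach AUC 1.0 under every stage ordering — so the ordering
comparison has little dynamic range at this scale, and the mean AUCs of the
three orderings typically agree to within the benchmark's resolution
(a single swapped test pair moves one run's AUC by ~0.004).  The
curriculum-versus-baseline ordering should therefore be read as a mechanism
check of Algorithm-style staged training, not as evidence about its benefit
on real data.

Other known limitations: corruption operates on magnitude-image spectra
(true complex raw data is not modelled); breathing translations are 1D along
the phase encode axis; arrhythmia and mixed artefacts are not simulated;
the localiser assumes one beating structure per image.
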
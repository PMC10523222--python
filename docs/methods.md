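# Methods

## Problem setting

A single squat repetition, captured by a frontal camera at a nominal
30 fps and reduced to per-frame 2D keypoints by a pose estimator, is to be
classified as showing correct or incorrect form. The package covers the
whole chain from keypoint JSON to a pass/fail verdict and a 0–10 session
score, plus a kinematic simulator that generates labeled training data.

## Keypoint handling

Input is OpenPose-style BODY_25 output (one JSON per frame, or a single
stream document). Ten landmarks are retained — neck, mid-hip, left/right
shoulder, hip, knee, ankle — giving 20 coordinate channels. Arms, head and
feet are dropped: their configuration varies freely without bearing on
squat correctness, and removing them reduces input dimensionality and
estimator-noise exposure.

Coordinates stay in image convention (origin top-left, y downward)
throughout. A confidence of 0, or the OpenPose all-zeros triple, marks a
joint as missing. Missing joints are filled by linear interpolation in time
(nearest-value fill at clip edges); if a required joint is missing in more
than 20% of frames the clip is rejected rather than repaired, since beyond
that level interpolation fabricates motion. The interpolation policy and
the 20% tolerance are choices of this package — pose-estimator dropout
handling admits no single standard.

## Normalization

A reference frame is chosen from the first `ref_window` frames (default 30,
about one second): the frame maximizing the projected mid-hip→neck
distance, ties to the earliest. Standing upright in front of a level camera
maximizes that projection, so the argmax is a robust proxy for "upright"
without needing angle estimates. The transform that maps the reference
mid-hip to (0, 0) and the torso length to 1 — a translation followed by an
isotropic scaling, no rotation — is applied to every frame.

Rotation is deliberately excluded from the transform family: aligning the
torso to an axis would erase lean defects that the classifier must see. A
consequence asserted by the test suite: the feature tensor is invariant to
global translation and uniform scaling of the raw pixels but *changes*
under a 90° rotation of the input.

## Smoothing and features

Each joint's x- and y-series is convolved with a normalized discrete
Gaussian (σ = 1 frame by default), truncated at radius ⌈4σ⌉ and
renormalized, with reflected boundaries. Because the normalization is
affine and the filter linear, smoothing and normalization commute; the
pipeline normalizes first, then smooths. Finally per-frame differences are
taken: a k-frame clip yields a (k−1) × 20 tensor in the fixed channel order
[neck, mid-hip, L/R shoulder, L/R hip, L/R knee, L/R ankle] × (x, y). The
channel order travels with model checkpoints, which refuse to load against
a mismatched order. A motionless clip produces an exactly zero tensor.

## Classifier

The full variant is three temporal 1D convolutions (kernel depths 5, 3, 3;
filters 32, 64, 64; valid padding, stride 1, ReLU), a bidirectional LSTM
with 64 total outputs, a 32-unit ReLU fully connected layer, and a 2-class
softmax. "64 outputs" for the BiLSTM is read as total output
dimensionality: 32 hidden units per direction, final states concatenated.
The FC layer consumes that concatenation. Dropout 0.3 follows each
convolution and the FC layer, active only during training. Training
minimizes softmax cross-entropy with Adam at learning rate 0.003
(β₁ = 0.9, β₂ = 0.999), batch size 32, up to 100 epochs, early-stopped when
validation accuracy has not improved for 10 epochs, with best-validation
weights restored.

Variants: `conv_only` replaces the LSTM with a mean-pool over time;
`lstm_only` feeds the 20 raw channels straight into the BiLSTM. With valid
padding the conv stack consumes 8 time steps, so the full and `conv_only`
variants need at least 9 feature rows (10 frames); `same` padding is
available by configuration and removes the floor.

The network and its backpropagation are written directly in numpy.
Variable-length clips are handled by accumulating gradients over the
sequences of a minibatch one at a time — mathematically identical to
zero-padded batching with a length mask, with no masking bookkeeping.
Initialization is Glorot-uniform with an LSTM forget-gate bias of 1; all
randomness (weights, dropout masks, shuffling) flows through seeded numpy
generators, so training is bit-reproducible given the config seed.

A grid-search helper exhaustively trains every hyperparameter combination
against a fixed validation split and returns the configuration with the
highest validation accuracy together with the full result table.

## Evaluation protocol

Metrics are computed from the 2×2 confusion matrix with *correct posture*
as the positive class: accuracy (TP+TN)/total, precision TP/(TP+FP), recall
TP/(TP+FN). Datasets are split **by subject** (GroupShuffleSplit on
synthetic subject ids, 50/25/25): clips from one subject never span splits,
so reported test accuracy measures generalization to unseen bodies rather
than memorization of a subject's geometry. A variant × train/val/test
accuracy grid can be rendered for model comparisons.

## Simulator

A planar two-leg + torso linkage viewed frontally. The knee-flexion angle
θ follows a cosine-eased profile per repetition, 0° at the ends and
`depth_deg` at mid-rep. In frontal projection, sagittal motion appears as
vertical foreshortening: the knee sits shank·cos(θ/2) above the ankle and
the hip thigh·cos(θ/2) above the knee; forward lean shortens the projected
torso by cos(lean). Gaussian jitter of SD `noise_px` emulates
pose-estimator noise; optional random dropout emulates missing detections.

Defaults describe a typical adult at a typical camera distance: torso 160,
thigh 130, shank 120, shoulder width 110, hip width 80 px; depth 95°; 2 s
per repetition at 30 fps; 1 px jitter. Dataset generation assigns clips to
synthetic subjects, each with its own segment lengths (±10%), tempo (±20%)
and global image position/scale, shared across that subject's clips; peak
depth additionally jitters ±5° per clip.

Defect modes and the fixed label thresholds (package conventions, chosen so
labels are reproducible):

| defect         | geometric effect                              | incorrect when        |
|----------------|-----------------------------------------------|-----------------------|
| shallow_depth  | achieved depth = depth_deg − magnitude (deg)  | achieved < 70°        |
| knee_valgus    | knees shift medially ∝ flexion, peak = magnitude × hip width | magnitude > 0.15 |
| forward_lean   | torso foreshortened by cos(magnitude°) ∝ flexion | magnitude > 20°   |
| asymmetric     | left/right flexion split ± magnitude/2 (deg)  | magnitude > 15°       |

What the simulator does **not** emulate: correlated estimator noise (real
OpenPose errors are bursty and joint-correlated, not i.i.d. Gaussian),
out-of-plane limb motion beyond torso foreshortening, heel rise, partial
occlusion, clothing-driven landmark drift, and the continuum of real human
form errors. Passing tests on simulated data therefore demonstrate that
the pipeline, model and training machinery are correct and can recover a
known, well-separated class structure — not that the reported accuracies
transfer to real video.

## Numerical choices

- Gaussian kernel radius ⌈4σ⌉, renormalized; reflect boundaries.
- Normalization invariance asserted at ≤1e-9 relative tolerance; the
  delta-tensor telescoping identity at ≤1e-12.
- Sigmoid arguments clipped at ±60 to avoid overflow; cross-entropy floors
  probabilities at 1e-300.
- Grid-search and early-stopping ties break to the earlier candidate/epoch.
- Degenerate inputs fail loudly: empty sequences, zero torso length at the
  reference, single-class training sets, and clips shorter than the
  variant's temporal minimum each raise a typed error.

## Problem sizes

The shipped experiments use 100 clips per class (about 60 frames each, one
repetition per clip) over 20 synthetic subjects, which trains the full
variant in well under a minute on one CPU; the separation experiment
repeats training across three seeds. These sizes were chosen as the
smallest at which subject-wise splitting is meaningful and accuracy
estimates on the test split (n = 50) are stable.

## Known limitations

- Binary verdicts only; no localization of *which* body part failed.
- Single person, frontal view; no 3D reasoning or camera calibration.
- The simulator's defect taxonomy is a stylized subset of real form errors.
- The numpy network trains on CPU at small scale; it is not a framework.
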
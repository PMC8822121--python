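# Methods

This note documents the models, parameters and design choices behind
`gazegrasp`, and what the synthetic experiments do and do not show.

## Pipeline model

The control loop treats the sEMG classifier as both intent detector
and grasp classifier. A posterior over 11 classes (ten grasps + rest)
is emitted every 20 samples of the 1926 Hz sEMG stream, each time
classifying the trailing 200-sample window (causal: the window ends at
the emission instant, as required for online control). A grasp-intent
event is the first non-rest argmax following a rest step (or the
stream start — analysis windows may clip the rest lead-in). On intent,
the target object is the most recent looked-at object in the preceding
480 samples (~250 ms, counted on the sEMG sample clock); if none, the
search continues forward up to 500 ms (49 classification steps of 20
samples; gaze hits are only accepted up to the 500 ms bound even
though the step grid overshoots it by 17 samples). With an identified
object, the emitted grasp is the posterior argmax restricted to the
grasp types paired with that object; without one, the unimodal argmax.
Any rest-classified step emits rest and resets the machine (a debounce
parameter exists but defaults to a single sample).

Two structural consequences are asserted deterministically in the test
suite: restriction can never demote a correct unimodal decision when
the object is identified correctly (the true grasp is always in the
paired set, by construction of the protocol), and an identified object
whose paired set excludes the true grasp forces every fused non-rest
decision to be wrong.

## Classifier

Architecture: ConvLSTM (128 filters, 1×3 kernel) → dropout 0.5 →
flatten → dense 200 (ReLU) → dense 50 (ReLU) → dropout 0.2 → dense
11 (softmax). Input windows are reshaped to 10 subsequences of
1×20×12; the "1" axis is a spatial height of one, so the 1×3 kernel
convolves along the 20-column (time-within-subsequence) axis with the
electrode axis as channels. The convolution uses valid padding on the
input transform (width 20 → 18) and same padding on the recurrent
transform, mirroring the usual ConvLSTM layer semantics.

Training: class-weighted categorical cross-entropy (balanced inverse
frequency, w_c = N / (K·n_c), countering the predominance of rest),
Adam with default parameters (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7),
150 epochs of shuffled batches of 32 by default, no early stopping and
no schedule; the parameter snapshot with the highest validation
accuracy is kept. Validation accuracy is computed per window.

The network is implemented directly in NumPy (im2col convolutions,
backpropagation through time, inverted dropout); gradients are
verified against central finite differences in the test suite, and
streaming inference is verified identical to batch inference on the
extracted windows. Initialization is Glorot-uniform for both the
input and recurrent kernels with a forget-gate bias of 1 (a common
alternative is an orthogonal recurrent initializer; Glorot behaves
equivalently at these widths and keeps the implementation small).
All randomness (init, shuffling, dropout) derives from explicit seeds,
so equal seeds give bit-identical models.

## Preprocessing

Per-channel standardization (mean/sd fit on training repetitions only,
pooled over samples) followed by rectification, |(x−μ)/σ|; then
non-overlapping 200-sample windows, trailing remainder dropped. There
is deliberately no filtering or feature extraction. The label of a
mixed rest/grasp window is the majority label, ties broken toward
rest — conservative for intent detection, since a spurious grasp label
triggers the fusion machinery. The same rule defines the ground-truth
label of each streaming step (majority of the trailing window), so
training and streaming evaluation use one labelling convention.

## Protocol encoding

10 grasps × 3 paired objects; 12 static-seated + 12 static-standing
repetitions per grasp (4 per object) and 8 dynamic repetitions on two
of the three objects — 320 rest-grasp-rest segments per subject. Fold
assignment is round-robin on the repetition index within each (grasp,
condition, object) cell, giving each of the 4 folds 3 seated + 3
standing + 2 dynamic repetitions per grasp on distinct objects. Which
two objects serve the dynamic condition is not dictated by the
pairing table; the first two in table order are used, deterministically.
The validation split draws one repetition per (condition × grasp) cell
from the 3-fold training pool (240 → 210 train + 30 validation),
seeded.

## Synthetic recordings

The generator reproduces the *structure* the pipeline depends on, not
sEMG physiology or scene appearance:

- **sEMG**: rest is zero-mean Gaussian noise (sd 0.25 by default);
  a grasp adds a per-grasp nonnegative 12-channel signature (three
  active electrodes with amplitudes 1.0/0.8/0.6, offset per grasp)
  under a raised-cosine envelope with 0.1 s ramps. Rest durations are
  uniform on [1, 3] s (the 1 s minimum is protocol; the 3 s maximum is
  a choice), grasp durations uniform on [1.5, 2.5] s. The amputee
  population differs only by a 1.5× noise multiplier — a variability
  stand-in with no claim of physiological realism.
- **Scenes**: a 1920×1080 px frame (origin top-left, y down) holding
  the target plus ≥ 4 distractors as simple star-shaped polygons of
  8–16 vertices, pairwise separated by ≥ 50 px (rejection sampling
  with bounded retries), occasionally a person instance.
- **Gaze** (100 Hz): fixates a point inside the target contour from
  1 s before the onset until 0.25 s after it (static) or until a
  0.3 s post-onset shift away (dynamic, emulating the gaze moving on
  to the next action step); wanders across distractors otherwise;
  4 px jitter; 2% invalid samples.
- **Detections** (25 FPS): per frame, each scene object is missed
  with probability 0.05, its score drawn from N(0.93, 0.05) clipped to
  [0, 1] (so a small fraction falls below the 0.8 filter), contour
  vertices jittered by 1 px; spurious instances appear with
  probability 0.02. Frames are stored only within each trial's
  analysis window (2 s before to 3.5 s after the onset) clipped to the
  trial's own segment, so neighbouring trials' scenes never coexist;
  this mirrors storing contours only where the multimodal analysis
  reads them.

Because the signatures are separable by design, the trained classifier
approaches ceiling accuracy; passing tests therefore demonstrate the
*contracts* of the pipeline (alignment, causality, restriction,
reset, no train/test leakage), not realistic sEMG difficulty. In
particular the multimodal step-accuracy gain at default noise is ≈ 0 —
there are almost no unimodal errors left to fix — so the benefit of
fusion is demonstrated by construction: deterministic scenarios in
which unimodal errors fall outside the identified object's paired set
show the guaranteed correction, and adversarial identifications show
the guaranteed failure. Real recordings, with far noisier sEMG, are
where the restriction yields its double-digit gains.

## Gaze-object association

Score threshold 0.8 is inclusive ("lower than 0.8" is discarded);
the 20 px rule is strict (<). Distance is Euclidean to the contour,
with points inside the polygon at distance 0 (being on the object is
the strongest looking-at evidence); a `boundary_only` flag measures to
the contour polyline instead. Geometry uses shapely; a dense
boundary-sampling brute force bounds the error at ≤ 0.5 px in tests.
Each gaze sample maps to the last started video frame
(floor(t·25 FPS)); ties between equidistant instances break to the
lower instance index. A timeline entry requires both a valid gaze
estimate and at least one accepted non-person/background instance.

## Evaluation and statistics

Accuracy counts every classification step in the analysis window,
rest included, over all 11 classes; the analysis window is clipped to
the trial's segment so neighbouring trials do not leak in. Fold
accuracies are averaged as per-fold percentages. The
object-identification rate scores, per subject and condition (seated
and standing merged as static), whether the object recognized at the
beginning of the grasp equals the target; "at the beginning of the
grasp" is read as the intent event of the first non-rest episode that
reaches the ground-truth onset — the machine resets at every rest
sample, so a false-alarm episode that dies out before the onset
carries no identification into the grasp. Missing identifications
count as incorrect.

Approach comparisons use the one-sided Wilcoxon signed-rank test
(alternative: multimodal better), group comparisons the two-sided
Mann-Whitney test, both on per-subject averages. Zero differences are
dropped (the common convention; ≥ 5 non-zero pairs required); the
exact null is used up to n = 25 without tied ranks, otherwise the
normal approximation with continuity/tie correction. Effect sizes are
the magnitudes of the matched rank-biserial correlation
(W⁺−W⁻)/(W⁺+W⁻) and the rank-biserial correlation 1 − 2U/(n₁n₂).
p-values are computed via scipy and verified against exhaustive
sign-flip / group-labeling enumeration for small n in the tests.

## Problem sizes used in tests and the acceptance script

Structural counts run on a full-protocol synthetic subject (320
segments). End-to-end runs use the miniature protocol — two grasps
(medium wrap, tripod grasp) sharing two of four objects, 64 segments —
with a 16-filter ConvLSTM trained for 8 epochs (8 filters / 2-3 epochs
for smoke tests), which reaches > 95% held-out window accuracy on the
separable signatures; these sizes are the package's choice for a
desk-scale demonstration, and every quantity scales with the config.

## Known limitations

- The sEMG model is additive and stationary; no electrode shift,
  fatigue, force variation or crosstalk, which are the phenomena that
  actually limit myoelectric control.
- The dynamic condition models only a post-onset gaze shift, not
  object-manipulation kinematics.
- Validation accuracy is per window; whether per-repetition selection
  would choose different snapshots is untested.
- Pre-identification steps of an episode are not re-labelled once the
  object is found (forward-causal), which an offline analysis could
  choose to do differently.
- The real-data adapter is a documented stub; nothing here validates
  against real recordings.
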
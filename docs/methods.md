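# Methods

## The task

Clinical movement exams for Parkinson's disease (PD) score repetitive
limb movements — finger tapping (FT), hand movements (HM),
pronation–supination (PS), toe tapping (TT), leg agility (LA) — on
the MDS-UPDRS 0–4 severity scale. `motorgrade` implements the binary
version of this grading (low = 0/1 vs high = 3/4; severity 2 is
excluded) from two tri-axial accelerometers sampled at 80 Hz, and the
surrounding methodology: masked self-supervised pre-training,
transfer-initialized supervised classification, max-vote inference,
noise-robustness probing, and CKA-based representation comparison.

## Synthetic cohort model

Real recordings of this kind are not bundled with the package; a
generative stand-in reproduces the statistical structure the analysis
depends on. Per recording, the movement signal is

    s(t) = A·exp(−δ·t)·cos(2π f₀ t + φ(t))·g(t) + A_tr·sin(2π f_tr t + ϑ)

- `A` — movement amplitude (g-units); decreases with severity
  (anchors: 0.70 g at severity 0, 0.15 g at severity 4).
- `δ` — exponential amplitude decrement (the bradykinesia "sequence
  effect"), 0 → 0.08 s⁻¹ across severity.
- `φ(t)` — phase jitter, a Gaussian random walk with rate
  0.05 → 0.45 rad/√s (movement regularity degrades with severity).
- `g(t)` — hesitation gate: pauses arrive as a Poisson process
  (0 → 0.25 events/s), each a cosine-tapered dip to zero lasting
  0.3–1.0 s. The taper keeps the signal smooth so jerk stays bounded.
- `A_tr`, `f_tr` — rest-tremor sinusoid, amplitude 0 → 0.30 g,
  frequency uniform in 4–6 Hz. Severity 0 has exactly zero tremor and
  zero hesitations.
- `f₀` — task-specific repetition rate (FT 3 Hz, HM 2.5, PS 2.0,
  TT 2.5, LA 2.0 Hz), jittered ±8 % per recording.

Severity maps to parameters by linear interpolation between the
severity-0 and severity-4 anchors, multiplied by per-recording
log-normal heterogeneity (σ = 0.15). All draws happen in a fixed
order, so identically seeded generators yield parameter sets that
preserve the severity ordering — a property the tests assert.

Each sensor k ∈ {1, 2} reads

    a_k(t) = ĝ + γ_k · s(t) · u_k + ε_k(t)

with a static unit gravity vector `ĝ`, a unit axis direction `u_k`
(near vertical, randomly tilted), a gain γ₁ = 1, γ₂ ~ U(0.8, 1),
and i.i.d. Gaussian noise ε (sd 0.02 g per axis). The two sensors
share the movement phase, differing only in gain, axis and noise.

**Why the gravity offset.** A real accelerometer measures gravity
plus motion, and the offset matters for the pipeline's first step:
the resultant of a zero-mean oscillation is rectified (|cos| has its
fundamental at 2f₀), whereas the resultant of `ĝ + s·u` carries the
movement linearly, so spectral structure (including the 4–6 Hz tremor
band) survives at its true frequency. The generator therefore
includes the offset by default; setting `gravity=(0,0,0)` recovers a
pure-motion signal.

Cohort shape defaults emulate a small clinical study: 20 PD + 8 HOA
participants, one session each plus a retest with probability 0.68,
one 20-s recording per task per session, PD severity drawn per
recording from (0.20, 0.30, 0.20, 0.20, 0.10) over grades 0–4. The
20-s default duration yields 15 overlapping 5-s windows per recording
so max-vote inference aggregates a meaningful number of votes. One
severity label is emitted per recording (not per body side); this is
an explicit simplifying assumption.

What the generator does **not** emulate: biomechanical limb dynamics,
medication state, sensor drift/saturation, inter-task correlation
within a participant, and the label noise of human raters.
Consequently, green end-to-end tests show the pipeline recovers the
generative severity signal under controlled conditions — not that it
attains any particular accuracy on real patients.

## Preprocessing

Resultant `A_ij = √(ax² + ay² + az²)` per sensor and time step
(orientation-invariant; tested under random 3-D rotations); jerk as
the forward difference scaled by the sampling rate (the scaling is
physically interpretable but irrelevant after standardization);
sliding 1-s RMS with stride 1 (a block-wise variant is available via
`rms_stride=80`); overlapping 400-sample windows with stride 80
(1 s, i.e. 80 % overlap — configurable); per-channel z-scoring within
each window, with an ε = 1e-8 guard mapping constant channels to
zeros. Recordings shorter than one window are skipped with a logged
warning rather than aborting a cohort. The model input is the
two-channel per-sensor RMS-of-jerk-of-resultant; this is the minimal
channel set consistent with a two-sensor montage.

Note that per-window standardization removes absolute amplitude, so
classification rests on waveform shape: tremor content, hesitation
dips, decrement trend and regularity.

## Splitting

Groups (recordings) are the splitting unit. Stratified K-fold over
PD group labels delegates to scikit-learn's `StratifiedKFold` after a
feasibility pre-check that names the deficient class; fold i is the
test set and the remaining groups are split 70–30 (round-half-up,
remainder to training, unstratified) into train/validation. HOA
groups are split 80–20 and never appear in any test set. A leakage
tripwire re-checks segment-level disjointness at construction.
Test/retest sessions of one participant may land in different folds
(recording-level grouping); participant-level grouping would be
stricter but is not the default.

## Network and training

The backbone stacks `n_modules` inception-style modules: a pointwise
bottleneck to f channels, three depthwise-separable convolutions at
kernel scales {k, k/2, k/4} (k = 39 by default; even sizes are bumped
to odd), and a maxpool→pointwise branch, concatenated to 4f channels.
After every second module a residual shortcut (pointwise conv + batch
norm on the block input) is added and ReLU-activated. Channel width
doubles per module; the default width is f = 8 (the width is not a
published constant, and this keeps CPU training practical — all
experiments here run on modest desk-scale budgets). The
classification head is adaptive average pooling to 50 steps, two
BN+ReLU pointwise convolutions halving channels twice, a final
1-channel pointwise convolution and global average pooling to a
single logit. The reconstruction head is a length-preserving
two-layer pointwise stack back to the input channels; only backbone
weights transfer, so any length-preserving head is admissible.

Everything runs on a small reverse-mode autodiff engine written on
NumPy/SciPy (`motorgrade.nn`): pointwise convolutions are BLAS
matmuls, depthwise convolutions FFT-based correlations, and the whole
graph is float64. Analytic gradients are verified against central
finite differences across every parameter tensor in the tests.
Optimization is Adam under a one-cycle schedule (cosine warm-up to
the maximum learning rate over the first quarter of steps, cosine
anneal after), matching the "maximum learning rate" convention of the
training regimes implemented here: 200 pre-training epochs and 50
supervised epochs at max LR 1e-3 at full scale (tests and the CLI's
`--epochs-scale` run reduced budgets), batch size 64 by default.

Masking draws alternating geometric run lengths on {1, 2, …} with
success probabilities 1/lm and 1/lu (lu = lm(1−r)/r, so r = 0.15 and
lm = 3 give lu = 17 exactly); the first run is masked with
probability r; masks are drawn independently per channel and
resampled every epoch (both behaviors have flags). The loss averages
squared error over masked positions only — perturbing unmasked
predictions provably leaves it unchanged. Model selection keeps the
best-validation checkpoint (masked MSE for pre-training, BCE for
classification); no early stopping, no class reweighting.

FTL optimizes head parameters only for 10 epochs (backbone parameter
freeze is asserted by hashing; batch-norm *running statistics* in the
backbone do update during this phase, as they are buffers rather than
parameters), then all parameters for 50 epochs. FTA optimizes all
parameters for 50 epochs directly. Random-init models train 50
epochs with no scheme.

## Inference, metrics, noise

Segment probability ≥ 0.5 maps to "high" (boundary inclusive, by
convention). Max-vote takes the per-recording mode of segment labels;
ties (possible with even vote counts) break by mean p_high vs 0.5.
Accuracy and F1 (positive class "high", zero when undefined) come
from scikit-learn and are cross-checked in tests against a
confusion-matrix oracle. Noise robustness re-evaluates test sets
with i.i.d. N(0, 0.05²) added to the standardized windows — σ is
thus a fraction of unit channel variance; no monotone degradation is
asserted, since noise can help as well as hurt. Attribute aggregates
pool all matching model × fold results (rather than averaging
fold-means) and report mean ± sd.

## CKA

Linear CKA uses the feature-space ‖YᵀX‖ form (columns centered),
algebraically identical to the centered-Gram HSIC form but cheaper
for d ≪ n; the tests verify the identity to 1e-10, plus
self-similarity, exact symmetry (the implementation canonicalizes
argument order so the two evaluation orders are bitwise equal),
orthogonal/scale invariance and a shear negative control. Probe data
are each fold's PD test segments (never seen in training by the
compared models); representations are mean-pooled over time at the
first and last backbone modules; FTL models are excluded so each
initialization contributes equally; pairs are formed across attribute
groups within a fold only, and self-pairs are excluded by default.

## Orchestration and reproducibility

The pipeline is staged (simulate → preprocess → split → pretrain →
train → evaluate → cka); each stage writes its artifacts plus a
manifest entry (config hash, derived seed) and re-runs
deterministically. A single global seed fans out to per-stage seeds
by fixed offsets so stages can be re-run independently. All
randomness flows through explicitly seeded NumPy generators; training
is single-threaded deterministic.

## Problem sizes used in the checks

The packaged checks run at desk scale by design: mask statistics use
10,000 masks of 4,000 steps; pre-training efficacy uses a ~160-segment
single-task cohort, a 2-module width-2 model and 5 epochs; the
end-to-end severity-recovery check uses 40 PD + 8 HOA recordings of
one task with severities restricted to {0, 1, 3, 4}, K = 2 folds, a
width-6 3-module model, 5 pre-training and 10 supervised epochs.
These sizes are the package's own reduced defaults for fast,
deterministic verification; the full-scale regime (K = 5, 200/50
epochs, all five tasks plus the task-pooled aggregate mode) is
available through the same APIs and CLI.

## Known limitations

- The synthetic severity signal is far cleaner than clinical data;
  absolute accuracies on it say nothing about clinical performance.
- Binary grading only; no ordinal 0–4 output, no per-side labels,
  no rigidity assessment.
- No resampling support for non-80 Hz input and no filtering beyond
  the stated chain.
- CPU-bound NumPy training: practical for the reduced budgets above,
  slow at very large widths or cohort sizes.
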
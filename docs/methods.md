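# Methods

This note documents the models, algorithms and design decisions behind
`dancehar`, the assumptions they make, and what the synthetic-data
experiments do and do not demonstrate.

## Data model

A recording session is one dancer wearing six 9-channel IMUs (triaxial
accelerometer, g; gyroscope, deg/s; magnetometer, µT) at 100 Hz on the
thoracic spine, sacrum and both thighs and shins. The six locations
have a fixed canonical order (thoracic, sacrum, left thigh, right
thigh, left shin, right shin) so that channel stacking — and therefore
the classifier's input geometry — is deterministic. Frames are 0-based;
all intervals are half-open; streams must be gap-free at exactly 10 ms
spacing (a gap is a read error, never silently filled). Physical,
calibrated units are assumed throughout.

Activity labels live in a three-level taxonomy: movement family (jump /
leg lift), jump type (bilateral-landing small jump, unilateral-landing
small jump, leap) or lift direction (front / side / back), and
laterality. Level-3 classes are flattened two-part names
(`leap_right`, `front_left`, …), giving class-set sizes 2, 6 and 11
excluding `other`. Frames not covered by an annotation are implicitly
`other` (transition movement). Windows are labelled once at level 3 by
the majority-frame rule (ties break toward non-`other`, then
lexicographically) and coarsened to levels 2 and 1, which guarantees
cross-level consistency; whether real annotation pipelines use
majority, centre-frame or any-overlap labelling is an open convention,
and majority was chosen as the most common and fully deterministic
rule.

## Synchronization

Each recording begins with 5 s stillness, a double-leg heel raise, and
5 s stillness. The detector works on the smoothed acceleration
magnitude (0.15 s moving average — the stillness criterion describes
residual *motion*, which sits well below the raw noise floor of a
100 Hz MEMS accelerometer): stillness is a rolling standard deviation
(0.25 s window) below `still_threshold` (default 0.02 g) with magnitude
within 3× the threshold of 1 g, sustained for `still_min_duration`
(default 4 s, tolerating protocol imprecision against the nominal 5 s);
momentary excursions shorter than 0.5 s do not end a stillness period.
The sync event is the earliest magnitude-deviation peak bracketed by
two qualifying stillness periods, refined to the midpoint of the
half-height support so that a flat-topped transient localizes to ±1–3
frames under noise. Alignment shifts each stream by an integer frame
count so its event lands on the heel-raise frame recorded in the
annotation file (a dedicated `sync` row), then crops all streams to the
common extent. Sub-sample alignment is deliberately not attempted:
10 ms granularity is two orders of magnitude below the 1-s analysis
window. Clock drift over a session is not modelled.

## The classifier

Input is a (9·L) × 100 matrix: L location blocks of 9 channels, 100
frames. The architecture is fixed:

1. convolution, filters 9 channels × 25 frames, vertical stride 9 —
   one filter application per location block, so features are learned
   per sensor location (L vertical positions, 76 time positions);
2. ReLU; convolution over each location's feature stack, 10 frames
   wide (67 time positions); ReLU;
3. global max pooling over time per (location, filter);
4. dense layer (default 128 units), ReLU, inverted dropout (default
   0.5); softmax output.

Channel extents or strides other than 9 would let filters straddle
location blocks and are rejected; non-default filter time extents are
accepted but flagged. Convolutions are valid-mode (no padding). Default
training: Adam (learning rate 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-8), 30
epochs, batch 64, He initialization. One independent model is trained
per classification level; class imbalance is handled by
inverse-frequency class weights when transition windows are included
(they dominate the timeline). The whole network is implemented in
numpy with explicit forward/backward passes (verified against central
finite differences in the test suite); all randomness flows from a
single integer seed through `numpy.random.Generator`, so
build + train + predict is bit-reproducible on one device.

Per-channel z-scoring statistics are always computed on the training
fold only and reused for the test fold; a numerically zero-variance
channel has its scale clamped to 1 with a warning.

## Evaluation

Leave-one-participant-out cross-validation: the held-out dancer
contributes nothing to training data or normalization statistics.
Accuracy is trace/total of the confusion matrix — the multiclass form
of (TP+TN)/total — and cohort results are unweighted per-participant
means (not pooled over windows), so a dancer with a long session does
not dominate. With transition windows included, `other` is a scored
class at every level; without, `other` windows are removed from both
training and test sets. Folds with no test windows are reported and
skipped, never silently dropped. The sensor ablation evaluates all
C(6,k) subsets for k = 1…6 (63 total) per transitions variant; sessions
are segmented once with all six locations and each subset is a
row-restriction of the same windows, so subset differences are
attributable to sensors alone. Overlapping windows are kept in test
folds; they are correlated items and absolute accuracies should be read
with that caveat.

## Synthetic data generator

The generator emulates the data-collection protocol, not human
physiology: signal templates are parametric (half-sine impacts,
trapezoidal angular-velocity profiles), with just enough structure to
make every label distinction learnable from the signals.

* **Jumps** — takeoff push, flight-phase free-fall dip, and a half-sine
  landing impact on the vertical accelerometer axis of the lower-limb
  sensors and sacrum (attenuated at the thorax). Small jumps peak at
  3 g, leaps at 5 g (× effect_scale × a per-participant factor). Leaps
  additionally have a longer flight phase and a horizontal travel surge
  on the trunk sensors; unilateral landings add an impact-roll
  gyroscope transient absent in bilateral landings.
* **Leg lifts** — a sustained trapezoidal angular-velocity profile on
  the lifted-side thigh and shin (120 deg/s nominal), with the
  gyroscope axis mixture encoding front/side/back, plus a gravity-tilt
  accelerometer change.
* **Cue salience decreases with taxonomy depth by design**: the
  family-level contrast (impact vs sustained rotation) is strongest;
  type-level contrasts are encoded by robust shape cues; laterality is
  carried only by graded side asymmetries with per-event jitter
  (contralateral impact weight, stance-limb co-activation between 20
  and 80 % of the lifted limb). This mirrors the difficulty gradient of
  the real task, where finer distinctions are subtler and have fewer
  examples per class.
* **Transition movement** — band-limited low-amplitude motion on all
  sensors in the gaps between tasks (fraction of the timeline set by
  `transition_fraction`, default 0.4).
* **Magnetometer** — a slowly drifting baseline plus a weak
  (0.02×) orientation-correlated echo of the gyroscope, so it carries
  only faint class information, mirroring the ambiguity of sensor-type
  contributions in practice.
* **Prelude** — stillness / 1-s heel raise (0.5 g, similar on all
  sensors) / stillness, with independent per-sensor clock offsets of
  0–2 s so the synchronization stage is genuinely exercised. Truth
  annotations use post-alignment frame indices.

Defaults: 23 participants (any number allowed), accelerometer noise
0.05 g (gyro and magnetometer noise are fixed multiples: 20 deg/s and
10 µT per g, so one knob controls SNR), participant variability 0.15
(perturbing template amplitude and timing), seed 42. The default task
script mirrors a condensed ballet class covering every level-3 class:
3 slow lifts per direction per side (~1.5 s each), 8 bilateral small
jumps, 8 unilateral small jumps split over both landing legs, and 2
leaps per landing leg — a deliberately compact session (~80 s) rather
than a 45-minute class, so that full leave-one-participant-out
experiments run on a single CPU in minutes.

What passing tests on this data shows: the pipeline's plumbing is
correct end-to-end (alignment, labelling, no leakage, geometry), the
classification task is well-posed (a hand-coded threshold rule already
separates the families), and the classifier recovers the planted
structure with the qualitative orderings expected of the hierarchy
(coarse ≥ fine; excluding transitions ≥ including them). What it does
not show: absolute accuracies on real dancers — real signals have
orientation drift, soft-tissue artefact, inter-dancer technique
differences and annotation noise that the templates do not model.

## Problem sizes and numerical choices

Evaluation runs in the acceptance script and test suite use a
reduced-width model (8/16 convolution filters, 64 dense units, 8
epochs, learning rate 2e-3, no dropout change) and an 8-participant
cohort; at these sizes a full six-sensor, three-level LOOCV takes a few
minutes on one CPU while leaving the canonical architecture defaults
untouched. The exhaustive 63-subset ablation is demonstrated at further
reduced scale (3 participants, shortened script, level 1,
non-overlapping windows). Stage seeds are derived from a single global
seed by CRC-32 hashing of stage names, keeping stages independently
reproducible. Argmax ties in prediction resolve to the lowest class
index; majority-label ties resolve non-`other`-first then
lexicographically; empty training sets, unknown labels, geometry
mismatches and out-of-range intervals raise immediately with the
offending quantity named.

## Known limitations

* Real raw-export dialects (e.g. proprietary binary formats) are not
  parsed; data must be in the documented CSV dialect.
* Only 100 Hz input is supported; no resampling.
* The ablation trains 63 × folds × levels models per variant; at
  canonical model width this is a long computation — the package keeps
  it feasible via the reduced-width configuration rather than
  distributed execution.
* Event-level counting (how many jumps?) is out of scope; the unit of
  prediction is the 1-s window.
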
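# dancehar

Human activity recognition for ballet training-load monitoring from
body-worn inertial sensors.

Dancers' musculoskeletal pain is linked to training volume, but no
tooling exists to count *which* movements a dancer performs during
training. `dancehar` implements a full pipeline that turns raw
multi-sensor IMU recordings into per-second activity labels for the two
movement families that dominate lower-limb load in classical ballet —
jumps and leg lifts — at three nested levels of detail:

| level | question | classes (plus `other`) |
|---|---|---|
| 1 | jump or leg lift? | 2 |
| 2 | jump type / lift direction | 6 |
| 3 | laterality (landing or lifted leg) | 11 |

The instrumentation model is six 9-channel IMUs (triaxial accelerometer
in g, gyroscope in deg/s, magnetometer in µT, 100 Hz) worn on the
thoracic spine, sacrum, and both thighs and shins.

## What the package does

1. **I/O** — a documented CSV dialect for date-time-stamped raw sensor
   exports and frame-level annotation files (`dancehar.io`).
2. **Synchronization** — each recording starts with 5 s stillness, a
   double-leg heel raise, and 5 s stillness; the stillness-bracketed
   magnitude transient is detected on every stream and used to align
   all six to the annotation timeline at 10 ms granularity
   (`dancehar.sync`).
3. **Segmentation** — aligned sessions are cut into 1-s windows
   (100 frames) with 0/25/50/75 % overlap; each window is labelled at
   level 3 by the majority-frame rule and coarsened, so labels are
   consistent across levels (`dancehar.segmentation`).
4. **Classification** — a convolutional network whose layer-1 filters
   are 9 channels × 25 frames applied at a vertical stride of 9, so
   each filter reads exactly one sensor location's
   accelerometer + gyroscope + magnetometer block at a time; layer-2
   filters (10 frames) operate per location, followed by global max
   pooling over time, a dense layer and a softmax. Training uses Adam
   on (optionally class-weighted) cross-entropy. The network is
   implemented in numpy with explicit forward/backward passes, which
   makes every run bit-reproducible on one device (`dancehar.model`,
   `dancehar.nn`).
5. **Evaluation** — leave-one-participant-out cross-validation;
   per-participant confusion matrices averaged unweighted across the
   cohort; accuracy = trace/total. Exhaustive sensor ablation evaluates
   all 63 non-empty location subsets on identical windows
   (`dancehar.evaluation`).
6. **Synthetic data** — the dancer dataset the protocol describes is
   not publicly deposited, so `dancehar.synth` generates seeded,
   annotated sessions: a heel-raise prelude with per-sensor clock
   offsets, scripted jumping/leg-lifting tasks built from parametric
   signal templates, and unlabelled transition movement between tasks.

## Worked example

```bash
python examples/quickstart.py
```

generates three synthetic dancers, aligns their streams, trains a
level-1 classifier on two dancers and evaluates on the third:

```
P01: per-sensor shifts {'thoracic': 107, 'sacrum': 14, ...} (frames at 100 Hz)
training windows: 360, held-out windows: 172
final training loss 0.0300
          jump  leg_lift
jump        69         0
leg_lift     0       103
held-out dancer accuracy: 1.000
```

The shifts are the recovered per-sensor clock offsets; the confusion
matrix counts 1-s windows of the unseen dancer (rows = truth, columns =
prediction), and the accuracy is the fraction classified correctly.
`examples/sensor_ablation.py` and `examples/synchronization_demo.py`
demonstrate the other capabilities, and the `dancehar` CLI
(`simulate`, `prepare`, `segment`, `train`, `ablate`, `run`) chains the
same stages from the shell, e.g.

```bash
dancehar simulate --participants 4 --seed 42 --out data/
dancehar run --config examples/run_config.yaml
```

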
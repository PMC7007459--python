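"""Seeded synthetic recording sessions emulating the ballet protocol.

The real dataset (six-IMU recordings of pre-professional dancers) is
not publicly deposited, so this module generates annotated sessions
with the same structure: a stillness–heel-raise–stillness
synchronization prelude, a scripted sequence of jumping and leg-lifting
tasks interleaved with unlabelled transition movement, recorded by six
body-worn 9-channel sensors at 100 Hz with per-sensor clock offsets.

Signal templates are parametric, not biomechanically simulated; they
encode only the contrasts the label taxonomy depends on:

* jumps — a takeoff push, a flight-phase free-fall dip and a half-sine
  landing impact on the vertical accelerometer axis of the lower-limb
  sensors and sacrum (attenuated at the thorax); leaps are larger than
  small jumps and have longer flight; unilateral landings load the
  landing-side shin/thigh far more than the contralateral side;
* leg lifts — a sustained trapezoidal angular-velocity profile on the
  lifted-side thigh and shin, with the gyroscope axis mixture encoding
  the lift direction (front/side/back) and a modest gravity-tilt change
  on the accelerometer;
* transition ("other") movement — band-limited, low-amplitude motion on
  all sensors;
* magnetometer — a slowly drifting baseline plus a weak
  orientation-correlated echo of the gyroscope, so it carries only
  faint class information.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np

from .io import save_dataset
from .session import (
    ALL_LOCATIONS,
    SAMPLING_RATE_HZ,
    AnnotationEntry,
    AnnotationTrack,
    RecordingSession,
    SensorLocation,
    SensorStream,
)
from .taxonomy import ActivityLabel

RATE = SAMPLING_RATE_HZ

# fixed multiples of noise_sd (itself in g) for the other sensor types
GYRO_NOISE_PER_G = 20.0  # deg/s of gyro noise per 1 g of accel noise
MAG_NOISE_PER_G = 10.0  # µT of mag noise per 1 g of accel noise

MAG_BASELINE = np.array([20.0, -5.0, 45.0])  # µT, idealized field at rest

# prelude layout (frames): 5 s still, 1 s heel raise, 5 s still
PRELUDE_STILL = 5 * RATE
PRELUDE_RAISE = 1 * RATE
PRELUDE_FRAMES = 2 * PRELUDE_STILL + PRELUDE_RAISE
SYNC_PEAK_FRAME = PRELUDE_STILL + PRELUDE_RAISE // 2
MAX_SENSOR_OFFSET = 2 * RATE  # per-sensor clock offset, 0..2 s


@dataclass(frozen=True)
class ScriptEntry:
    """One scripted task: a label, how often, and how long each rep is."""

    label: ActivityLabel
    repetitions: int
    duration: float  # seconds per repetition

    def __post_init__(self) -> None:
        if self.repetitions <= 0 or self.duration <= 0:
            raise ValueError("repetitions and duration must be positive")


def default_script() -> tuple[ScriptEntry, ...]:
    """Scripted task sequence mirroring a condensed ballet class.

    Leg lifts first (3 reps per direction per side, slow ~1.5 s each),
    then jumps: 8 bilateral-landing small jumps (sautés), 8 unilateral
    small jumps split over both landing legs (jetés), and 2 leaps per
    landing leg (grands jetés).
    """
    lifts = [
        ScriptEntry(ActivityLabel("leg_lift", direction, side), 3, 1.5)
        for direction in ("front", "side", "back")
        for side in ("right", "left")
    ]
    jumps = [
        ScriptEntry(ActivityLabel("jump", "bilateral_small", "bilateral"), 8, 0.8),
        ScriptEntry(ActivityLabel("jump", "unilateral_small", "right"), 4, 0.8),
        ScriptEntry(ActivityLabel("jump", "unilateral_small", "left"), 4, 0.8),
        ScriptEntry(ActivityLabel("jump", "leap", "right"), 2, 1.0),
        ScriptEntry(ActivityLabel("jump", "leap", "left"), 2, 1.0),
    ]
    return tuple(lifts + jumps)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for synthetic data generation."""

    n_participants: int = 23
    seed: int = 42
    script: tuple[ScriptEntry, ...] = field(default_factory=default_script)
    effect_scale: float = 1.0
    noise_sd: float = 0.05  # g
    participant_variability: float = 0.15
    transition_fraction: float = 0.4
    include_sync_prelude: bool = True

    def __post_init__(self) -> None:
        if not self.script:
            raise ValueError("script must contain at least one task")
        for frac in (self.participant_variability, self.transition_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.effect_scale < 0 or self.noise_sd < 0:
            raise ValueError("effect_scale and noise_sd must be non-negative")

    def hash(self) -> str:
        payload = asdict(self)
        for entry in payload["script"]:
            entry["label"] = asdict_label(entry["label"])
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def asdict_label(label) -> dict:
    if isinstance(label, ActivityLabel):
        return {"level1": label.level1, "level2": label.level2, "level3": label.level3}
    return dict(label)


@dataclass(frozen=True)
class GeneratedEvent:
    """Provenance metadata for one generated movement."""

    start_frame: int
    end_frame: int
    label: ActivityLabel
    amplitude: float


# ---------------------------------------------------------------------------
# signal templates

def _half_sine(n: int) -> np.ndarray:
    return np.sin(np.linspace(0.0, np.pi, n, endpoint=True))


def _trapezoid(n: int) -> np.ndarray:
    """Rise 25% — hold 50% — fall 25%, peak 1."""
    rise = max(1, n // 4)
    fall = max(1, n // 4)
    hold = n - rise - fall
    return np.concatenate(
        [np.linspace(0, 1, rise), np.ones(hold), np.linspace(1, 0, fall)]
    )


#: per-location amplitude weights for jump impact/flight, by laterality.
#: Laterality is deliberately the *subtlest* cue in the generator: cue
#: salience decreases with taxonomy depth (family > type > laterality),
#: mirroring the difficulty gradient of the real task, so the landing-side
#: contrast carries per-event jitter.
def _jump_weights(level3: str, rng: np.random.Generator) -> dict[SensorLocation, float]:
    w = {
        SensorLocation.THORACIC: 0.25,
        SensorLocation.SACRUM: 0.7,
        SensorLocation.LEFT_THIGH: 0.8,
        SensorLocation.RIGHT_THIGH: 0.8,
        SensorLocation.LEFT_SHIN: 0.9,
        SensorLocation.RIGHT_SHIN: 0.9,
    }
    if level3 in ("right", "left"):
        jitter = rng.uniform(0.5, 2.0)
        land_shin, land_thigh = 1.1, 1.0
        off_shin, off_thigh = 0.35 * jitter, 0.4 * jitter
        if level3 == "right":
            w[SensorLocation.RIGHT_SHIN], w[SensorLocation.RIGHT_THIGH] = land_shin, land_thigh
            w[SensorLocation.LEFT_SHIN], w[SensorLocation.LEFT_THIGH] = off_shin, off_thigh
        else:
            w[SensorLocation.LEFT_SHIN], w[SensorLocation.LEFT_THIGH] = land_shin, land_thigh
            w[SensorLocation.RIGHT_SHIN], w[SensorLocation.RIGHT_THIGH] = off_shin, off_thigh
    return w


#: gyroscope axis mixture per leg-lift direction (x, y, z)
_LIFT_AXES = {
    "front": np.array([1.0, 0.2, 0.1]),
    "side": np.array([0.15, 1.0, 0.25]),
    "back": np.array([-0.7, 0.15, 0.55]),
}


def _add_jump(
    sig: dict[SensorLocation, np.ndarray],
    start: int,
    n: int,
    label: ActivityLabel,
    amp: float,
    effect: float,
    rng: np.random.Generator,
) -> None:
    """Takeoff push + flight free-fall dip + landing impact.

    Jump *type* is encoded by shape, not amplitude alone: leaps have a
    long flight phase and a horizontal travel surge on the trunk
    sensors; unilateral landings add an impact-roll gyroscope transient
    on the landing leg that bilateral landings lack.
    """
    leap = label.level2 == "leap"
    unilateral = label.level3 in ("right", "left")
    flight_frac = 0.4 if leap else 0.15
    n_push = max(4, int(0.15 * n))
    n_flight = max(4, int(flight_frac * n))
    n_impact = max(6, int(0.15 * n))
    t_push = start + int(0.1 * n)
    t_flight = t_push + n_push
    t_impact = min(t_flight + n_flight, start + n - n_impact)

    weights = _jump_weights(label.level3, rng)
    for loc, w in weights.items():
        z = sig[loc][:, 2]
        z[t_push : t_push + n_push] += effect * 0.5 * amp * w * _half_sine(n_push)
        # flight: acceleration magnitude dips toward 0 g (free fall)
        z[t_flight : t_flight + n_flight] -= effect * min(1.0, 0.9 * w) * _half_sine(
            n_flight
        )
        z[t_impact : t_impact + n_impact] += effect * amp * w * _half_sine(n_impact)
        # landing also shakes the horizontal axes a little
        sig[loc][t_impact : t_impact + n_impact, 0] += (
            effect * 0.25 * amp * w * _half_sine(n_impact)
        )
        # gyro transient during the jump
        g_amp = (150.0 if leap else 80.0) * w
        sig[loc][t_push : t_impact + n_impact, 4] += (
            effect * g_amp * _half_sine(t_impact + n_impact - t_push)
        )

    if leap:
        # travelling momentum: horizontal accel surge on trunk and thighs
        for loc in (
            SensorLocation.SACRUM,
            SensorLocation.THORACIC,
            SensorLocation.LEFT_THIGH,
            SensorLocation.RIGHT_THIGH,
        ):
            sig[loc][start : t_impact + n_impact, 1] += (
                effect * 0.6 * _half_sine(t_impact + n_impact - start)
            )
    if unilateral:
        # impact roll: absent in bilateral landings (a robust type cue);
        # side balance is jittered so laterality stays the subtler cue
        right = (SensorLocation.RIGHT_SHIN, SensorLocation.RIGHT_THIGH)
        left = (SensorLocation.LEFT_SHIN, SensorLocation.LEFT_THIGH)
        landing, off = (right, left) if label.level3 == "right" else (left, right)
        land_gain = rng.uniform(0.7, 1.3)
        off_gain = rng.uniform(0.3, 1.1)
        for legs, gain in ((landing, land_gain), (off, off_gain)):
            for loc, g in zip(legs, (200.0, 140.0)):
                sig[loc][t_impact : t_impact + n_impact, 3] += (
                    effect * g * gain * _half_sine(n_impact)
                )


def _add_leg_lift(
    sig: dict[SensorLocation, np.ndarray],
    start: int,
    n: int,
    label: ActivityLabel,
    amp: float,
    effect: float,
    rng: np.random.Generator,
) -> None:
    """Sustained trapezoidal angular velocity on the lifted limb.

    The stance limb co-activates (balance corrections) by a per-event
    random fraction, so laterality is a graded rather than an on/off
    contrast.
    """
    side = label.level3
    axes = _LIFT_AXES[label.level2]
    trap = _trapezoid(n)
    lifted_thigh = (
        SensorLocation.RIGHT_THIGH if side == "right" else SensorLocation.LEFT_THIGH
    )
    lifted_shin = (
        SensorLocation.RIGHT_SHIN if side == "right" else SensorLocation.LEFT_SHIN
    )
    stance = rng.uniform(0.25, 0.9)  # stance-limb co-activation fraction
    gains = {
        lifted_thigh: 1.0,
        lifted_shin: 0.7,
        SensorLocation.SACRUM: 0.2,
        SensorLocation.THORACIC: 0.15,
    }
    for loc in ALL_LOCATIONS:
        gains.setdefault(loc, stance)
    for loc, gain in gains.items():
        for ax in range(3):
            sig[loc][start : start + n, 3 + ax] += (
                effect * amp * 120.0 * gain * axes[ax] * trap
            )
        # gravity reorientation: z loses, x gains, on the lifted limb
        tilt = effect * 0.35 * gain * trap
        sig[loc][start : start + n, 2] -= tilt * amp * 0.8
        sig[loc][start : start + n, 0] += tilt * amp


def _add_transition_movement(
    sig: dict[SensorLocation, np.ndarray],
    start: int,
    n: int,
    rng: np.random.Generator,
) -> None:
    """Band-limited low-amplitude movement on all sensors."""
    if n < 4:
        return
    kernel = np.ones(15) / 15.0
    for loc in ALL_LOCATIONS:
        for col, amp in ((0, 0.12), (1, 0.12), (2, 0.15), (3, 12.0), (4, 12.0), (5, 8.0)):
            raw = rng.standard_normal(n + 14)
            sig[loc][start : start + n, col] += amp * np.convolve(raw, kernel, "valid")


def _add_heel_raise(sig: dict[SensorLocation, np.ndarray]) -> None:
    """The synchronization transient: similar on all sensors."""
    n = PRELUDE_RAISE
    bump = 0.5 * _half_sine(n)
    for loc in ALL_LOCATIONS:
        w = 1.0 if loc in (SensorLocation.LEFT_SHIN, SensorLocation.RIGHT_SHIN) else 0.85
        sig[loc][PRELUDE_STILL : PRELUDE_STILL + n, 2] += w * bump


# ---------------------------------------------------------------------------
# session generation

def generate_session(
    config: GeneratorConfig, participant_index: int
) -> RecordingSession:
    """Generate one participant's six unaligned streams + truth annotations.

    Streams carry independent random clock offsets of 0–2 s (prepended
    stillness) so the synchronization stage is genuinely exercised;
    truth annotations are expressed in post-alignment (canonical
    timeline) frame indices.  Bit-identical for identical
    (config, participant_index).
    """
    rng = np.random.default_rng([config.seed, participant_index])
    pv = config.participant_variability
    amp_factor = float(np.clip(1.0 + pv * rng.standard_normal(), 0.3, None))
    time_factor = float(np.clip(1.0 + 0.5 * pv * rng.standard_normal(), 0.5, None))

    # --- lay out the canonical timeline -----------------------------------
    reps = [
        (entry.label, max(20, int(round(entry.duration * time_factor * RATE))))
        for entry in config.script
        for _ in range(entry.repetitions)
    ]
    total_activity = sum(n for _, n in reps)
    f = config.transition_fraction
    n_gaps = len(reps) + 1
    base_gap = total_activity * (f / (1.0 - f)) / n_gaps if f < 1.0 else 0.0
    gap_lengths = [
        max(10, int(round(base_gap * rng.uniform(0.5, 1.5)))) for _ in range(n_gaps)
    ]

    prelude = PRELUDE_FRAMES if config.include_sync_prelude else 0
    events: list[GeneratedEvent] = []
    cursor = prelude + gap_lengths[0]
    for (label, n), gap in zip(reps, gap_lengths[1:]):
        amp = 5.0 if label.level2 == "leap" else 3.0
        if label.level1 == "leg_lift":
            amp = 1.0
        events.append(
            GeneratedEvent(cursor, cursor + n, label, amp * amp_factor)
        )
        cursor += n + gap
    total_frames = cursor

    # --- baseline + noise ---------------------------------------------------
    sig = {}
    for loc in ALL_LOCATIONS:
        s = np.zeros((total_frames, 9))
        s[:, 2] = 1.0  # gravity on the vertical accelerometer axis
        s[:, 6:9] = MAG_BASELINE
        # slow magnetometer drift (orientation wander)
        t = np.arange(total_frames) / RATE
        phase = rng.uniform(0, 2 * np.pi, size=3)
        s[:, 6:9] += 1.5 * np.sin(2 * np.pi * 0.01 * t[:, None] + phase)
        sig[loc] = s

    # --- movements ----------------------------------------------------------
    if config.include_sync_prelude:
        _add_heel_raise(sig)
    gap_start = prelude
    gap_iter = [(gap_start, gap_lengths[0])]
    for ev, gap in zip(events, gap_lengths[1:]):
        gap_iter.append((ev.end_frame, gap))
    for start, n in gap_iter:
        _add_transition_movement(sig, start, n, rng)

    for ev in events:
        n = ev.end_frame - ev.start_frame
        if ev.label.level1 == "jump":
            _add_jump(
                sig, ev.start_frame, n, ev.label, ev.amplitude, config.effect_scale, rng
            )
        else:
            _add_leg_lift(
                sig, ev.start_frame, n, ev.label, ev.amplitude, config.effect_scale, rng
            )

    # weak orientation-correlated magnetometer echo of the gyroscope
    for loc in ALL_LOCATIONS:
        sig[loc][:, 6:9] += 0.02 * sig[loc][:, 3:6]

    # --- noise + per-sensor clock offsets ----------------------------------
    participant_id = f"P{participant_index + 1:02d}"
    base_time = np.datetime64("2024-01-01T09:00:00.000", "ms") + np.timedelta64(
        participant_index * 3_600_000, "ms"
    )
    streams = {}
    for loc in ALL_LOCATIONS:
        offset = int(rng.integers(0, MAX_SENSOR_OFFSET + 1)) if config.include_sync_prelude else 0
        lead = np.zeros((offset, 9))
        lead[:, 2] = 1.0
        lead[:, 6:9] = MAG_BASELINE
        samples = np.concatenate([lead, sig[loc]], axis=0)
        noise = rng.standard_normal(samples.shape)
        noise[:, 0:3] *= config.noise_sd
        noise[:, 3:6] *= config.noise_sd * GYRO_NOISE_PER_G
        noise[:, 6:9] *= config.noise_sd * MAG_NOISE_PER_G
        streams[loc] = SensorStream(
            location=loc,
            samples=samples + noise,
            start_time=base_time - np.timedelta64(offset * 10, "ms"),
            participant_id=participant_id,
        )

    annotations = AnnotationTrack(
        entries=tuple(
            AnnotationEntry(ev.start_frame, ev.end_frame, ev.label) for ev in events
        ),
        total_frames=total_frames,
        sync_frame=SYNC_PEAK_FRAME if config.include_sync_prelude else None,
    )
    return RecordingSession(
        participant_id=participant_id,
        streams=streams,
        annotations=annotations,
        aligned=not config.include_sync_prelude,
        events=list(events),
    )


def generate_dataset(config: GeneratorConfig, out_dir: str | Path) -> dict:
    """Write one session per participant in the core dialect + manifest.

    Produces ``<participant>_<location>.csv`` per stream,
    ``<participant>_annotations.csv`` per participant, and
    ``manifest.json`` recording the files, the seed and a config hash.
    """
    sessions = [
        generate_session(config, i) for i in range(config.n_participants)
    ]
    return save_dataset(
        sessions,
        out_dir,
        extra={
            "n_participants": config.n_participants,
            "seed": config.seed,
            "config_hash": config.hash(),
        },
    )
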
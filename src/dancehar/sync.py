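"""Time synchronization of the six sensor streams.

Each recording starts with a standardized prelude: the dancer stands
still for ~5 s, performs a double-leg heel raise, then stands still for
another ~5 s.  The heel raise produces a near-simultaneous acceleration
transient on every sensor, bracketed by stillness, which this module
detects algorithmically and uses to shift every stream onto the common
annotation timeline (integer-frame shifts at 10 ms granularity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import (
    AnnotationTrack,
    RecordingSession,
    SensorLocation,
    SensorStream,
    canonical_locations,
)

G_BASELINE = 1.0  # resting acceleration magnitude, g

DEFAULT_STILL_THRESHOLD = 0.02  # g, rolling-sd ceiling for "standing still"
DEFAULT_STILL_MIN_DURATION = 4.0  # s, required stillness on each side
_ROLL_WINDOW = 25  # samples (0.25 s) for the rolling standard deviation
_SMOOTH_WINDOW = 15  # samples (0.15 s) moving-average prefilter
_MIN_PEAK_FACTOR = 5.0  # event must exceed this multiple of still_threshold


class SyncError(ValueError):
    """Raised when the heel-raise pattern cannot be found."""


@dataclass(frozen=True)
class SyncEvent:
    """Detected heel-raise signature on one stream."""

    location: SensorLocation
    event_frame: int
    pre_still: tuple[int, int]
    post_still: tuple[int, int]


def _rolling_sd(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling standard deviation, edge-padded to len(x)."""
    c1 = np.cumsum(np.insert(x, 0, 0.0))
    c2 = np.cumsum(np.insert(x * x, 0, 0.0))
    n = len(x) - window + 1
    mean = (c1[window:] - c1[:-window]) / window
    var = np.maximum((c2[window:] - c2[:-window]) / window - mean**2, 0.0)
    sd = np.sqrt(var)
    pad_l = (len(x) - n) // 2
    pad_r = len(x) - n - pad_l
    return np.pad(sd, (pad_l, pad_r), mode="edge")


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, edge-padded to len(x).

    Separates movement from per-sample electronic noise before the
    stillness gate: the still-threshold describes residual *motion*,
    which sits well below the raw noise floor of a 100 Hz MEMS
    accelerometer.
    """
    pad = window // 2
    xp = np.pad(x, (pad, window - 1 - pad), mode="edge")
    return np.convolve(xp, np.ones(window) / window, mode="valid")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.nonzero(padded == 1)[0]
    ends = np.nonzero(padded == -1)[0]
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def _still_runs(mask: np.ndarray, min_len: int, close_gap: int = 50) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_len, half-open.

    Gaps shorter than ``close_gap`` samples (0.5 s) are bridged first:
    a momentary statistical excursion does not end a stillness period.
    """
    if not mask.any():
        return []
    mask = mask.copy()
    for s, e in _runs(~mask):
        if 0 < s and e < len(mask) and e - s < close_gap:
            mask[s:e] = True
    return [(s, e) for s, e in _runs(mask) if e - s >= min_len]


def detect_sync_event(
    stream: SensorStream,
    still_threshold: float = DEFAULT_STILL_THRESHOLD,
    still_min_duration: float = DEFAULT_STILL_MIN_DURATION,
) -> SyncEvent:
    """Locate the heel-raise transient bracketed by stillness.

    The event frame is the earliest local maximum of the acceleration
    magnitude deviation ``| ||a|| - 1 g |`` that lies between two
    qualifying stillness intervals (rolling sd of ``||a||`` below
    ``still_threshold`` for at least ``still_min_duration`` seconds).
    """
    rate = stream.sampling_rate
    if stream.n_samples < int(12 * rate):
        raise SyncError(
            f"{stream.location.value}: stream too short for sync detection "
            f"({stream.n_samples} samples < {12 * rate})"
        )
    accel = stream.samples[:, :3]
    mag = _smooth(np.linalg.norm(accel, axis=1), _SMOOTH_WINDOW)
    dev = np.abs(mag - G_BASELINE)
    sd = _rolling_sd(mag, _ROLL_WINDOW)

    min_len = int(round(still_min_duration * rate))
    # still = low short-term variability AND magnitude near 1 g (so the
    # quiet crest of a movement transient never counts as stillness)
    still_mask = (sd < still_threshold) & (dev < 3.0 * still_threshold)
    runs = _still_runs(still_mask, min_len)

    best: tuple[float, int] | None = None
    for (s0, e0), (s1, e1) in zip(runs, runs[1:]):
        gap = dev[e0:s1]
        if gap.size == 0:
            continue
        arg = int(np.argmax(gap))
        height = float(gap[arg])
        if height >= _MIN_PEAK_FACTOR * still_threshold:
            # refine to the midpoint of the half-height support around the
            # maximum: robust to noise on a flat-topped transient
            above = gap >= 0.5 * height
            lo = arg
            while lo > 0 and above[lo - 1]:
                lo -= 1
            hi = arg
            while hi < len(gap) - 1 and above[hi + 1]:
                hi += 1
            peak = e0 + (lo + hi) // 2
            return SyncEvent(stream.location, peak, (s0, e0), (s1, e1))
        if best is None or height > best[0]:
            best = (height, arg + e0)
    detail = (
        f"best candidate peak {best[1]} with height {best[0]:.4f} g"
        if best else f"{len(runs)} qualifying stillness interval(s), no bracketed peak"
    )
    raise SyncError(
        f"{stream.location.value}: sync event not found ({detail}; "
        f"threshold {still_threshold} g, min stillness {still_min_duration} s)"
    )


def align_session(
    streams: dict[SensorLocation, SensorStream],
    annotations: AnnotationTrack,
    reference_event_frame: int | None = None,
    participant_id: str = "",
    still_threshold: float = DEFAULT_STILL_THRESHOLD,
    still_min_duration: float = DEFAULT_STILL_MIN_DURATION,
) -> RecordingSession:
    """Shift every stream so its heel-raise lands on the reference frame.

    ``reference_event_frame`` defaults to ``annotations.sync_frame``
    (the dedicated sync row of the annotation file).  Streams are
    cropped to the common overlapping extent; the annotation track is
    remapped onto the cropped timeline.  Residual inter-stream offset is
    zero by construction (integer-frame shifts).
    """
    if reference_event_frame is None:
        reference_event_frame = annotations.sync_frame
    if reference_event_frame is None:
        raise SyncError("no reference event frame: annotations carry no sync row")

    events = {
        loc: detect_sync_event(s, still_threshold, still_min_duration)
        for loc, s in streams.items()
    }
    # annotation-timeline frame f corresponds to sample f + shift in stream
    shifts = {
        loc: ev.event_frame - reference_event_frame for loc, ev in events.items()
    }
    f_lo = max(0, max(-sh for sh in shifts.values()))
    f_hi = min(
        min(len(streams[loc]) - sh for loc, sh in shifts.items()),
        annotations.total_frames,
    )
    n = f_hi - f_lo
    if n < 100:
        raise SyncError(
            f"common aligned extent {n} frames is shorter than one 100-frame window"
        )

    aligned_streams = {
        loc: streams[loc].slice(f_lo + sh, f_hi + sh) for loc, sh in shifts.items()
    }
    new_track = annotations.shifted(-f_lo, n)
    return RecordingSession(
        participant_id=participant_id,
        streams=aligned_streams,
        annotations=new_track,
        aligned=True,
    )


def trim_unwanted(
    session: RecordingSession, keep: list[tuple[int, int]]
) -> RecordingSession:
    """Concatenate the ``keep`` intervals, discarding everything else.

    Removes non-task periods (breaks, instruction, practice) after
    synchronization.  Samples inside ``keep`` are copied bit-exactly;
    annotation intervals are remapped onto the concatenated timeline
    (annotations straddling a cut are clipped to the kept portion).
    """
    session.validate_aligned()
    if not keep:
        raise ValueError("keep must contain at least one interval")
    n = session.n_frames
    prev_end = 0
    for s, t in keep:
        if not (0 <= s < t <= n):
            raise ValueError(f"keep interval [{s},{t}) outside session extent [0,{n})")
        if s < prev_end:
            raise ValueError(f"keep intervals overlap or are unsorted at [{s},{t})")
        prev_end = t

    locs = canonical_locations(session.streams)
    pieces = {loc: [] for loc in locs}
    for s, t in keep:
        for loc in locs:
            pieces[loc].append(session.streams[loc].samples[s:t])
    new_streams = {
        loc: SensorStream(
            location=loc,
            samples=np.concatenate(pieces[loc], axis=0),
            start_time=session.streams[loc].start_time,
            participant_id=session.participant_id,
        )
        for loc in locs
    }

    total = sum(t - s for s, t in keep)
    new_entries = []
    offset = 0
    sync = None
    for s, t in keep:
        shifted = session.annotations.shifted(-s, t - s)
        for e in shifted.entries:
            new_entries.append(
                type(e)(e.start_frame + offset, e.end_frame + offset, e.label)
            )
        if shifted.sync_frame is not None:
            sync = shifted.sync_frame + offset
        offset += t - s
    track = AnnotationTrack(tuple(new_entries), total, sync)
    return RecordingSession(
        participant_id=session.participant_id,
        streams=new_streams,
        annotations=track,
        aligned=True,
    )
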
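"""Core data model: sensor locations, streams, annotations, sessions.

A recording session is one dancer wearing six ActiGraph-Link-style IMUs
(triaxial accelerometer in g, gyroscope in deg/s, magnetometer in µT,
all sampled at 100 Hz) at fixed body locations, together with a
frame-level annotation track produced from synchronized video.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .taxonomy import ActivityLabel, OTHER_LABEL

SAMPLING_RATE_HZ = 100
N_CHANNELS = 9

CHANNEL_NAMES = (
    "accel_x", "accel_y", "accel_z",
    "gyro_x", "gyro_y", "gyro_z",
    "mag_x", "mag_y", "mag_z",
)


class SensorLocation(enum.Enum):
    """The six body locations, in canonical (stacking) order."""

    THORACIC = "thoracic"
    SACRUM = "sacrum"
    LEFT_THIGH = "left_thigh"
    RIGHT_THIGH = "right_thigh"
    LEFT_SHIN = "left_shin"
    RIGHT_SHIN = "right_shin"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def index(self) -> int:
        return _LOCATION_ORDER[self]


ALL_LOCATIONS: tuple[SensorLocation, ...] = tuple(SensorLocation)
_LOCATION_ORDER = {loc: i for i, loc in enumerate(ALL_LOCATIONS)}


def canonical_locations(locations: Iterable[SensorLocation | str]) -> tuple[SensorLocation, ...]:
    """Normalize to SensorLocation values sorted in canonical order."""
    locs = [SensorLocation(loc) if not isinstance(loc, SensorLocation) else loc
            for loc in locations]
    if len(set(locs)) != len(locs):
        raise ValueError("duplicate sensor locations")
    return tuple(sorted(locs, key=lambda l: l.index))


@dataclass
class SensorStream:
    """One body location's 9-channel 100 Hz time series.

    ``samples`` has shape (n_samples, 9) with columns ``CHANNEL_NAMES``;
    timestamps are implicit: sample ``k`` occurs at
    ``start_time + k / 100`` seconds. Gap-free sampling is a validity
    requirement — gaps are a read error, never silently filled.
    """

    location: SensorLocation
    samples: np.ndarray
    start_time: np.datetime64 = np.datetime64("2000-01-01T00:00:00.000", "ms")
    sampling_rate: int = SAMPLING_RATE_HZ
    participant_id: str = ""

    def __post_init__(self) -> None:
        if self.sampling_rate != SAMPLING_RATE_HZ:
            raise ValueError(
                f"sampling_rate must be {SAMPLING_RATE_HZ} Hz, got {self.sampling_rate}"
            )
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0:
            self.samples = self.samples.reshape(0, N_CHANNELS)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise ValueError(
                f"samples must have shape (n, {N_CHANNELS}), got {self.samples.shape}"
            )

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def timestamps(self) -> np.ndarray:
        """Absolute per-sample timestamps (datetime64[ms])."""
        step = np.timedelta64(1000 // SAMPLING_RATE_HZ, "ms")
        return self.start_time + np.arange(self.n_samples) * step

    def slice(self, start: int, end: int) -> "SensorStream":
        step = np.timedelta64(1000 // SAMPLING_RATE_HZ, "ms")
        return replace(
            self,
            samples=self.samples[start:end].copy(),
            start_time=self.start_time + start * step,
        )


@dataclass(frozen=True)
class AnnotationEntry:
    start_frame: int
    end_frame: int  # half-open
    label: ActivityLabel

    def __post_init__(self) -> None:
        if not (0 <= self.start_frame < self.end_frame):
            raise ValueError(
                f"invalid interval [{self.start_frame}, {self.end_frame})"
            )


@dataclass
class AnnotationTrack:
    """Frame-level annotations over a session timeline.

    Entries are sorted, non-overlapping half-open intervals; frames not
    covered by any entry are implicitly ``other`` (transition movement).
    ``sync_frame``, when present, is the annotation-timeline frame of
    the heel-raise synchronization event.
    """

    entries: tuple[AnnotationEntry, ...]
    total_frames: int
    sync_frame: int | None = None

    def __post_init__(self) -> None:
        entries = tuple(sorted(self.entries, key=lambda e: e.start_frame))
        for prev, cur in zip(entries, entries[1:]):
            if cur.start_frame < prev.end_frame:
                raise ValueError(
                    f"overlapping annotations [{prev.start_frame},{prev.end_frame}) "
                    f"and [{cur.start_frame},{cur.end_frame})"
                )
        if entries and entries[-1].end_frame > self.total_frames:
            raise ValueError(
                f"annotation [{entries[-1].start_frame},{entries[-1].end_frame}) "
                f"exceeds total_frames={self.total_frames}"
            )
        if self.total_frames < 0:
            raise ValueError("total_frames must be non-negative")
        self.entries = entries

    def label_at(self, frame: int) -> ActivityLabel:
        for e in self.entries:
            if e.start_frame <= frame < e.end_frame:
                return e.label
        return OTHER_LABEL

    def frame_labels(self) -> list[ActivityLabel]:
        """Dense per-frame labels (uncovered frames are 'other')."""
        out = [OTHER_LABEL] * self.total_frames
        for e in self.entries:
            for f in range(e.start_frame, e.end_frame):
                out[f] = e.label
        return out

    def shifted(self, offset: int, total_frames: int) -> "AnnotationTrack":
        """Translate entries by ``offset`` and clip to [0, total_frames)."""
        new = []
        for e in self.entries:
            s = max(e.start_frame + offset, 0)
            t = min(e.end_frame + offset, total_frames)
            if s < t:
                new.append(AnnotationEntry(s, t, e.label))
        sync = None
        if self.sync_frame is not None:
            cand = self.sync_frame + offset
            if 0 <= cand < total_frames:
                sync = cand
        return AnnotationTrack(tuple(new), total_frames, sync)


@dataclass
class RecordingSession:
    """A participant's six sensor streams plus the annotation track.

    ``aligned=True`` asserts that every stream and the annotation track
    share frame index 0 and have equal length.
    """

    participant_id: str
    streams: dict[SensorLocation, SensorStream]
    annotations: AnnotationTrack
    aligned: bool = False
    events: list = field(default_factory=list)  # generator provenance, if synthetic

    def __post_init__(self) -> None:
        if self.aligned:
            self.validate_aligned()

    def validate_aligned(self) -> None:
        lengths = {loc: len(s) for loc, s in self.streams.items()}
        distinct = set(lengths.values()) | {self.annotations.total_frames}
        if len(distinct) != 1:
            raise ValueError(
                f"aligned session has unequal extents: streams={lengths}, "
                f"annotations={self.annotations.total_frames}"
            )

    @property
    def locations(self) -> tuple[SensorLocation, ...]:
        return canonical_locations(self.streams)

    @property
    def n_frames(self) -> int:
        if not self.aligned:
            raise ValueError("n_frames is defined only for aligned sessions")
        return self.annotations.total_frames

    def stacked(self, locations: Sequence[SensorLocation] | None = None) -> np.ndarray:
        """Channel-stacked matrix of shape (9·|locations|, n_frames).

        Rows are grouped in 9-row blocks per location, canonical order.
        """
        self.validate_aligned()
        locs = canonical_locations(locations if locations is not None else self.streams)
        return np.concatenate([self.streams[loc].samples.T for loc in locs], axis=0)
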
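"""Sliding-window segmentation of aligned sessions.

Aligned sessions are cut into fixed 1-s windows (100 frames at 100 Hz)
with configurable overlap; overlapping windows capture events near
window boundaries.  Each window receives one class per classification
level: the window is labelled at level 3 by the majority-frame rule and
the coarser levels are derived by projection, which guarantees
cross-level consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np

from .session import (
    N_CHANNELS,
    AnnotationTrack,
    RecordingSession,
    SensorLocation,
    canonical_locations,
)
from .taxonomy import OTHER, coarsen_class

ALLOWED_OVERLAPS = (0.0, 0.25, 0.5, 0.75)
DEFAULT_WINDOW = 100
DEFAULT_OVERLAP = 0.75

LEVELS = (1, 2, 3)


def stride_for(window: int, overlap_fraction: float) -> int:
    """Integer stride implied by a window size and overlap fraction."""
    if overlap_fraction not in ALLOWED_OVERLAPS:
        raise ValueError(
            f"overlap_fraction must be one of {ALLOWED_OVERLAPS}, got {overlap_fraction}"
        )
    stride = window * (1.0 - overlap_fraction)
    if stride != int(stride) or stride <= 0:
        raise ValueError(
            f"window {window} with overlap {overlap_fraction} gives non-integer stride"
        )
    return int(stride)


@dataclass(frozen=True)
class Segment:
    """One labelled window: (9·|locations|) × window data matrix."""

    participant_id: str
    start_frame: int
    data: np.ndarray
    labels: dict[int, str]  # level -> class name


@dataclass
class SegmentSet:
    """A stack of segments sharing geometry and provenance.

    ``data`` has shape (n_segments, 9·|locations|, window); rows are
    grouped in 9-row blocks per location in canonical order.
    """

    data: np.ndarray
    labels: dict[int, np.ndarray]  # level -> (n_segments,) array of class names
    start_frames: np.ndarray
    participant_ids: np.ndarray
    locations: tuple[SensorLocation, ...]
    window: int = DEFAULT_WINDOW
    overlap_fraction: float = DEFAULT_OVERLAP

    def __post_init__(self) -> None:
        self.locations = canonical_locations(self.locations)
        n, rows, w = self.data.shape
        if rows != N_CHANNELS * len(self.locations):
            raise ValueError(
                f"data has {rows} rows, expected {N_CHANNELS * len(self.locations)} "
                f"for {len(self.locations)} locations"
            )
        if w != self.window:
            raise ValueError(f"data has {w} columns, expected window={self.window}")

    def __len__(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, i: int) -> Segment:
        return Segment(
            participant_id=str(self.participant_ids[i]),
            start_frame=int(self.start_frames[i]),
            data=self.data[i],
            labels={lvl: str(self.labels[lvl][i]) for lvl in LEVELS},
        )

    def __iter__(self) -> Iterator[Segment]:
        return (self[i] for i in range(len(self)))

    @property
    def stride(self) -> int:
        return stride_for(self.window, self.overlap_fraction)

    def labels_at(self, level: int) -> np.ndarray:
        return self.labels[level]


def assign_window_label(
    window_interval: tuple[int, int],
    annotations: AnnotationTrack,
    level: int,
    policy: str = "majority",
) -> str:
    """Class covering the most frames of the interval at ``level``.

    Unannotated frames count toward ``other``.  Ties are broken toward
    the non-``other`` class first, then lexicographically, so the result
    is deterministic and independent of annotation order.
    """
    if policy != "majority":
        raise ValueError(f"unknown labeling policy {policy!r}")
    s, t = window_interval
    if not (0 <= s < t <= annotations.total_frames):
        raise ValueError(
            f"window [{s},{t}) outside track extent [0,{annotations.total_frames})"
        )
    counts: dict[str, int] = {}
    covered = 0
    for e in annotations.entries:
        ov = min(t, e.end_frame) - max(s, e.start_frame)
        if ov > 0:
            cls = e.label.at_level(level)
            counts[cls] = counts.get(cls, 0) + ov
            covered += ov
    counts[OTHER] = counts.get(OTHER, 0) + (t - s) - covered
    return min(counts, key=lambda c: (-counts[c], c == OTHER, c))


def segment_session(
    session: RecordingSession,
    locations: Sequence[SensorLocation] | None = None,
    window: int = DEFAULT_WINDOW,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> SegmentSet:
    """Cut an aligned session into labelled overlapping windows.

    Produces floor((n_frames − window)/stride) + 1 segments; the
    trailing partial window is discarded.  Window data are verbatim
    slices of the stacked channel matrix.
    """
    session.validate_aligned()
    locs = canonical_locations(locations if locations is not None else session.streams)
    stride = stride_for(window, overlap_fraction)
    n = session.n_frames
    if n < window:
        raise ValueError(f"session has {n} frames, shorter than window={window}")

    stacked = session.stacked(locs)  # (9L, n)
    n_seg = (n - window) // stride + 1
    starts = np.arange(n_seg) * stride
    data = np.stack([stacked[:, s : s + window] for s in starts])

    lvl3 = np.array(
        [assign_window_label((int(s), int(s) + window), session.annotations, 3)
         for s in starts],
        dtype=object,
    )
    labels = {
        3: lvl3,
        2: np.array([coarsen_class(c, 2) for c in lvl3], dtype=object),
        1: np.array([coarsen_class(c, 1) for c in lvl3], dtype=object),
    }
    return SegmentSet(
        data=data,
        labels=labels,
        start_frames=starts,
        participant_ids=np.array([session.participant_id] * n_seg, dtype=object),
        locations=locs,
        window=window,
        overlap_fraction=overlap_fraction,
    )


def drop_other(segments: SegmentSet) -> SegmentSet:
    """Remove transition windows (level-1 label ``other``).

    Builds the without-transitions variant of a dataset.
    """
    mask = segments.labels[1] != OTHER
    return replace(
        segments,
        data=segments.data[mask],
        labels={lvl: segments.labels[lvl][mask] for lvl in LEVELS},
        start_frames=segments.start_frames[mask],
        participant_ids=segments.participant_ids[mask],
    )


def select_locations(
    segments: SegmentSet, subset: Sequence[SensorLocation | str]
) -> SegmentSet:
    """Restrict segment data to a subset of sensor locations.

    Keeps the 9-row blocks of the subset in canonical order; labels are
    untouched, so ablation compares identical windows across subsets.
    """
    locs = canonical_locations(subset)
    if not locs:
        raise ValueError("subset must be non-empty")
    missing = [l.value for l in locs if l not in segments.locations]
    if missing:
        raise ValueError(f"locations {missing} not present in this segment set")
    block = {loc: i for i, loc in enumerate(segments.locations)}
    rows = np.concatenate(
        [np.arange(N_CHANNELS) + N_CHANNELS * block[loc] for loc in locs]
    )
    return replace(segments, data=segments.data[:, rows, :], locations=locs)


def concat_segment_sets(sets: Sequence[SegmentSet]) -> SegmentSet:
    """Stack segment sets with identical geometry (training folds)."""
    if not sets:
        raise ValueError("nothing to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if s.locations != first.locations or s.window != first.window:
            raise ValueError("segment sets have mismatched geometry")
    return replace(
        first,
        data=np.concatenate([s.data for s in sets]),
        labels={
            lvl: np.concatenate([s.labels[lvl] for s in sets]) for lvl in LEVELS
        },
        start_frames=np.concatenate([s.start_frames for s in sets]),
        participant_ids=np.concatenate([s.participant_ids for s in sets]),
    )


def save_segments(segments: SegmentSet, path: str | Path) -> None:
    """Persist a segment set to an HDF5 container (float32 data)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=segments.data.astype(np.float32))
        for lvl in LEVELS:
            f.create_dataset(
                f"labels_level{lvl}",
                data=np.array([s.encode() for s in segments.labels[lvl]]),
            )
        f.create_dataset("start_frames", data=segments.start_frames.astype(np.int64))
        f.create_dataset(
            "participant_ids",
            data=np.array([s.encode() for s in segments.participant_ids]),
        )
        f.attrs["window"] = segments.window
        f.attrs["overlap_fraction"] = segments.overlap_fraction
        f.attrs["locations"] = ",".join(l.value for l in segments.locations)


def load_segments(path: str | Path) -> SegmentSet:
    with h5py.File(path, "r") as f:
        locations = canonical_locations(str(f.attrs["locations"]).split(","))
        return SegmentSet(
            data=f["data"][:].astype(np.float64),
            labels={
                lvl: np.array(
                    [b.decode() for b in f[f"labels_level{lvl}"][:]], dtype=object
                )
                for lvl in LEVELS
            },
            start_frames=f["start_frames"][:],
            participant_ids=np.array(
                [b.decode() for b in f["participant_ids"][:]], dtype=object
            ),
            locations=locations,
            window=int(f.attrs["window"]),
            overlap_fraction=float(f.attrs["overlap_fraction"]),
        )
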
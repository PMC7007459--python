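"""Readers/writers for sensor-stream and annotation files.

Sensor streams use a small documented CSV dialect modelled on raw
activity-monitor exports (one file per participant per body location):

    participant,P01
    location,sacrum
    start_time,2024-01-01T10:00:00.000
    rate_hz,100
    timestamp,accel_x,accel_y,accel_z,gyro_x,gyro_y,gyro_z,mag_x,mag_y,mag_z
    2024-01-01T10:00:00.000,-0.01,0.0,1.01,...
    ...

Rows are date-time stamped at exactly 10 ms spacing; a missing or
duplicated row is an integrity error (gaps are never silently filled).
Floats are written with shortest round-trip precision, so
write → read → write is byte-stable.

Annotation files are plain CSV with columns
``start_frame,end_frame,level1,level2,level3`` (half-open 0-based frame
intervals on the session timeline).  A dedicated row with all three
levels equal to ``sync`` marks the heel-raise synchronization frame.
All files are UTF-8 with LF line endings.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .session import (
    CHANNEL_NAMES,
    SAMPLING_RATE_HZ,
    AnnotationEntry,
    AnnotationTrack,
    RecordingSession,
    SensorLocation,
    SensorStream,
)
from .taxonomy import ActivityLabel

_STEP_MS = 1000 // SAMPLING_RATE_HZ

SYNC_MARKER = "sync"


class FormatError(ValueError):
    """The file does not conform to the documented dialect."""


class IntegrityError(ValueError):
    """The file parses but violates a data invariant (gap, overlap...)."""


def _ts_str(t: np.datetime64) -> str:
    return np.datetime_as_string(np.datetime64(t, "ms"), unit="ms")


def write_sensor_stream(stream: SensorStream, path: str | Path) -> None:
    """Write a stream in the core dialect; re-readable with equality."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"participant,{stream.participant_id}\n")
    buf.write(f"location,{stream.location.value}\n")
    buf.write(f"start_time,{_ts_str(stream.start_time)}\n")
    buf.write(f"rate_hz,{stream.sampling_rate}\n")
    buf.write("timestamp," + ",".join(CHANNEL_NAMES) + "\n")
    ts = stream.timestamps()
    for k in range(stream.n_samples):
        row = ",".join(repr(float(v)) for v in stream.samples[k])
        buf.write(f"{_ts_str(ts[k])},{row}\n")
    path.write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def read_sensor_stream(path: str | Path, location: SensorLocation | str | None = None) -> SensorStream:
    """Read and validate a sensor-stream file.

    ``location``, when given, must match the file header.  Timestamp
    gaps or non-monotone timestamps raise :class:`IntegrityError`
    naming the first offending data row (0-based).
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header: dict[str, str] = {}
        for key in ("participant", "location", "start_time", "rate_hz"):
            line = fh.readline().rstrip("\n")
            name, _, value = line.partition(",")
            if name != key:
                raise FormatError(f"{path}: expected header line {key!r}, got {name!r}")
            header[key] = value
        columns_line = fh.readline().rstrip("\n").split(",")
        expected = ["timestamp", *CHANNEL_NAMES]
        if columns_line != expected:
            missing = [c for c in expected if c not in columns_line]
            extra = [c for c in columns_line if c not in expected]
            raise FormatError(
                f"{path}: bad column header; missing {missing}, unexpected {extra}"
            )
        body = pd.read_csv(
            fh, header=None, names=expected, float_precision="round_trip"
        )

    rate = int(header["rate_hz"])
    if rate != SAMPLING_RATE_HZ:
        raise FormatError(f"{path}: unsupported sampling rate {rate} Hz")
    file_loc = SensorLocation(header["location"])
    if location is not None and SensorLocation(location) != file_loc:
        raise FormatError(
            f"{path}: header location {file_loc.value!r} != requested "
            f"{SensorLocation(location).value!r}"
        )
    start = np.datetime64(header["start_time"], "ms")

    samples = body[list(CHANNEL_NAMES)].to_numpy(dtype=np.float64)
    if np.isnan(samples).any():
        bad = int(np.argwhere(np.isnan(samples))[0, 0])
        raise FormatError(f"{path}: non-numeric value in data row {bad}")

    ts = pd.to_datetime(body["timestamp"]).to_numpy().astype("datetime64[ms]")
    if len(ts):
        if ts[0] != start:
            raise IntegrityError(
                f"{path}: first timestamp {ts[0]} != declared start_time {start} (row 0)"
            )
        deltas = np.diff(ts).astype("timedelta64[ms]").astype(np.int64)
        bad = np.nonzero(deltas != _STEP_MS)[0]
        if bad.size:
            i = int(bad[0]) + 1
            kind = "non-monotone" if deltas[bad[0]] <= 0 else "gapped"
            raise IntegrityError(
                f"{path}: {kind} timestamp at data row {i} "
                f"(step {deltas[bad[0]]} ms, expected {_STEP_MS} ms)"
            )

    return SensorStream(
        location=file_loc,
        samples=samples,
        start_time=start,
        participant_id=header["participant"],
    )


def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    path = Path(path)
    lines = ["start_frame,end_frame,level1,level2,level3"]
    if track.sync_frame is not None:
        lines.append(
            f"{track.sync_frame},{track.sync_frame + 1},"
            f"{SYNC_MARKER},{SYNC_MARKER},{SYNC_MARKER}"
        )
    for e in track.entries:
        lab = e.label
        lines.append(
            f"{e.start_frame},{e.end_frame},{lab.level1},{lab.level2},{lab.level3}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_annotations(path: str | Path, total_frames: int) -> AnnotationTrack:
    """Read an annotation CSV and validate it against the taxonomy.

    Hierarchy violations (e.g. a jump with a leg-lift direction) and
    interval overlaps are errors naming the offending row(s).
    """
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["start_frame", "end_frame", "level1", "level2", "level3"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")

    entries = []
    sync_frame = None
    for i, row in df.iterrows():
        if row["level1"] == SYNC_MARKER:
            sync_frame = int(row["start_frame"])
            continue
        try:
            label = ActivityLabel(row["level1"], row["level2"], row["level3"])
        except ValueError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
        s, t = int(row["start_frame"]), int(row["end_frame"])
        if not (0 <= s < t <= total_frames):
            raise IntegrityError(
                f"{path}: row {i}: interval [{s},{t}) outside [0,{total_frames})"
            )
        entries.append(AnnotationEntry(s, t, label))

    try:
        return AnnotationTrack(tuple(entries), total_frames, sync_frame)
    except ValueError as exc:
        raise IntegrityError(f"{path}: {exc}") from exc


def save_dataset(
    sessions: Sequence[RecordingSession], out_dir: str | Path, extra: dict | None = None
) -> dict:
    """Write sessions in the core dialect with a loadable manifest.

    Emits ``<participant>_<location>.csv`` per stream,
    ``<participant>_annotations.csv`` per participant, and
    ``manifest.json`` recording files, per-session frame counts and
    alignment state.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    participants: dict[str, dict] = {}
    for s in sessions:
        stream_files = {}
        for loc, stream in s.streams.items():
            fname = f"{s.participant_id}_{loc.value}.csv"
            write_sensor_stream(stream, out_dir / fname)
            stream_files[loc.value] = fname
        ann = f"{s.participant_id}_annotations.csv"
        write_annotations(s.annotations, out_dir / ann)
        participants[s.participant_id] = {
            "streams": stream_files,
            "annotations": ann,
            "total_frames": s.annotations.total_frames,
            "aligned": s.aligned,
        }
    manifest = {"participants": participants, **(extra or {})}
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def load_dataset(data_dir: str | Path) -> list[RecordingSession]:
    """Load a dataset previously written by :func:`save_dataset`."""
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text(encoding="utf-8"))
    sessions = []
    for pid, info in sorted(manifest["participants"].items()):
        streams = {
            SensorLocation(loc): read_sensor_stream(data_dir / fname, loc)
            for loc, fname in info["streams"].items()
        }
        annotations = read_annotations(
            data_dir / info["annotations"], info["total_frames"]
        )
        sessions.append(
            RecordingSession(
                participant_id=pid,
                streams=streams,
                annotations=annotations,
                aligned=bool(info.get("aligned", False)),
            )
        )
    return sessions
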
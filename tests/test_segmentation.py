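"""Window segmentation, labeling policy and location selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dancehar import (
    AnnotationEntry,
    AnnotationTrack,
    ActivityLabel,
    RecordingSession,
    SensorLocation,
    SensorStream,
    assign_window_label,
    concat_segment_sets,
    drop_other,
    load_segments,
    save_segments,
    segment_session,
    select_locations,
)
from dancehar.segmentation import stride_for


def make_session(n_frames, entries=(), participant="P01", seed=0):
    rng = np.random.default_rng(seed)
    streams = {
        loc: SensorStream(location=loc, samples=rng.standard_normal((n_frames, 9)))
        for loc in SensorLocation
    }
    track = AnnotationTrack(tuple(entries), total_frames=n_frames)
    return RecordingSession(participant, streams, track, aligned=True)


@pytest.mark.parametrize(
    "n_frames, overlap, expected_starts",
    [
        (200, 0.75, [0, 25, 50, 75, 100]),
        (100, 0.75, [0]),
        (100, 0.0, [0]),
        (250, 0.0, [0, 100]),  # frames 200-249 discarded
        (199, 0.5, [0, 50]),
    ],
)
def test_segment_counts_and_starts(n_frames, overlap, expected_starts):
    segs = segment_session(make_session(n_frames), overlap_fraction=overlap)
    assert list(segs.start_frames) == expected_starts


def test_session_shorter_than_window_rejected():
    with pytest.raises(ValueError, match="shorter than window"):
        segment_session(make_session(99))


def test_invalid_overlap_rejected():
    with pytest.raises(ValueError, match="overlap_fraction"):
        segment_session(make_session(200), overlap_fraction=0.3)
    with pytest.raises(ValueError):
        stride_for(100, 0.3)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    n_frames=st.integers(min_value=100, max_value=1500),
    overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
)
def test_segment_count_matches_brute_force_slide(n_frames, overlap):
    """floor((n − w)/stride) + 1 equals an explicit slide enumeration."""
    window = 100
    stride = stride_for(window, overlap)
    brute = [s for s in range(0, n_frames) if s + window <= n_frames and s % stride == 0]
    assert (n_frames - window) // stride + 1 == len(brute)


def test_segment_data_is_verbatim_slice():
    session = make_session(300, seed=3)
    segs = segment_session(session, overlap_fraction=0.5)
    stacked = session.stacked()
    for i in range(len(segs)):
        s = int(segs.start_frames[i])
        np.testing.assert_array_equal(segs.data[i], stacked[:, s : s + 100])


# --- window labeling -------------------------------------------------------

def track_of(*spans, total=200):
    return AnnotationTrack(
        tuple(AnnotationEntry(s, e, lab) for s, e, lab in spans), total_frames=total
    )


JUMP = ActivityLabel("jump", "leap", "right")
LIFT = ActivityLabel("leg_lift", "front", "left")


def test_window_inside_single_annotation():
    track = track_of((0, 200, JUMP))
    assert assign_window_label((50, 150), track, 3) == "leap_right"
    assert assign_window_label((50, 150), track, 1) == "jump"


def test_majority_prefers_larger_cover():
    """60 unannotated frames beat 40 annotated ones at level 1."""
    track = track_of((60, 100, JUMP), total=100)
    assert assign_window_label((0, 100), track, 1) == "other"


def test_tie_breaks_toward_non_other_then_lexicographic():
    # 50/50 annotated vs unannotated -> the non-'other' class wins
    track = track_of((50, 100, JUMP), total=100)
    assert assign_window_label((0, 100), track, 1) == "jump"
    # 50/50 between two classes -> lexicographically smaller class,
    # independent of annotation order
    t1 = track_of((0, 50, JUMP), (50, 100, LIFT), total=100)
    t2 = track_of((0, 50, LIFT), (50, 100, JUMP), total=100)
    assert assign_window_label((0, 100), t1, 1) == "jump"
    assert assign_window_label((0, 100), t2, 1) == "jump"


def test_segment_labels_are_cross_level_consistent(aligned_sessions):
    from dancehar.taxonomy import coarsen_class

    segs = segment_session(aligned_sessions[0])
    for i in range(len(segs)):
        c3 = segs.labels[3][i]
        assert segs.labels[2][i] == coarsen_class(c3, 2)
        assert segs.labels[1][i] == coarsen_class(c3, 1)


def test_event_spanning_windows_share_label():
    """An event longer than window + stride yields identically labelled
    consecutive windows inside it."""
    track = track_of((0, 200, LIFT), total=300)
    session = make_session(300, entries=track.entries)
    segs = segment_session(session, overlap_fraction=0.75)
    inside = [
        i
        for i in range(len(segs))
        if segs.start_frames[i] >= 0 and segs.start_frames[i] + 100 <= 200
    ]
    assert len(inside) >= 2
    assert {segs.labels[3][i] for i in inside} == {"front_left"}


# --- subsetting ------------------------------------------------------------

def test_drop_other(aligned_sessions):
    segs = segment_session(aligned_sessions[0])
    kept = drop_other(segs)
    assert set(kept.labels[1]) <= {"jump", "leg_lift"}
    assert len(kept) == int((segs.labels[1] != "other").sum())
    # idempotent on an other-free set
    again = drop_other(kept)
    assert len(again) == len(kept)


def test_select_locations_blocks_and_order():
    session = make_session(200, seed=4)
    segs = segment_session(session)
    sub = select_locations(segs, [SensorLocation.RIGHT_THIGH, SensorLocation.LEFT_SHIN])
    assert sub.data.shape[1] == 18
    # canonical order puts left_shin AFTER right_thigh
    assert sub.locations == (SensorLocation.RIGHT_THIGH, SensorLocation.LEFT_SHIN)
    stacked = session.stacked([SensorLocation.RIGHT_THIGH, SensorLocation.LEFT_SHIN])
    np.testing.assert_array_equal(sub.data[0], stacked[:, :100])


def test_select_locations_composes():
    """Selecting B from A-selected equals selecting B directly (B ⊆ A)."""
    segs = segment_session(make_session(200, seed=5))
    A = [SensorLocation.SACRUM, SensorLocation.LEFT_THIGH, SensorLocation.RIGHT_SHIN]
    B = [SensorLocation.SACRUM, SensorLocation.RIGHT_SHIN]
    via_a = select_locations(select_locations(segs, A), B)
    direct = select_locations(segs, B)
    np.testing.assert_array_equal(via_a.data, direct.data)
    assert via_a.locations == direct.locations


def test_select_locations_empty_rejected():
    segs = segment_session(make_session(200))
    with pytest.raises(ValueError):
        select_locations(segs, [])


def test_single_location_gives_nine_rows():
    segs = segment_session(make_session(200))
    sub = select_locations(segs, [SensorLocation.SACRUM])
    assert sub.data.shape[1] == 9


def test_segment_set_hdf5_round_trip(tmp_path, aligned_sessions):
    segs = segment_session(aligned_sessions[0])
    path = tmp_path / "segs.h5"
    save_segments(segs, path)
    back = load_segments(path)
    assert len(back) == len(segs)
    assert back.locations == segs.locations
    for lvl in (1, 2, 3):
        assert list(back.labels[lvl]) == list(segs.labels[lvl])
    np.testing.assert_allclose(back.data, segs.data, rtol=1e-6)


def test_concat_segment_sets(aligned_sessions):
    sets = [segment_session(s) for s in aligned_sessions[:2]]
    both = concat_segment_sets(sets)
    assert len(both) == len(sets[0]) + len(sets[1])
    assert set(both.participant_ids) == {
        sets[0].participant_ids[0], sets[1].participant_ids[0]
    }
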
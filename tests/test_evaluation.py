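"""Confusion matrices, LOOCV structure and the sensor ablation."""

import numpy as np
import pytest

from dancehar import (
    SensorLocation,
    accuracy,
    average_results,
    confusion_matrix,
    enumerate_subsets,
    loocv,
    run_ablation,
)
from dancehar.evaluation import ConfusionMatrix, _loocv_segments
from dancehar.segmentation import segment_session


def test_confusion_matrix_counts():
    cm = confusion_matrix(["a", "a", "b"], ["a", "b", "b"], ["a", "b"])
    np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])
    assert cm.total == 3


def test_confusion_matrix_perfect_prediction_is_diagonal():
    labels = ["a", "b", "c", "b", "a"]
    cm = confusion_matrix(labels, labels, ["a", "b", "c"])
    assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
    assert accuracy(cm) == 1.0


def test_confusion_matrix_empty_inputs():
    cm = confusion_matrix([], [], ["a", "b"])
    assert cm.total == 0
    with pytest.raises(ValueError):
        accuracy(cm)


def test_confusion_matrix_rejects_unknown_label():
    with pytest.raises(ValueError, match="unknown label"):
        confusion_matrix(["a"], ["z"], ["a", "b"])


@pytest.mark.parametrize(
    "counts, expected",
    [
        ([[2, 1], [0, 3]], 5 / 6),
        ([[3, 0, 0], [0, 3, 1], [1, 0, 2]], 0.8),
    ],
)
def test_accuracy_is_trace_over_total(counts, expected):
    names = tuple("abc"[: len(counts)])
    cm = ConfusionMatrix(names, np.array(counts))
    assert accuracy(cm) == pytest.approx(expected)


def test_accuracy_matches_brute_force_recount():
    """trace/total equals a direct recount of matching label pairs."""
    rng = np.random.default_rng(0)
    classes = ["a", "b", "c", "d"]
    for _ in range(50):
        n = int(rng.integers(1, 60))
        t = rng.choice(classes, n)
        p = rng.choice(classes, n)
        cm = confusion_matrix(list(t), list(p), classes)
        assert accuracy(cm) == pytest.approx(np.mean(t == p))


def test_average_results_means():
    from dancehar.evaluation import FoldResult

    cm1 = ConfusionMatrix(("a", "b"), np.array([[2, 0], [0, 2]]))
    cm2 = ConfusionMatrix(("a", "b"), np.array([[1, 1], [1, 1]]))
    folds = [
        FoldResult("P01", {1: cm1}, {1: 1.0}),
        FoldResult("P02", {1: cm2}, {1: 0.5}),
    ]
    avg = average_results(folds)
    assert avg[1][0] == pytest.approx(0.75)
    np.testing.assert_allclose(avg[1][1].counts, [[1.5, 0.5], [0.5, 1.5]])
    single = average_results(folds[:1])
    assert single[1][0] == 1.0


@pytest.mark.parametrize("size, expected", [(1, 6), (2, 15), (3, 20), (4, 15), (5, 6), (6, 1)])
def test_enumerate_subsets_counts(size, expected):
    subsets = enumerate_subsets(size)
    assert len(subsets) == expected
    assert len(set(subsets)) == expected
    for sub in subsets:
        indices = [loc.index for loc in sub]
        assert indices == sorted(indices)  # canonical internal order
    assert subsets == sorted(subsets, key=lambda s: [l.index for l in s])


def test_enumerate_subsets_rejects_bad_size():
    for bad in (0, 7):
        with pytest.raises(ValueError):
            enumerate_subsets(bad)


def test_loocv_partitions_participants(aligned_sessions, fast_model_config):
    folds = loocv(
        aligned_sessions,
        fast_model_config,
        locations=[SensorLocation.SACRUM],
        transitions=False,
        levels=(1,),
    )
    held = [f.held_out_participant for f in folds]
    assert sorted(held) == sorted(s.participant_id for s in aligned_sessions)
    assert len(set(held)) == len(held)
    for f in folds:
        assert f.matrices[1].total > 0
        assert 0.0 <= f.accuracies[1] <= 1.0


def test_loocv_scales_to_full_cohort_size():
    """23 participants give 23 folds that partition the cohort (the
    models here are untrained: this checks fold structure only)."""
    from tests.test_model import toy_segments
    from dancehar.model import ModelConfig
    from dancehar.session import ALL_LOCATIONS

    by_p = {}
    for i in range(23):
        segs = toy_segments(4, ALL_LOCATIONS[:1], seed=i)
        for lvl in (1, 2, 3):
            segs.labels[lvl] = np.where(
                segs.labels[lvl] == "a", "jump", "leg_lift"
            ).astype(object)
        by_p[f"P{i:02d}"] = segs
    cfg = ModelConfig(
        conv1_filters=2, conv2_filters=2, dense_units=4, epochs=0,
        class_weighting=False,
    )
    folds = _loocv_segments(by_p, cfg, transitions=False, levels=(1,))
    assert len(folds) == 23
    assert sorted(f.held_out_participant for f in folds) == sorted(by_p)


def test_loocv_requires_two_participants(aligned_sessions, fast_model_config):
    with pytest.raises(ValueError, match="2 participants"):
        loocv(aligned_sessions[:1], fast_model_config)


def test_loocv_normalization_excludes_held_out(aligned_sessions, fast_model_config):
    """Shifting one participant's channels must not move the training
    statistics of the fold that holds that participant out."""
    by_p = {
        s.participant_id: segment_session(s, [SensorLocation.SACRUM])
        for s in aligned_sessions
    }
    pids = list(by_p)
    shifted = {p: s for p, s in by_p.items()}
    bumped = by_p[pids[0]]
    bumped = type(bumped)(
        data=bumped.data + 100.0,
        labels=bumped.labels,
        start_frames=bumped.start_frames,
        participant_ids=bumped.participant_ids,
        locations=bumped.locations,
        window=bumped.window,
        overlap_fraction=bumped.overlap_fraction,
    )
    shifted[pids[0]] = bumped

    folds_a = _loocv_segments(by_p, fast_model_config, False, (1,))
    folds_b = _loocv_segments(shifted, fast_model_config, False, (1,))

    def stats_of(folds, pid):
        return [f for f in folds if f.held_out_participant == pid][0].norm_stats

    # fold holding out the bumped participant: training stats identical
    np.testing.assert_array_equal(
        stats_of(folds_a, pids[0]).mean, stats_of(folds_b, pids[0]).mean
    )
    # any other fold trains on the bumped data: stats must move
    assert not np.allclose(
        stats_of(folds_a, pids[1]).mean, stats_of(folds_b, pids[1]).mean
    )


def test_ablation_structure(aligned_sessions, fast_model_config):
    """A restricted ablation has C(6,k) rows per size and coherent
    per-size summary statistics."""
    report = run_ablation(
        aligned_sessions,
        fast_model_config,
        transitions=False,
        levels=(1,),
        subset_sizes=(5, 6),
        overlap_fraction=0.0,
    )
    assert report.n_subsets == 6 + 1
    summary = report.summary_frame()
    for _, row in summary.iterrows():
        assert row["min_accuracy"] <= row["mean_accuracy"] <= row["max_accuracy"]
        size_rows = report.subset_frame()
        accs = size_rows[size_rows.n_sensors == row["n_sensors"]]["level1_accuracy"]
        assert row["max_accuracy"] == pytest.approx(accs.max())
        assert row["min_accuracy"] == pytest.approx(accs.min())
    counts = summary.set_index("n_sensors")["n_combinations"]
    assert counts[5] == 6 and counts[6] == 1
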
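"""Leave-one-participant-out evaluation and exhaustive sensor ablation.

Model performance is estimated by leave-one-participant-out
cross-validation: the classifier is trained on every dancer but one and
tested on the held-out dancer, repeated until each dancer has served as
the test set.  Per-participant confusion matrices are averaged
(unweighted per participant) across the population; accuracy is
trace/total, the multiclass form of (TP+TN)/total.  The sensor ablation
re-runs this procedure for every non-empty subset of the six body
locations (63 subsets), reusing one segmentation pass so all subsets
see identical windows.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .model import ModelConfig, build_model, derive_seed, normalize, predict, train
from .segmentation import (
    DEFAULT_OVERLAP,
    DEFAULT_WINDOW,
    SegmentSet,
    concat_segment_sets,
    drop_other,
    segment_session,
    select_locations,
)
from .session import ALL_LOCATIONS, RecordingSession, SensorLocation
from .taxonomy import class_names as taxonomy_classes

LEVELS = (1, 2, 3)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows = true class, columns = predicted."""

    class_names: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.class_names), len(self.class_names)):
            raise ValueError(
                f"counts shape {c.shape} does not match {len(self.class_names)} classes"
            )

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names)


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_names: Sequence[str],
) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    known = set(class_names)
    for lab in itertools.chain(true_labels, predicted_labels):
        if lab not in known:
            raise ValueError(f"unknown label {lab!r} (classes: {list(class_names)})")
    if len(true_labels) == 0:
        counts = np.zeros((len(class_names), len(class_names)), dtype=int)
    else:
        counts = _sk_confusion(true_labels, predicted_labels, labels=list(class_names))
    return ConfusionMatrix(tuple(class_names), counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """trace/total — the multiclass form of (TP+TN)/total."""
    if cm.total == 0:
        raise ValueError("cannot compute accuracy of an empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


@dataclass
class FoldResult:
    """One held-out participant's evaluation."""

    held_out_participant: str
    matrices: dict[int, ConfusionMatrix | None]
    accuracies: dict[int, float | None]
    warnings: list[str] = field(default_factory=list)
    norm_stats: object | None = None  # training-fold NormStats (leakage audit)


def _loocv_segments(
    by_participant: Mapping[str, SegmentSet],
    config: ModelConfig,
    transitions: bool,
    levels: Sequence[int] = LEVELS,
) -> list[FoldResult]:
    """LOOCV over precomputed per-participant segment sets."""
    if len(by_participant) < 2:
        raise ValueError("leave-one-out needs at least 2 participants")
    if not transitions:
        by_participant = {p: drop_other(s) for p, s in by_participant.items()}

    participants = list(by_participant)
    folds = []
    for held_out in participants:
        test = by_participant[held_out]
        train_sets = [by_participant[p] for p in participants if p != held_out]
        fold = FoldResult(held_out, {}, {})
        if len(test) == 0:
            fold.warnings.append("no test segments for this participant; fold skipped")
            fold.matrices = {lvl: None for lvl in levels}
            fold.accuracies = {lvl: None for lvl in levels}
            warnings.warn(f"fold {held_out}: no test segments, skipped", stacklevel=2)
            folds.append(fold)
            continue
        train_all = concat_segment_sets(train_sets)
        # normalization statistics come from the training fold only
        train_norm, stats = normalize(train_all)
        test_norm, _ = normalize(test, stats)
        fold.norm_stats = stats
        classes_by_level = {
            lvl: taxonomy_classes(lvl, include_other=transitions) for lvl in levels
        }
        for lvl in levels:
            fold_seed = derive_seed(config.seed, held_out, lvl, transitions)
            mdl = build_model(
                replace(config, seed=fold_seed),
                train_norm.locations,
                classes_by_level[lvl],
                level=lvl,
            )
            mdl.norm_stats = stats
            train(mdl, train_norm, level=lvl)
            pred, _ = predict(mdl, test_norm)
            cm = confusion_matrix(
                list(test_norm.labels_at(lvl)), pred, classes_by_level[lvl]
            )
            fold.matrices[lvl] = cm
            fold.accuracies[lvl] = accuracy(cm)
        folds.append(fold)
    return folds


def loocv(
    sessions: Sequence[RecordingSession],
    config: ModelConfig,
    locations: Sequence[SensorLocation] | None = None,
    transitions: bool = False,
    levels: Sequence[int] = LEVELS,
    window: int = DEFAULT_WINDOW,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> list[FoldResult]:
    """Leave-one-participant-out cross-validation over aligned sessions.

    The held-out participant contributes nothing to training data or
    normalization statistics.
    """
    by_participant = {
        s.participant_id: segment_session(s, locations, window, overlap_fraction)
        for s in sessions
    }
    if len(by_participant) != len(sessions):
        raise ValueError("duplicate participant ids")
    return _loocv_segments(by_participant, config, transitions, levels)


def average_results(
    folds: Sequence[FoldResult],
) -> dict[int, tuple[float, ConfusionMatrix]]:
    """Unweighted per-participant mean accuracy and element-wise mean matrix.

    Skipped folds (no test segments) are excluded from the averages.
    """
    if not folds:
        raise ValueError("no folds to average")
    levels = sorted(folds[0].accuracies)
    out = {}
    for lvl in levels:
        valid = [f for f in folds if f.accuracies.get(lvl) is not None]
        if not valid:
            raise ValueError(f"no evaluable folds at level {lvl}")
        mean_acc = float(np.mean([f.accuracies[lvl] for f in valid]))
        mean_counts = np.mean([f.matrices[lvl].counts for f in valid], axis=0)
        out[lvl] = (
            mean_acc,
            ConfusionMatrix(valid[0].matrices[lvl].class_names, mean_counts),
        )
    return out


def enumerate_subsets(size: int) -> list[tuple[SensorLocation, ...]]:
    """All C(6, size) location subsets, canonical order, lexicographic."""
    if not 1 <= size <= len(ALL_LOCATIONS):
        raise ValueError(f"subset size must be in 1..{len(ALL_LOCATIONS)}, got {size}")
    return list(itertools.combinations(ALL_LOCATIONS, size))


@dataclass
class AblationReport:
    """Per-subset LOOCV accuracies plus per-size summary rows."""

    transitions: bool
    levels: tuple[int, ...]
    accuracies: dict[tuple[SensorLocation, ...], dict[int, float]]
    fold_warnings: dict[tuple[SensorLocation, ...], list[str]] = field(
        default_factory=dict
    )

    @property
    def n_subsets(self) -> int:
        return len(self.accuracies)

    def subset_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subset": "+".join(l.value for l in subset),
                "n_sensors": len(subset),
                **{f"level{lvl}_accuracy": acc[lvl] for lvl in self.levels},
            }
            for subset, acc in self.accuracies.items()
        ]
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        """Rows per (subset size, level): mean, min, max, best, worst."""
        rows = []
        for size in sorted({len(s) for s in self.accuracies}):
            subsets = [s for s in self.accuracies if len(s) == size]
            for lvl in self.levels:
                accs = {s: self.accuracies[s][lvl] for s in subsets}
                best = max(accs, key=accs.get)
                worst = min(accs, key=accs.get)
                rows.append(
                    {
                        "n_sensors": size,
                        "n_combinations": len(subsets),
                        "level": lvl,
                        "mean_accuracy": float(np.mean(list(accs.values()))),
                        "min_accuracy": accs[worst],
                        "max_accuracy": accs[best],
                        "best_subset": "+".join(l.value for l in best),
                        "worst_subset": "+".join(l.value for l in worst),
                    }
                )
        return pd.DataFrame(rows)


def run_ablation(
    sessions: Sequence[RecordingSession],
    config: ModelConfig,
    transitions: bool = False,
    levels: Sequence[int] = LEVELS,
    subset_sizes: Sequence[int] = (1, 2, 3, 4, 5, 6),
    window: int = DEFAULT_WINDOW,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> AblationReport:
    """Exhaustive sensor-subset evaluation.

    Sessions are segmented once with all six locations; each subset is a
    row-restriction of the same windows, so differences between subsets
    are attributable to the sensors alone.
    """
    full = {
        s.participant_id: segment_session(s, None, window, overlap_fraction)
        for s in sessions
    }
    report = AblationReport(transitions=transitions, levels=tuple(levels), accuracies={})
    for size in subset_sizes:
        for subset in enumerate_subsets(size):
            per_part = {p: select_locations(s, subset) for p, s in full.items()}
            folds = _loocv_segments(per_part, config, transitions, levels)
            averaged = average_results(folds)
            report.accuracies[subset] = {lvl: averaged[lvl][0] for lvl in levels}
            warns = [w for f in folds for w in f.warnings]
            if warns:
                report.fold_warnings[subset] = warns
    return report
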
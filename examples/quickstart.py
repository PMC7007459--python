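"""Generate a small synthetic cohort, align it, train a level-1
classifier and evaluate it on a held-out dancer.

Run:  python examples/quickstart.py
"""

from dancehar import (
    GeneratorConfig,
    ModelConfig,
    accuracy,
    build_model,
    confusion_matrix,
    concat_segment_sets,
    drop_other,
    generate_session,
    normalize,
    predict,
    prepare_sessions,
    segment_session,
    train,
)
from dancehar.taxonomy import class_names

# Three synthetic dancers; sensors carry random 0-2 s clock offsets.
gen = GeneratorConfig(n_participants=3, seed=42)
sessions = [generate_session(gen, i) for i in range(3)]

# Detect the heel-raise prelude on every stream and align to the
# annotation timeline.
aligned, report = prepare_sessions(sessions)
for pid, entry in report.items():
    print(f"{pid}: per-sensor shifts {entry['shifts']} (frames at 100 Hz)")

# 1-s windows at 75% overlap, one label per level; drop transition
# windows ("other") for the without-transitions variant.
segments = {s.participant_id: segment_session(s) for s in aligned}
train_set = drop_other(concat_segment_sets([segments["P01"], segments["P02"]]))
test_set = drop_other(segments["P03"])
print(f"training windows: {len(train_set)}, held-out windows: {len(test_set)}")

# z-score with TRAINING statistics only, then train a small level-1
# classifier (jump vs leg lift).
train_norm, stats = normalize(train_set)
test_norm, _ = normalize(test_set, stats)
config = ModelConfig(
    conv1_filters=8, conv2_filters=16, dense_units=64,
    epochs=6, learning_rate=2e-3, seed=7, class_weighting=False,
)
model = build_model(config, train_norm.locations, class_names(1, include_other=False), level=1)
train(model, train_norm)
print(f"final training loss {model.training_log[-1]['loss']:.4f}")

pred, _ = predict(model, test_norm)
cm = confusion_matrix(list(test_norm.labels_at(1)), pred, model.class_names)
print(cm.to_frame())
print(f"held-out dancer accuracy: {accuracy(cm):.3f}")
# Rows are true classes, columns predictions; the accuracy is the
# fraction of 1-s windows of an unseen dancer classified correctly.
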
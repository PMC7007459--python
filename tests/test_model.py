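"""Classifier geometry, determinism, normalization and learning."""

import copy

import numpy as np
import pytest

from dancehar import (
    ModelConfig,
    build_model,
    load_model,
    normalize,
    predict,
    save_model,
    train,
)
from dancehar import nn
from dancehar.segmentation import SegmentSet
from dancehar.session import ALL_LOCATIONS


def toy_segments(n, locations, seed=0, separation=5.0, window=100):
    """Two-class set: class b carries a big bump on every channel."""
    rng = np.random.default_rng(seed)
    rows = 9 * len(locations)
    data = rng.standard_normal((n, rows, window))
    labels = np.array(["a" if i % 2 == 0 else "b" for i in range(n)], dtype=object)
    bump = np.sin(np.linspace(0, np.pi, 30))
    for i in range(n):
        if labels[i] == "b":
            data[i, :, 30:60] += separation * bump
    return SegmentSet(
        data=data,
        labels={1: labels, 2: labels.copy(), 3: labels.copy()},
        start_frames=np.arange(n) * 25,
        participant_ids=np.array(["P"] * n, dtype=object),
        locations=tuple(locations),
        window=window,
    )


def small_config(**kw):
    defaults = dict(
        conv1_filters=4, conv2_filters=8, dense_units=16,
        epochs=4, batch_size=32, learning_rate=2e-3, seed=9,
        class_weighting=False, dropout=0.2,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


@pytest.mark.parametrize("n_loc", [1, 2, 3, 4, 5, 6])
def test_layer1_vertical_positions_equal_locations(n_loc):
    """With 25×9 / 10×9 filters at channel stride 9, layer 1 has one
    vertical filter position per sensor location."""
    model = build_model(small_config(), n_loc, ["a", "b"])
    geom = model.layer_geometry()
    assert geom["conv1_vertical_positions"] == n_loc
    assert geom["conv1_time_positions"] == 76
    assert geom["conv2_time_positions"] == 67
    # forward pass agrees with the bookkeeping
    x = np.zeros((2, 9 * n_loc, 100), dtype=np.float32)
    logits, cache = nn.forward(model.params, x, 25, 10)
    L, T1, T2 = cache[-1]
    assert (L, T1, T2) == (n_loc, 76, 67)
    assert logits.shape == (2, 2)


def test_fewer_than_two_classes_rejected():
    with pytest.raises(ValueError, match="2 classes"):
        build_model(small_config(), 2, ["only"])


def test_equal_seed_identical_initialization():
    m1 = build_model(small_config(seed=3), 2, ["a", "b"])
    m2 = build_model(small_config(seed=3), 2, ["a", "b"])
    for k in m1.params:
        np.testing.assert_array_equal(m1.params[k], m2.params[k])
    m3 = build_model(small_config(seed=4), 2, ["a", "b"])
    assert any(not np.array_equal(m1.params[k], m3.params[k]) for k in m1.params)


def test_zero_epochs_leaves_parameters_unchanged():
    locs = ALL_LOCATIONS[:2]
    segs = toy_segments(16, locs)
    model = build_model(small_config(epochs=0), locs, ["a", "b"])
    before = copy.deepcopy(model.params)
    train(model, segs)
    for k in before:
        np.testing.assert_array_equal(model.params[k], before[k])


def test_training_is_deterministic():
    """Identical seed + data give bit-identical losses and parameters."""
    locs = ALL_LOCATIONS[:1]
    results = []
    for _ in range(2):
        model = build_model(small_config(epochs=2), locs, ["a", "b"])
        train(model, toy_segments(32, locs, seed=1))
        results.append((model.training_log, model.params))
    assert results[0][0] == results[1][0]
    for k in results[0][1]:
        np.testing.assert_array_equal(results[0][1][k], results[1][1][k])


def test_learns_separable_data_and_generalizes():
    locs = ALL_LOCATIONS[:1]
    model = build_model(small_config(epochs=30, batch_size=16), locs, ["a", "b"])
    train_set, _ = normalize(toy_segments(96, locs, seed=2))
    train(model, train_set)
    assert model.training_log[-1]["accuracy"] >= 0.99
    held_out, _ = normalize(toy_segments(40, locs, seed=3))
    pred, probs = predict(model, held_out)
    acc = np.mean(np.array(pred) == held_out.labels[1])
    assert acc >= 0.95
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_loss_decreases_early():
    """Mean loss does not increase over at least 2 of the first 3
    epoch transitions on separable data."""
    locs = ALL_LOCATIONS[:1]
    model = build_model(small_config(epochs=4), locs, ["a", "b"])
    train(model, toy_segments(64, locs, seed=4))
    losses = [e["loss"] for e in model.training_log]
    assert all(np.isfinite(losses))
    non_increase = sum(losses[i + 1] <= losses[i] for i in range(3))
    assert non_increase >= 2


def test_duplicated_segment_identical_predictions():
    locs = ALL_LOCATIONS[:1]
    model = build_model(small_config(epochs=1), locs, ["a", "b"])
    segs = toy_segments(10, locs, seed=5)
    one = segs.data[:1]
    dup = SegmentSet(
        data=np.repeat(one, 10, axis=0),
        labels={lvl: np.array(["a"] * 10, dtype=object) for lvl in (1, 2, 3)},
        start_frames=np.zeros(10, dtype=int),
        participant_ids=np.array(["P"] * 10, dtype=object),
        locations=locs,
    )
    pred, probs = predict(model, dup)
    assert len(set(pred)) == 1
    np.testing.assert_array_equal(probs, np.repeat(probs[:1], 10, axis=0))


def test_geometry_mismatch_names_shapes():
    model = build_model(small_config(), 2, ["a", "b"])
    segs = toy_segments(4, ALL_LOCATIONS[:3])
    with pytest.raises(ValueError, match="18"):
        predict(model, segs)


def test_gradients_match_finite_differences():
    """Backprop gradients agree with central finite differences."""
    rng = np.random.default_rng(0)
    params = nn.init_params(
        n_locations=1, n_classes=3, conv1_filters=2, conv1_time=5,
        conv2_filters=3, conv2_time=3, dense_units=4, rng=rng,
    )
    params = {k: v.astype(np.float64) for k, v in params.items()}
    x = rng.standard_normal((4, 9, 20)).astype(np.float64)
    y = np.array([0, 1, 2, 1])

    def loss_of(p):
        logits, _ = nn.forward(p, x, 5, 3)
        l, _ = nn.cross_entropy(logits.astype(np.float64), y)
        return l

    logits, cache = nn.forward(params, x, 5, 3)
    _, dlogits = nn.cross_entropy(logits.astype(np.float64), y)
    grads = nn.backward(params, cache, dlogits, 5, 3)
    eps = 1e-4
    for name in ("W4", "b3", "W2", "b1", "W1"):
        g = grads[name]
        flat_idx = [0, g.size // 2, g.size - 1]
        for fi in flat_idx:
            idx = np.unravel_index(fi, g.shape)
            p2 = {k: v.copy() for k, v in params.items()}
            p2[name][idx] += eps
            up = loss_of(p2)
            p2[name][idx] -= 2 * eps
            down = loss_of(p2)
            numeric = (up - down) / (2 * eps)
            assert numeric == pytest.approx(float(g[idx]), rel=2e-2, abs=1e-5)


# --- normalization ---------------------------------------------------------

def test_normalize_constant_channel_warns_and_zeroes():
    locs = ALL_LOCATIONS[:1]
    segs = toy_segments(8, locs, seed=6)
    segs.data[:, 0, :] = 3.14
    with pytest.warns(UserWarning, match="zero-variance"):
        normed, stats = normalize(segs)
    np.testing.assert_allclose(normed.data[:, 0, :], 0.0, atol=1e-9)
    assert stats.sd[0] == 1.0


def test_normalize_self_application_is_standard():
    locs = ALL_LOCATIONS[:2]
    segs = toy_segments(32, locs, seed=7)
    normed, stats = normalize(segs)
    np.testing.assert_allclose(normed.data.mean(axis=(0, 2)), 0.0, atol=1e-6)
    np.testing.assert_allclose(normed.data.std(axis=(0, 2)), 1.0, atol=1e-6)


def test_normalize_stats_do_not_leak_between_sets():
    locs = ALL_LOCATIONS[:1]
    a = toy_segments(16, locs, seed=8)
    b = toy_segments(16, locs, seed=9)
    b.data *= 10.0
    _, stats_a = normalize(a)
    _, stats_b = normalize(b)
    assert not np.allclose(stats_a.sd, stats_b.sd)
    b_with_a, _ = normalize(b, stats_a)
    assert b_with_a.data.std() > 5.0  # A's stats do not whiten B


def test_model_save_load_round_trip(tmp_path):
    locs = ALL_LOCATIONS[:2]
    model = build_model(small_config(epochs=1), locs, ["a", "b"])
    segs, stats = normalize(toy_segments(16, locs, seed=10))
    model.norm_stats = stats
    train(model, segs)
    path = tmp_path / "model.npz"
    save_model(model, path)
    back = load_model(path)
    assert back.class_names == model.class_names
    assert back.locations == model.locations
    assert back.config == model.config
    for k in model.params:
        np.testing.assert_array_equal(back.params[k], model.params[k])
    pred_a, prob_a = predict(model, segs)
    pred_b, prob_b = predict(back, segs)
    assert pred_a == pred_b
    np.testing.assert_array_equal(prob_a, prob_b)
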
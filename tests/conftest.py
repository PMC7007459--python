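"""Shared fixtures: small synthetic datasets and fast model configs."""

from __future__ import annotations

import pytest

from dancehar import (
    ActivityLabel,
    GeneratorConfig,
    ModelConfig,
    ScriptEntry,
    generate_session,
    prepare_sessions,
)


def tiny_script() -> tuple[ScriptEntry, ...]:
    """A condensed task script covering every level-3 class once or twice."""
    lifts = [
        ScriptEntry(ActivityLabel("leg_lift", d, s), 1, 1.5)
        for d in ("front", "side", "back")
        for s in ("right", "left")
    ]
    jumps = [
        ScriptEntry(ActivityLabel("jump", "bilateral_small", "bilateral"), 2, 0.8),
        ScriptEntry(ActivityLabel("jump", "unilateral_small", "right"), 1, 0.8),
        ScriptEntry(ActivityLabel("jump", "unilateral_small", "left"), 1, 0.8),
        ScriptEntry(ActivityLabel("jump", "leap", "right"), 1, 1.0),
        ScriptEntry(ActivityLabel("jump", "leap", "left"), 1, 1.0),
    ]
    return tuple(lifts + jumps)


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    return GeneratorConfig(n_participants=3, seed=11, script=tiny_script())


@pytest.fixture(scope="session")
def tiny_sessions(tiny_config):
    """Three small unaligned synthetic sessions."""
    return [
        generate_session(tiny_config, i) for i in range(tiny_config.n_participants)
    ]


@pytest.fixture(scope="session")
def aligned_sessions(tiny_sessions):
    aligned, _ = prepare_sessions(tiny_sessions)
    return aligned


@pytest.fixture()
def fast_model_config() -> ModelConfig:
    """A small-capacity configuration for quick training in tests."""
    return ModelConfig(
        conv1_filters=4,
        conv2_filters=8,
        dense_units=32,
        epochs=3,
        batch_size=64,
        learning_rate=2e-3,
        seed=5,
        class_weighting=False,
    )
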
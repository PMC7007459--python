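"""Hierarchical activity-label taxonomy for ballet movement tasks.

Movements are labelled at three nested levels of granularity:

* level 1 — movement family: ``jump`` or ``leg_lift``;
* level 2 — jump type (bilateral-landing small jump, unilateral-landing
  small jump, unilateral-landing large jump a.k.a. leap) or leg-lift
  direction (front, side, back);
* level 3 — laterality: the landing leg for unilateral jumps, the lifted
  leg for leg lifts, ``bilateral`` for bilateral-landing small jumps.

Anything that is not one of these tasks (transition movement, stillness,
walking between exercises) is ``other`` at every level.  Excluding
``other``, the flattened class sets have sizes 2, 6 and 11: level-3
classes are two-part names such as ``"leap_right"`` or ``"front_left"``
because laterality alone does not identify a movement.
"""

from __future__ import annotations

from dataclasses import dataclass

OTHER = "other"

LEVEL1_CLASSES = ("jump", "leg_lift")
JUMP_TYPES = ("bilateral_small", "unilateral_small", "leap")
LIFT_DIRECTIONS = ("front", "side", "back")
LEVEL2_CLASSES = JUMP_TYPES + LIFT_DIRECTIONS

# level2 -> admissible level-3 lateralities
_LATERALITY = {
    "bilateral_small": ("bilateral",),
    "unilateral_small": ("right", "left"),
    "leap": ("right", "left"),
    "front": ("right", "left"),
    "side": ("right", "left"),
    "back": ("right", "left"),
}

LEVEL3_CLASSES = tuple(
    f"{l2}_{l3}" for l2 in LEVEL2_CLASSES for l3 in _LATERALITY[l2]
)

_LEVEL2_TO_LEVEL1 = {l2: "jump" for l2 in JUMP_TYPES}
_LEVEL2_TO_LEVEL1.update({l2: "leg_lift" for l2 in LIFT_DIRECTIONS})


def class_names(level: int, include_other: bool = True) -> tuple[str, ...]:
    """Ordered class vocabulary at a classification level.

    ``other`` (transition movement) is listed last when included.
    """
    if level == 1:
        base = LEVEL1_CLASSES
    elif level == 2:
        base = LEVEL2_CLASSES
    elif level == 3:
        base = LEVEL3_CLASSES
    else:
        raise ValueError(f"level must be 1, 2 or 3, got {level!r}")
    return base + (OTHER,) if include_other else base


@dataclass(frozen=True)
class ActivityLabel:
    """A point in the three-level taxonomy.

    The three fields are the raw per-level values; hierarchy consistency
    is enforced at construction (e.g. a jump cannot have a leg-lift
    direction, a bilateral small jump is always ``bilateral``).
    """

    level1: str
    level2: str
    level3: str

    def __post_init__(self) -> None:
        if self.level1 == OTHER:
            if self.level2 != OTHER or self.level3 != OTHER:
                raise ValueError(
                    f"'other' labels must be 'other' at all levels, got {self}"
                )
            return
        if self.level1 not in _LEVEL2_TO_LEVEL1.values():
            raise ValueError(f"unknown level-1 class {self.level1!r}")
        if self.level2 not in _LATERALITY:
            raise ValueError(f"unknown level-2 class {self.level2!r}")
        if _LEVEL2_TO_LEVEL1[self.level2] != self.level1:
            raise ValueError(
                f"level-2 class {self.level2!r} is not a kind of {self.level1!r}"
            )
        if self.level3 not in _LATERALITY[self.level2]:
            raise ValueError(
                f"laterality {self.level3!r} invalid for {self.level2!r} "
                f"(expected one of {_LATERALITY[self.level2]})"
            )

    @property
    def is_other(self) -> bool:
        return self.level1 == OTHER

    def at_level(self, level: int) -> str:
        return coarsen_label(self, level)


OTHER_LABEL = ActivityLabel(OTHER, OTHER, OTHER)


def coarsen_label(label: ActivityLabel, level: int) -> str:
    """Project a label onto the class set of a classification level."""
    if level not in (1, 2, 3):
        raise ValueError(f"level must be 1, 2 or 3, got {level!r}")
    if label.is_other:
        return OTHER
    if level == 1:
        return label.level1
    if level == 2:
        return label.level2
    return f"{label.level2}_{label.level3}"


def parse_level3_class(name: str) -> ActivityLabel:
    """Inverse of ``coarsen_label(..., 3)``: rebuild the full label."""
    if name == OTHER:
        return OTHER_LABEL
    for l2 in LEVEL2_CLASSES:
        prefix = l2 + "_"
        if name.startswith(prefix):
            l3 = name[len(prefix):]
            return ActivityLabel(_LEVEL2_TO_LEVEL1[l2], l2, l3)
    raise ValueError(f"unknown level-3 class {name!r}")


def coarsen_class(level3_class: str, level: int) -> str:
    """Project a level-3 class *name* onto a coarser level."""
    return coarsen_label(parse_level3_class(level3_class), level)
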
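"""Behaviour class vocabulary.

Scent-marking postures are first-class labels; everything else collapses to a
single ``OTHER`` class.  Fine-grained "other" annotations (walk, run, jump,
stand, lie, sit, shake) are accepted on input and mapped to ``OTHER``.
"""

from __future__ import annotations

from enum import Enum


class BehaviourClass(str, Enum):
    LEFT_LEG = "left_leg"
    RIGHT_LEG = "right_leg"
    SQUAT_URINATE = "squat_urinate"
    SQUAT_DEFAECATE = "squat_defaecate"
    OTHER = "other"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


#: Postures that constitute a scent-marking event.
SCENT_CLASSES = frozenset(
    {
        BehaviourClass.LEFT_LEG,
        BehaviourClass.RIGHT_LEG,
        BehaviourClass.SQUAT_URINATE,
        BehaviourClass.SQUAT_DEFAECATE,
    }
)

#: Fine-grained labels that collapse to OTHER.
FINE_OTHER_LABELS = frozenset(
    {"walk", "run", "jump", "stand", "lie", "sit", "shake"}
)

_ALIASES = {
    "left": BehaviourClass.LEFT_LEG,
    "left_leg_raised": BehaviourClass.LEFT_LEG,
    "right": BehaviourClass.RIGHT_LEG,
    "right_leg_raised": BehaviourClass.RIGHT_LEG,
    "squat": BehaviourClass.SQUAT_URINATE,
    "squat_urination": BehaviourClass.SQUAT_URINATE,
    "defaecate": BehaviourClass.SQUAT_DEFAECATE,
    "defecate": BehaviourClass.SQUAT_DEFAECATE,
    "squat_defecate": BehaviourClass.SQUAT_DEFAECATE,
    "squat_defaecation": BehaviourClass.SQUAT_DEFAECATE,
}


def parse_class(label: str) -> BehaviourClass:
    """Map a raw annotation label to a :class:`BehaviourClass`.

    Fine-grained locomotion/resting labels collapse to ``OTHER``; common
    spelling variants of the scent classes are accepted.
    """
    key = label.strip().lower().replace(" ", "_").replace("-", "_")
    if key in FINE_OTHER_LABELS:
        return BehaviourClass.OTHER
    if key in _ALIASES:
        return _ALIASES[key]
    try:
        return BehaviourClass(key)
    except ValueError:
        raise ValueError(f"unknown behaviour label: {label!r}") from None


def is_scent(cls: BehaviourClass) -> bool:
    return cls in SCENT_CLASSES
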
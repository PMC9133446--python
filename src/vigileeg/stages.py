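"""Vigilance stage alphabet and numeric arousal mapping.

Resting-state EEG vigilance staging distinguishes, per 1-s segment:

* ``0``    — desynchronized active wakefulness (low-amplitude, beta-dominant)
* ``A1``   — relaxed wakefulness, posterior alpha dominance
* ``A2``   — relaxed wakefulness, alpha spreading anteriorly
* ``A3``   — relaxed wakefulness, frontal alpha dominance
* ``B1``   — low-voltage non-alpha drowsiness
* ``B2/3`` — delta/theta-dominant drowsiness
* ``C``    — sleep onset (spindles / K-complexes)

Segments rejected during preprocessing carry the ``ARTIFACT`` symbol.
"""

from __future__ import annotations

STAGE_0 = "0"
STAGE_A1 = "A1"
STAGE_A2 = "A2"
STAGE_A3 = "A3"
STAGE_B1 = "B1"
STAGE_B23 = "B2/3"
STAGE_C = "C"
ARTIFACT = "ARTIFACT"
UNSCORABLE = "UNSCORABLE"

#: Stage order from full wakefulness down to sleep onset.
STAGES: tuple[str, ...] = (
    STAGE_0,
    STAGE_A1,
    STAGE_A2,
    STAGE_A3,
    STAGE_B1,
    STAGE_B23,
    STAGE_C,
)

#: Numeric arousal value per stage: higher = more aroused.  The 7..1
#: mapping (0 -> 7 down to C -> 1) makes the "mean vigilance level" an
#: average arousal score bounded by [1, 7].
STAGE_VALUE: dict[str, int] = {
    STAGE_0: 7,
    STAGE_A1: 6,
    STAGE_A2: 5,
    STAGE_A3: 4,
    STAGE_B1: 3,
    STAGE_B23: 2,
    STAGE_C: 1,
}

STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Stages counted as wakefulness by the arousal stability criteria.
WAKE_STAGES = frozenset({STAGE_0, STAGE_A1, STAGE_A2, STAGE_A3})
A_STAGES = frozenset({STAGE_A1, STAGE_A2, STAGE_A3})
B_STAGES = frozenset({STAGE_B1, STAGE_B23})


def validate_stage(label: str) -> str:
    if label not in STAGE_INDEX:
        raise ValueError(f"unknown vigilance stage label: {label!r}")
    return label
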
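"""Health-state definitions for the BCVA-based Markov model.

The model distinguishes eight levels of best-corrected visual acuity
(ETDRS letters, best vision first) plus an absorbing death state.
"""

from __future__ import annotations

#: BCVA bands, ordered best -> worst vision.
BCVA_LABELS: tuple[str, ...] = (
    ">85", "76-85", "66-75", "56-65", "46-55", "36-45", "26-35", "<=25",
)

#: Full state space: the eight BCVA bands followed by death.
STATE_LABELS: tuple[str, ...] = BCVA_LABELS + ("Death",)

N_ALIVE = 8
N_STATES = 9
DEATH = 8  # index of the absorbing death state

#: Indices of the low-vision states (BCVA <= 35 letters) that attract
#: the per-cycle low-vision healthcare cost.
LOW_VISION_STATES: tuple[int, ...] = (6, 7)

#: Treated-eye configurations of the alive cohort.
EYE_CONFIGS: tuple[str, ...] = ("both", "wse", "bse")


def state_index(label: str) -> int:
    """Return the ordinal index of a state label."""
    return STATE_LABELS.index(label)
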
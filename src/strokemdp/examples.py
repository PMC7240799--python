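"""Small worked-example fixtures reused by tests and the acceptance report."""

from __future__ import annotations

from .cohort_model import PatientAttributes, compute_reward, encode_state, grade_score
from .episode_builder import EpisodeStep

#: (action, score_before, score_after, multiplicity) behind the published
#: outcome table for pretreatment state 120223 (33 transitions in total)
REFERENCE_ROWS: tuple[tuple[str, int, int, int], ...] = (
    ("111", 8, 5, 17),
    ("111", 8, 7, 1),
    ("001", 8, 8, 11),
    ("101", 8, 8, 4),
)

REFERENCE_STATE = "120223"


def reference_transitions() -> list[EpisodeStep]:
    """The 33-transition worked example out of state ``120223``.

    Each transition is attributed to its own patient at day 1; scores are
    one consistent realisation of the published rewards (3, 1, 0, 0).
    """
    steps: list[EpisodeStep] = []
    pid = 0
    for action, before, after, multiplicity in REFERENCE_ROWS:
        for _ in range(multiplicity):
            state = encode_state(PatientAttributes(1, 2, 0, 2, 2, grade_score(before)))
            next_state = encode_state(PatientAttributes(1, 2, 0, 2, 2, grade_score(after)))
            steps.append(
                EpisodeStep(
                    patient_id=f"W{pid:03d}",
                    day=1,
                    state=state,
                    action=action,
                    reward=compute_reward(before, after),
                    next_state=next_state,
                    terminal=1,
                )
            )
            pid += 1
    assert steps[0].state == REFERENCE_STATE
    return steps
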
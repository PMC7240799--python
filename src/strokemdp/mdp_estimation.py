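"""Frequency estimation of the finite MDP from observed decision steps.

Transition probabilities are plain conditional frequencies
``P(s'|s,a) = count(s,a,s') / count(s,a)`` and rewards are arithmetic
means of the observed score differentials; nothing is smoothed, so only
observed (state, action) pairs carry estimates.  The outcome table
additionally reports JOINT frequencies over (action, next state) given
the pretreatment state — the published presentation, whose column sums
to 1 per state.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .episode_builder import EpisodeStep
from .errors import EstimationError

Triple = tuple[str, str, str]
Pair = tuple[str, str]


@dataclass
class TransitionModel:
    """Counts, conditional probabilities and mean rewards of the observed MDP."""

    counts: dict[Triple, int]
    probs: dict[Triple, float]
    rewards: dict[Triple, float]
    support: dict[Pair, int]
    states: frozenset[str]
    actions: frozenset[str]
    _successors: dict[Pair, list[tuple[str, float, float]]] = field(
        default=None, repr=False, compare=False
    )

    def supported_actions(self, state: str) -> tuple[str, ...]:
        """Actions observed at ``state``, sorted lexicographically."""
        return tuple(sorted(a for (s, a) in self.support if s == state))

    def successors(self, state: str, action: str) -> list[tuple[str, float, float]]:
        """(next_state, probability, mean reward) triples for one pair."""
        if self._successors is None:
            succ: dict[Pair, list[tuple[str, float, float]]] = defaultdict(list)
            for (s, a, s2) in sorted(self.counts):
                succ[(s, a)].append((s2, self.probs[(s, a, s2)], self.rewards[(s, a, s2)]))
            self._successors = dict(succ)
        return self._successors.get((state, action), [])

    @property
    def n_steps(self) -> int:
        return sum(self.counts.values())


def estimate_model(steps: list[EpisodeStep]) -> TransitionModel:
    """Exact frequency estimates over the observed steps."""
    if not steps:
        raise EstimationError("cannot estimate a transition model from zero steps")
    counts: dict[Triple, int] = defaultdict(int)
    reward_sums: dict[Triple, float] = defaultdict(float)
    support: dict[Pair, int] = defaultdict(int)
    states: set[str] = set()
    actions: set[str] = set()
    for step in steps:
        key = (step.state, step.action, step.next_state)
        counts[key] += 1
        reward_sums[key] += step.reward
        support[(step.state, step.action)] += 1
        states.add(step.state)
        states.add(step.next_state)
        actions.add(step.action)
    probs = {k: c / support[(k[0], k[1])] for k, c in counts.items()}
    rewards = {k: reward_sums[k] / c for k, c in counts.items()}
    return TransitionModel(
        counts=dict(counts),
        probs=probs,
        rewards=rewards,
        support=dict(support),
        states=frozenset(states),
        actions=frozenset(actions),
    )


def _truncate4(count: int, total: int) -> float:
    """Joint frequency truncated (not rounded) to 4 decimals, as published."""
    return (count * 10_000 // total) / 10_000


def joint_outcome_table(steps: list[EpisodeStep], state: str) -> pd.DataFrame:
    """Outcome table for one pretreatment state.

    One row per observed (action, next_state) pair with the display-level
    mean reward (nearest integer) and the joint frequency
    count / total-steps-from-state truncated to 4 decimals, so the
    frequency column sums to 1 up to truncation.
    """
    from_state = [s for s in steps if s.state == state]
    if not from_state:
        raise LookupError(f"state {state!r} never observed as a pretreatment state")
    total = len(from_state)
    counts: dict[Pair, int] = defaultdict(int)
    reward_sums: dict[Pair, float] = defaultdict(float)
    for s in from_state:
        counts[(s.action, s.next_state)] += 1
        reward_sums[(s.action, s.next_state)] += s.reward
    rows = [
        {
            "action": action,
            "next_state": next_state,
            "reward": int(round(reward_sums[(action, next_state)] / c)),
            "frequency": _truncate4(c, total),
        }
        for (action, next_state), c in counts.items()
    ]
    frame = pd.DataFrame(rows, columns=["action", "next_state", "reward", "frequency"])
    return frame.sort_values(
        ["frequency", "action", "next_state"], ascending=[False, True, True]
    ).reset_index(drop=True)


def state_inventory(steps: list[EpisodeStep]) -> pd.DataFrame:
    """Distinct pretreatment states with patient counts and observed actions.

    Sorted by patient count descending, then state code; empty input
    yields an empty table.
    """
    patients: dict[str, set[str]] = defaultdict(set)
    actions: dict[str, set[str]] = defaultdict(set)
    for s in steps:
        patients[s.state].add(s.patient_id)
        actions[s.state].add(s.action)
    rows = [
        {
            "state": state,
            "n_patients": len(patients[state]),
            "actions": ",".join(sorted(actions[state])),
        }
        for state in patients
    ]
    frame = pd.DataFrame(rows, columns=["state", "n_patients", "actions"])
    if len(frame):
        frame = frame.sort_values(
            ["n_patients", "state"], ascending=[False, True]
        ).reset_index(drop=True)
    return frame


def model_to_frame(model: TransitionModel) -> pd.DataFrame:
    rows = [
        {
            "state": s,
            "action": a,
            "next_state": s2,
            "count": model.counts[(s, a, s2)],
            "cond_prob": model.probs[(s, a, s2)],
            "mean_reward": model.rewards[(s, a, s2)],
        }
        for (s, a, s2) in sorted(model.counts)
    ]
    return pd.DataFrame(
        rows, columns=["state", "action", "next_state", "count", "cond_prob", "mean_reward"]
    )


def write_model(model: TransitionModel, path) -> None:
    model_to_frame(model).to_csv(path, sep="\t", index=False)


def read_model(path) -> TransitionModel:
    frame = pd.read_csv(
        path, sep="\t", dtype={"state": str, "action": str, "next_state": str}
    )
    counts: dict[Triple, int] = {}
    rewards: dict[Triple, float] = {}
    support: dict[Pair, int] = defaultdict(int)
    for s, a, s2, c, mr in zip(
        frame["state"], frame["action"], frame["next_state"],
        frame["count"], frame["mean_reward"],
    ):
        key = (s, a, s2)
        counts[key] = int(c)
        rewards[key] = float(mr)
        support[(s, a)] += int(c)
    if not counts:
        raise EstimationError(f"model file {path} holds no transitions")
    probs = {k: c / support[(k[0], k[1])] for k, c in counts.items()}
    states = frozenset(s for (s, _, _) in counts) | frozenset(s2 for (_, _, s2) in counts)
    return TransitionModel(
        counts=counts,
        probs=probs,
        rewards=rewards,
        support=dict(support),
        states=states,
        actions=frozenset(a for (_, a, _) in counts),
    )
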
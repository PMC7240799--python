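"""Tabular Monte Carlo control with exploring starts, plus an exact oracle.

Episodes are simulated on the estimated model: the start (state, action)
pair is drawn uniformly over supported pairs, subsequent actions follow
the current greedy policy, and the episode ends on reaching a state with
no supported action or on the horizon cap (21 epochs by default, the
147-day stay at 7-day spacing).  Q(s,a) is the running mean of the
undiscounted returns accumulated at each visit; the policy is the
Q-maximising supported action per state, ties broken by the
lexicographically smallest action code.  ``exact_q`` provides the
finite-horizon backward-induction values used to verify the Monte Carlo
estimate.
"""

from __future__ import annotations

import random
from bisect import bisect_right
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError, SolverError, SupportError
from .mdp_estimation import TransitionModel

EVERY_VISIT = "every_visit"
FIRST_VISIT = "first_visit"

#: paper-faithful Monte Carlo episode budget
DEFAULT_N_EPISODES = 500_000
#: 147-day cap at 7-day spacing -> at most 21 decision epochs per episode
DEFAULT_HORIZON = 21


@dataclass(frozen=True)
class SolverConfig:
    n_episodes: int = DEFAULT_N_EPISODES
    seed: int = 0
    horizon: int = DEFAULT_HORIZON
    visit_mode: str = EVERY_VISIT
    q_init: str = "zeros"

    def __post_init__(self):
        if self.n_episodes < 1:
            raise ConfigError(f"n_episodes must be >= 1, got {self.n_episodes}")
        if self.horizon < 1:
            raise ConfigError(f"horizon must be >= 1, got {self.horizon}")
        if self.visit_mode not in (EVERY_VISIT, FIRST_VISIT):
            raise ConfigError(f"visit_mode must be every_visit|first_visit, got {self.visit_mode!r}")
        if self.q_init not in ("zeros", "random"):
            raise ConfigError(f"q_init must be zeros|random, got {self.q_init!r}")

    @classmethod
    def paper_preset(cls, seed: int = 0) -> "SolverConfig":
        """The study's configuration: 500,000 episodes, random Q init."""
        return cls(n_episodes=DEFAULT_N_EPISODES, seed=seed, q_init="random")

    @classmethod
    def from_dict(cls, raw) -> "SolverConfig":
        return cls(**dict(raw))


@dataclass
class QTable:
    """Action-value estimates and the number of returns averaged into each."""

    values: dict[tuple[str, str], float]
    visit_counts: dict[tuple[str, str], int]

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.values[key]

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Policy:
    """Optimal action per state."""

    actions: dict[str, str]

    def __getitem__(self, state: str) -> str:
        return self.actions[state]

    def get(self, state: str, default=None):
        return self.actions.get(state, default)

    def __len__(self) -> int:
        return len(self.actions)

    def items(self):
        return self.actions.items()


class _Compiled:
    """Index-based view of a TransitionModel for the fast sampling loop."""

    def __init__(self, model: TransitionModel):
        self.states: list[str] = sorted(model.states)
        self.sidx = {s: i for i, s in enumerate(self.states)}
        pairs = sorted(model.support)  # (state, action) lexicographic
        self.pairs: list[tuple[str, str]] = pairs
        self.pidx = {p: i for i, p in enumerate(pairs)}
        # pairs at each state, in lex action order (drives tie-breaking)
        self.state_pairs: list[list[int]] = [[] for _ in self.states]
        for i, (s, _a) in enumerate(pairs):
            self.state_pairs[self.sidx[s]].append(i)
        self.cum: list[list[float]] = []
        self.nxt: list[list[int]] = []
        self.rwd: list[list[float]] = []
        self.pair_state: list[int] = []
        for (s, a) in pairs:
            succ = model.successors(s, a)
            acc, cum, nxt, rwd = 0.0, [], [], []
            for s2, p, r in succ:
                acc += p
                cum.append(acc)
                nxt.append(self.sidx[s2])
                rwd.append(r)
            cum[-1] = max(cum[-1], 1.0)  # guard float undershoot
            self.cum.append(cum)
            self.nxt.append(nxt)
            self.rwd.append(rwd)
            self.pair_state.append(self.sidx[s])


def simulate_episode(
    model: TransitionModel,
    start_state: str,
    start_action: str,
    rng: random.Random,
    policy: Policy | None = None,
    horizon: int = DEFAULT_HORIZON,
) -> list[tuple[str, str, float]]:
    """Roll one episode on the model; returns (state, action, reward) triples.

    The first transition is forced through (start_state, start_action);
    afterwards actions follow ``policy`` where defined and a uniform draw
    over supported actions elsewhere.  Terminates on a state with no
    supported action or after ``horizon`` steps.
    """
    if (start_state, start_action) not in model.support:
        raise SupportError(f"pair ({start_state!r}, {start_action!r}) has no observed support")
    comp = _Compiled(model)
    trajectory: list[tuple[str, str, float]] = []
    pair = comp.pidx[(start_state, start_action)]
    for _ in range(horizon):
        cum, nxt, rwd = comp.cum[pair], comp.nxt[pair], comp.rwd[pair]
        j = min(bisect_right(cum, rng.random()), len(cum) - 1)
        state, action = comp.pairs[pair]
        trajectory.append((state, action, rwd[j]))
        ns = nxt[j]
        candidates = comp.state_pairs[ns]
        if not candidates:
            break
        chosen = policy.get(comp.states[ns]) if policy is not None else None
        if chosen is not None and (comp.states[ns], chosen) in comp.pidx:
            pair = comp.pidx[(comp.states[ns], chosen)]
        else:
            pair = candidates[rng.randrange(len(candidates))]
    return trajectory


def run_mc_control(model: TransitionModel, config: SolverConfig) -> tuple[QTable, Policy]:
    """Monte Carlo control with exploring starts on the estimated model.

    Every episode starts at a uniformly drawn supported (state, action)
    pair and thereafter follows the evolving greedy policy.  The return
    G (undiscounted sum of rewards to episode end) is accumulated for
    each visit of a pair — every visit by default, first visit as a
    config switch — and Q is the running mean.  Fully reproducible from
    the seed.
    """
    if not model.support:
        raise SolverError("model has no supported (state, action) pairs")
    comp = _Compiled(model)
    rng = random.Random(config.seed)
    n_pairs = len(comp.pairs)

    if config.q_init == "random":
        q = [rng.uniform(-1.0, 1.0) for _ in range(n_pairs)]
    else:
        q = [0.0] * n_pairs
    sums = [0.0] * n_pairs
    counts = [0] * n_pairs

    def best_pair(state_i: int) -> int:
        best, best_v = -1, float("-inf")
        for p in comp.state_pairs[state_i]:  # lex action order -> smallest wins ties
            if q[p] > best_v:
                best, best_v = p, q[p]
        return best

    greedy = [best_pair(i) if comp.state_pairs[i] else -1 for i in range(len(comp.states))]
    first_visit = config.visit_mode == FIRST_VISIT
    cum, nxt, rwd = comp.cum, comp.nxt, comp.rwd
    state_pairs = comp.state_pairs

    for _ in range(config.n_episodes):
        pair = rng.randrange(n_pairs)
        traj_pairs: list[int] = []
        traj_rewards: list[float] = []
        for _t in range(config.horizon):
            c = cum[pair]
            j = bisect_right(c, rng.random())
            if j >= len(c):
                j = len(c) - 1
            traj_pairs.append(pair)
            traj_rewards.append(rwd[pair][j])
            ns = nxt[pair][j]
            if not state_pairs[ns]:
                break
            pair = greedy[ns]
        g = 0.0
        if first_visit:
            first_at = {}
            for i, p in enumerate(traj_pairs):
                if p not in first_at:
                    first_at[p] = i
            returns = [0.0] * len(traj_pairs)
            for i in range(len(traj_pairs) - 1, -1, -1):
                g += traj_rewards[i]
                returns[i] = g
            for p, i in first_at.items():
                sums[p] += returns[i]
                counts[p] += 1
                q[p] = sums[p] / counts[p]
        else:
            for i in range(len(traj_pairs) - 1, -1, -1):
                g += traj_rewards[i]
                p = traj_pairs[i]
                sums[p] += g
                counts[p] += 1
                q[p] = sums[p] / counts[p]
        for si in {comp.pair_state[p] for p in traj_pairs}:
            greedy[si] = best_pair(si)

    q_table = QTable(
        values={comp.pairs[i]: q[i] for i in range(n_pairs)},
        visit_counts={comp.pairs[i]: counts[i] for i in range(n_pairs)},
    )
    policy = Policy(
        actions={
            comp.states[i]: comp.pairs[greedy[i]][1]
            for i in range(len(comp.states))
            if greedy[i] >= 0
        }
    )
    return q_table, policy


def exact_q(model: TransitionModel, horizon: int) -> QTable:
    """Finite-horizon optimal action values by backward induction.

    ``Q_1(s,a) = E[R]``; ``Q_{k+1}(s,a) = E[R + max_a' Q_k(s',a')]`` with
    the max over an empty supported-action set equal to 0.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    pairs = sorted(model.support)
    q = {
        (s, a): sum(p * r for _s2, p, r in model.successors(s, a))
        for (s, a) in pairs
    }
    for _ in range(horizon - 1):
        v: dict[str, float] = {}
        for (s, a), value in q.items():
            if s not in v or value > v[s]:
                v[s] = value
        q = {
            (s, a): sum(p * (r + v.get(s2, 0.0)) for s2, p, r in model.successors(s, a))
            for (s, a) in pairs
        }
    return QTable(values=q, visit_counts={pair: 0 for pair in pairs})


def extract_policy(q: QTable) -> Policy:
    """Greedy policy from a Q table; ties go to the smallest action code."""
    best: dict[str, tuple[str, float]] = {}
    for (s, a) in sorted(q.values):
        value = q.values[(s, a)]
        if s not in best or value > best[s][1]:
            best[s] = (a, value)
    return Policy(actions={s: a for s, (a, _v) in best.items()})


def q_to_frame(q: QTable) -> pd.DataFrame:
    rows = [
        {"state": s, "action": a, "q_value": q.values[(s, a)],
         "n_returns": q.visit_counts.get((s, a), 0)}
        for (s, a) in sorted(q.values)
    ]
    return pd.DataFrame(rows, columns=["state", "action", "q_value", "n_returns"])


def policy_to_frame(policy: Policy, q: QTable | None = None) -> pd.DataFrame:
    rows = [
        {"state": s, "optimal_action": a,
         "q_value": q.values.get((s, a)) if q is not None else float("nan")}
        for s, a in sorted(policy.items())
    ]
    return pd.DataFrame(rows, columns=["state", "optimal_action", "q_value"])


def write_q(q: QTable, path) -> None:
    q_to_frame(q).to_csv(path, sep="\t", index=False)


def write_policy(policy: Policy, path, q: QTable | None = None) -> None:
    policy_to_frame(policy, q).to_csv(path, sep="\t", index=False)


def read_policy(path) -> Policy:
    frame = pd.read_csv(path, sep="\t", dtype={"state": str, "optimal_action": str})
    return Policy(actions=dict(zip(frame["state"], frame["optimal_action"])))
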
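"""Shared fixtures: worked-example steps, layered random models, small cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from strokemdp.episode_builder import EpisodeStep
from strokemdp.examples import reference_transitions
from strokemdp.mdp_estimation import TransitionModel, estimate_model
from strokemdp.synthetic_cohort import CohortConfig, EffectModel


@pytest.fixture
def worked_steps() -> list[EpisodeStep]:
    return reference_transitions()


def model_from_counts(
    counts: dict[tuple[str, str, str], int],
    rewards: dict[tuple[str, str, str], float],
) -> TransitionModel:
    """Build a TransitionModel directly from transition counts and rewards."""
    support: dict[tuple[str, str], int] = {}
    for (s, a, _s2), c in counts.items():
        support[(s, a)] = support.get((s, a), 0) + c
    probs = {k: c / support[(k[0], k[1])] for k, c in counts.items()}
    states = frozenset(s for (s, _, _) in counts) | frozenset(s2 for (_, _, s2) in counts)
    return TransitionModel(
        counts=dict(counts),
        probs=probs,
        rewards=dict(rewards),
        support=support,
        states=states,
        actions=frozenset(a for (_, a, _) in counts),
    )


def make_layered_model(seed: int, n_states: int = 5, n_actions: int = 3) -> TransitionModel:
    """Random strictly-forward model: from state i only states >i are reachable.

    The last state is absorbing-terminal (no supported actions), so every
    episode ends within n_states - 1 steps and finite-horizon backward
    induction at that depth gives the exact episodic action values.
    """
    rng = np.random.default_rng(seed)
    states = [f"s{i}" for i in range(n_states)]
    actions = [f"a{j}" for j in range(n_actions)]
    counts: dict[tuple[str, str, str], int] = {}
    rewards: dict[tuple[str, str, str], float] = {}
    for i in range(n_states - 1):
        for a in actions:
            succ = list(range(i + 1, n_states))
            for s2 in succ:
                counts[(states[i], a, states[s2])] = int(rng.integers(1, 30))
                rewards[(states[i], a, states[s2])] = int(rng.integers(-3, 4))
    return model_from_counts(counts, rewards)


def bandit_model(reward_best: float = 3.0, reward_other: float = 0.0) -> TransitionModel:
    """One decision state with two absorbing actions."""
    counts = {("s", "111", "t"): 5, ("s", "000", "t"): 5}
    rewards = {("s", "111", "t"): reward_best, ("s", "000", "t"): reward_other}
    return model_from_counts(counts, rewards)


def recovery_effect_model() -> EffectModel:
    """Strong planted effect (gap 2 points) with modest noise, no deaths."""
    return EffectModel(
        action_effects={"111": 3.0, "001": 1.0},
        baseline_mean=-0.5,
        noise_sd=0.5,
        death_prob=0.0,
    )


def recovery_config(n_patients: int = 5000, seed: int = 20240901) -> CohortConfig:
    return CohortConfig(
        n_patients=n_patients, seed=seed, effect_model=recovery_effect_model()
    )


@pytest.fixture
def small_cohort():
    from strokemdp.synthetic_cohort import generate_cohort

    config = recovery_config(n_patients=400, seed=7)
    patients, visits = generate_cohort(config)
    return config, patients, visits


@pytest.fixture
def worked_model(worked_steps) -> TransitionModel:
    return estimate_model(worked_steps)
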
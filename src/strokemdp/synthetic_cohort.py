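"""Seeded synthetic longitudinal cohorts with a planted optimal treatment.

The generator draws admission attributes from configurable marginal
frequencies (defaulting to the published cohort's Table-1 proportions),
then rolls each patient forward on the 7-day decision grid: every epoch
the logging policy picks a treatment combination, the impairment score
moves by a configurable treatment effect plus noise, and the patient may
die (absorbing, score fixed at 29).  Because the effect model makes one
action strictly best per severity band, the generator also exposes the
ground-truth optimal policy for solver-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_model import (
    ACTION_CODES,
    ATTRIBUTE_DOMAINS,
    LEVEL_BOUNDS,
    DEATH_SCORE,
    MILD,
    MODERATE_TO_SEVERE,
    SCORE_MAX,
    SCORE_MIN,
    SEVERITY_BANDS,
    STATE_FIELDS,
    iter_states,
    decode_state,
)
from .errors import ConfigError

#: category counts from the published cohort's admission table (N = 835;
#: level counts exclude the 31 incomplete records, hence sum to 804)
REFERENCE_COUNTS: dict[str, dict[int, int]] = {
    "age_band": {1: 51, 2: 251, 3: 533},
    "history": {0: 76, 1: 262, 2: 497},
    "complication": {0: 614, 1: 221},
    "diagnosis": {1: 637, 2: 198},
    "syndrome": {1: 13, 2: 498, 3: 64, 4: 227, 5: 33},
    "level": {1: 89, 2: 138, 3: 398, 4: 171, 5: 8},
}

PATIENT_COLUMNS = ("patient_id",) + STATE_FIELDS[:5]
VISIT_COLUMNS = ("patient_id", "day", "score", "a1", "a2", "a3", "death_flag")

#: columns that identify a record or its treatment and are never blanked
PROTECTED_COLUMNS = frozenset({"patient_id", "day", "a1", "a2", "a3", "death_flag"})


def default_marginals() -> dict[str, dict[int, float]]:
    """Per-attribute category frequencies matching the reference cohort."""
    return {
        attr: {cat: n / sum(counts.values()) for cat, n in counts.items()}
        for attr, counts in REFERENCE_COUNTS.items()
    }


def _normalize_action(code) -> str:
    text = str(code).zfill(3)
    if text not in ACTION_CODES:
        raise ConfigError(f"unknown action code {code!r}")
    return text


@dataclass(frozen=True)
class EffectModel:
    """Treatment-response process used to roll scores forward.

    ``action_effects`` gives the mean additional per-epoch score
    improvement of each action (unlisted actions contribute 0);
    ``severity_modifier`` optionally rescales those effects per severity
    band, either by a scalar or per-action.  The resulting expected
    improvement must have a strict maximiser in each band — the planted
    optimum recovered by :func:`planted_policy`.
    """

    action_effects: Mapping[str, float]
    baseline_mean: float = 0.0
    baseline_sd: float = 0.0
    severity_modifier: Mapping[str, object] | None = None
    noise_sd: float = 0.5
    death_prob: float = 0.0

    def __post_init__(self):
        effects = {_normalize_action(a): float(v) for a, v in self.action_effects.items()}
        object.__setattr__(self, "action_effects", effects)
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ConfigError("noise_sd and baseline_sd must be >= 0")
        if not 0.0 <= self.death_prob < 1.0:
            raise ConfigError("death_prob must lie in [0, 1)")
        if self.severity_modifier is not None:
            for band in self.severity_modifier:
                if band not in SEVERITY_BANDS:
                    raise ConfigError(f"unknown severity band {band!r}")
        for band in SEVERITY_BANDS:
            self.planted_action(band)  # raises on a tied maximum

    def effect(self, action: str, band: str) -> float:
        """Mean extra improvement of ``action`` in severity band ``band``."""
        base = self.action_effects.get(_normalize_action(action), 0.0)
        if self.severity_modifier is None:
            return base
        modifier = self.severity_modifier.get(band, 1.0)
        if isinstance(modifier, Mapping):
            return base * float(modifier.get(action, 1.0))
        return base * float(modifier)

    def expected_improvement(self, action: str, band: str) -> float:
        return self.baseline_mean + self.effect(action, band)

    def planted_action(self, band: str) -> str:
        """The strictly best action in ``band``; tie → :class:`ConfigError`."""
        scored = sorted(
            ((self.effect(a, band), a) for a in ACTION_CODES), reverse=True
        )
        (best, code), (runner_up, other) = scored[0], scored[1]
        if math.isclose(best, runner_up, rel_tol=0.0, abs_tol=1e-12):
            raise ConfigError(
                f"effect model has no strict optimum in band {band!r}: "
                f"{code} and {other} tie at {best}"
            )
        return code

    @classmethod
    def from_dict(cls, raw: Mapping) -> "EffectModel":
        known = {
            "action_effects", "baseline_mean", "baseline_sd",
            "severity_modifier", "noise_sd", "death_prob",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown effect_model keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "action_effects" in kwargs:
            kwargs["action_effects"] = {
                _normalize_action(a): v for a, v in kwargs["action_effects"].items()
            }
        if kwargs.get("severity_modifier"):
            kwargs["severity_modifier"] = {
                band: (
                    {_normalize_action(a): v for a, v in mod.items()}
                    if isinstance(mod, Mapping)
                    else mod
                )
                for band, mod in kwargs["severity_modifier"].items()
            }
        return cls(**kwargs)


def default_effect_model() -> EffectModel:
    return EffectModel(
        action_effects={"111": 2.0, "001": 0.75},
        baseline_mean=-0.3,
        noise_sd=0.8,
        death_prob=0.01,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate a cohort reproducibly."""

    n_patients: int
    seed: int = 0
    marginals: Mapping[str, Mapping[int, float]] = field(default_factory=default_marginals)
    effect_model: EffectModel = field(default_factory=default_effect_model)
    max_day: int = 147
    epoch_days: int = 7
    missing_rate: float = 0.0
    logging_policy: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.n_patients < 0:
            raise ConfigError(f"n_patients must be >= 0, got {self.n_patients}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")
        if self.epoch_days < 1 or self.max_day < 1:
            raise ConfigError("epoch_days and max_day must be >= 1")
        marginals: dict[str, dict[int, float]] = {}
        for attr in STATE_FIELDS:
            if attr not in self.marginals:
                raise ConfigError(f"marginals missing attribute {attr!r}")
            freqs = {int(c): float(p) for c, p in self.marginals[attr].items()}
            bad = set(freqs) - set(ATTRIBUTE_DOMAINS[attr])
            if bad:
                raise ConfigError(f"marginals[{attr!r}] has invalid categories {sorted(bad)}")
            if any(p < 0 for p in freqs.values()):
                raise ConfigError(f"marginals[{attr!r}] has negative frequencies")
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"marginals[{attr!r}] sum to {total}, expected 1")
            marginals[attr] = freqs
        object.__setattr__(self, "marginals", marginals)
        if self.logging_policy is not None:
            weights = {_normalize_action(a): float(w) for a, w in self.logging_policy.items()}
            if not weights or any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
                raise ConfigError("logging_policy weights must be non-negative with positive sum")
            object.__setattr__(self, "logging_policy", weights)

    @property
    def epoch_grid(self) -> tuple[int, ...]:
        return tuple(range(1, self.max_day + 1, self.epoch_days))

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CohortConfig":
        kwargs = dict(raw)
        if "effect_model" in kwargs and isinstance(kwargs["effect_model"], Mapping):
            kwargs["effect_model"] = EffectModel.from_dict(kwargs["effect_model"])
        if "logging_policy" in kwargs and kwargs["logging_policy"] is not None:
            kwargs["logging_policy"] = {
                _normalize_action(a): w for a, w in kwargs["logging_policy"].items()
            }
        return cls(**kwargs)


def _draw_categories(rng, attr: str, freqs: Mapping[int, float], size: int) -> np.ndarray:
    cats = np.array(sorted(freqs), dtype=np.int64)
    probs = np.array([freqs[c] for c in sorted(freqs)], dtype=float)
    probs = probs / probs.sum()  # remove the <=1e-9 slack
    return rng.choice(cats, size=size, p=probs)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (patients, visits) tables; byte-identical for equal configs.

    Patients carry the five static admission attributes; visits carry the
    impairment score, the treatment bits chosen for the epoch starting at
    each visit day, and a death flag.  Scores evolve by the configured
    effect model and are clipped to the 0–29 scale; death is absorbing
    with score 29 and terminates the visit sequence.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    em = config.effect_model

    patients = pd.DataFrame({"patient_id": [f"P{i:05d}" for i in range(n)]})
    for attr in STATE_FIELDS[:5]:
        patients[attr] = _draw_categories(rng, attr, config.marginals[attr], n)

    # admission score: draw the level, then uniformly within its interval
    level0 = _draw_categories(rng, "level", config.marginals["level"], n)
    lo = np.array([LEVEL_BOUNDS[lv][0] for lv in level0], dtype=np.int64)
    hi = np.array([LEVEL_BOUNDS[lv][1] for lv in level0], dtype=np.int64)
    scores = rng.integers(lo, hi + 1) if n else np.array([], dtype=np.int64)

    if config.logging_policy is None:
        action_probs = np.full(len(ACTION_CODES), 1.0 / len(ACTION_CODES))
    else:
        weights = np.array([config.logging_policy.get(a, 0.0) for a in ACTION_CODES])
        action_probs = weights / weights.sum()
    action_bits = np.array([[int(c) for c in a] for a in ACTION_CODES], dtype=np.int64)
    # per-action effect by band: row order follows ACTION_CODES
    effect_by_band = {
        band: np.array([em.effect(a, band) for a in ACTION_CODES]) for band in SEVERITY_BANDS
    }
    step_sd = math.hypot(em.baseline_sd, em.noise_sd)

    rows: list[pd.DataFrame] = []
    alive = np.ones(n, dtype=bool)
    ids = patients["patient_id"].to_numpy()
    actions = np.zeros(n, dtype=np.int64)  # index into ACTION_CODES

    for k, day in enumerate(config.epoch_grid):
        if not alive.any():
            break
        idx = np.flatnonzero(alive)
        if k > 0:
            # roll scores of survivors forward under last epoch's action
            band_mild = scores[idx] <= LEVEL_BOUNDS[2][1]
            effects = np.where(
                band_mild,
                effect_by_band[MILD][actions[idx]],
                effect_by_band[MODERATE_TO_SEVERE][actions[idx]],
            )
            improvement = em.baseline_mean + effects
            if step_sd > 0:
                improvement = improvement + rng.normal(0.0, step_sd, size=len(idx))
            new_scores = np.clip(
                scores[idx] - np.round(improvement).astype(np.int64), SCORE_MIN, SCORE_MAX
            )
            died = rng.random(len(idx)) < em.death_prob
            scores[idx] = np.where(died, DEATH_SCORE, new_scores)
        else:
            died = np.zeros(len(idx), dtype=bool)
        actions[idx] = rng.choice(len(ACTION_CODES), size=len(idx), p=action_probs)
        bits = action_bits[actions[idx]]
        bits[died] = 0  # no treatment interval starts at a death record
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": ids[idx],
                    "day": day,
                    "score": scores[idx],
                    "a1": bits[:, 0],
                    "a2": bits[:, 1],
                    "a3": bits[:, 2],
                    "death_flag": died.astype(np.int64),
                }
            )
        )
        alive[idx[died]] = False

    if rows:
        visits = pd.concat(rows, ignore_index=True)
        visits = visits.sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)
    else:
        visits = pd.DataFrame(columns=list(VISIT_COLUMNS)).astype(
            {c: np.int64 for c in VISIT_COLUMNS if c != "patient_id"}
        )

    if config.missing_rate > 0:
        visits = inject_missingness(visits, config.missing_rate, config.seed + 1)
        patients = inject_missingness(patients, config.missing_rate, config.seed + 2)
    return patients, visits


def planted_policy(config: CohortConfig) -> dict[str, str]:
    """Ground-truth optimal action per state under the config's effect model."""
    em = config.effect_model
    best = {band: em.planted_action(band) for band in SEVERITY_BANDS}
    return {code: best[decode_state(code).band] for code in iter_states()}


def inject_missingness(table: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Independently blank non-protected cells with probability ``rate``.

    Identifier, day, treatment-bit and death-flag columns are never
    blanked; scores on death records are kept (they are fixed at 29 by
    construction).  ``rate`` must lie in [0, 1).
    """
    if not 0.0 <= rate < 1.0:
        raise ConfigError(f"missingness rate must lie in [0, 1), got {rate}")
    if rate == 0.0:
        return table.copy()
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col in table.columns:
        if col in PROTECTED_COLUMNS:
            continue
        mask = rng.random(len(out)) < rate
        if col == "score" and "death_flag" in out.columns:
            mask &= out["death_flag"].to_numpy() == 0
        if mask.any():
            out[col] = out[col].astype("Int64") if out[col].dtype.kind in "iu" else out[col]
            out.loc[mask, col] = pd.NA
    return out


def write_cohort(patients: pd.DataFrame, visits: pd.DataFrame, patients_path, visits_path) -> None:
    patients.to_csv(patients_path, sep="\t", index=False)
    visits.to_csv(visits_path, sep="\t", index=False)


def read_cohort(patients_path, visits_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    patients = pd.read_csv(patients_path, sep="\t", dtype={"patient_id": str})
    visits = pd.read_csv(visits_path, sep="\t", dtype={"patient_id": str})
    return patients, visits
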
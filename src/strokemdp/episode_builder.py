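"""Cleaning, random fill, and conversion of visits into decision steps.

The builder walks each patient's visit sequence on the 7-day epoch grid
(day 1, 8, 15, ... capped at day 147) and emits one
(state, action, reward, next state) step per consecutive epoch pair.
Severity is re-graded from the score at every epoch, death records are
assigned the default score of 29 and terminate the episode, and rewards
are score differentials (before minus after).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_model import (
    ACTION_CODES,
    ATTRIBUTE_DOMAINS,
    DEATH_SCORE,
    LEVEL_BOUNDS,
    SCORE_MAX,
    SCORE_MIN,
    STATE_FIELDS,
)
from .errors import AlignmentError, IntegrityError

logger = logging.getLogger(__name__)

#: columns that identify a record or its treatment; blanks here are fatal
UNFILLABLE_COLUMNS = ("patient_id", "day", "a1", "a2", "a3", "death_flag")

#: per-column valid values for cleaning and uniform random fill
FILL_DOMAINS: dict[str, tuple[int, ...]] = {
    **{attr: ATTRIBUTE_DOMAINS[attr] for attr in STATE_FIELDS[:5]},
    "score": tuple(range(SCORE_MIN, SCORE_MAX + 1)),
}

EPISODE_COLUMNS = ("patient_id", "day", "state", "action", "reward", "next_state", "terminal")


@dataclass(frozen=True)
class EpisodeStep:
    """One (state, action, reward, next state) observation at a decision epoch."""

    patient_id: str
    day: int
    state: str
    action: str
    reward: int
    next_state: str
    terminal: int


def clean_records(visits: pd.DataFrame) -> pd.DataFrame:
    """Drop rows carrying abnormal values; duplicates raise instead.

    Removed: scores outside 0–29, non-binary treatment bits or death
    flags, and out-of-enumeration attribute values.  Blank (missing)
    attribute or score cells are retained for :func:`fill_missing`.
    """
    if {"patient_id", "day"} <= set(visits.columns):
        dupes = visits.loc[visits.duplicated(["patient_id", "day"], keep=False)]
        if len(dupes):
            offenders = sorted(
                set(zip(dupes["patient_id"], dupes["day"])))[:10]
            raise IntegrityError(
                f"duplicate (patient_id, day) rows: {offenders}"
            )
    keep = pd.Series(True, index=visits.index)
    for col, domain in FILL_DOMAINS.items():
        if col in visits.columns:
            keep &= visits[col].isna() | visits[col].isin(domain)
    for col in ("a1", "a2", "a3", "death_flag"):
        if col in visits.columns:
            keep &= visits[col].isin((0, 1))
    removed = int((~keep).sum())
    if removed:
        logger.info("clean_records: removed %d abnormal row(s)", removed)
    return visits.loc[keep].reset_index(drop=True)


def fill_missing(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Replace blank attribute/score cells by uniform draws over their domain.

    Deterministic given ``seed``; identifier, day and treatment columns
    must not be blank (IntegrityError).
    """
    for col in UNFILLABLE_COLUMNS:
        if col in table.columns and table[col].isna().any():
            raise IntegrityError(f"column {col!r} has blank cells and is not fillable")
    rng = np.random.default_rng(seed)
    out = table.copy()
    filled = 0
    for col, domain in FILL_DOMAINS.items():
        if col not in out.columns:
            continue
        blank = out[col].isna()
        n_blank = int(blank.sum())
        if n_blank:
            out.loc[blank, col] = rng.choice(np.array(domain), size=n_blank)
            out[col] = out[col].astype(np.int64)
            filled += n_blank
    if filled:
        logger.info("fill_missing: filled %d blank cell(s)", filled)
    return out


def _grade_vector(scores: np.ndarray) -> np.ndarray:
    """Vectorised score grading; assumes scores already validated to 0..29."""
    cuts = np.array([LEVEL_BOUNDS[lv][0] for lv in (2, 3, 4, 5)])
    return np.digitize(scores, cuts) + 1


def build_episodes(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    epoch_days: int = 7,
    max_day: int = 147,
) -> list[EpisodeStep]:
    """Convert cleaned, filled visit records into decision steps.

    A step is emitted for every consecutive epoch pair (t, t + epoch_days)
    whose start day does not exceed ``max_day``; the endpoint may fall one
    epoch beyond the cap.  Gaps in the grid yield no step across the gap.
    A death record contributes as an endpoint with score 29 and ends the
    episode.  ``terminal`` is set when no step starts at the endpoint.
    """
    if visits.empty:
        return []
    missing_cols = set(("patient_id", "day", "score", "a1", "a2", "a3")) - set(visits.columns)
    if missing_cols:
        raise IntegrityError(f"visit table lacks columns {sorted(missing_cols)}")

    df = visits.merge(patients, on="patient_id", how="left", validate="many_to_one")
    attr_cols = list(STATE_FIELDS[:5])
    if df[attr_cols].isna().any().any():
        orphans = df.loc[df[attr_cols].isna().any(axis=1), "patient_id"].unique()[:10]
        raise IntegrityError(f"visits reference patients without attributes: {list(orphans)}")

    off_grid = (df["day"] - 1) % epoch_days != 0
    if off_grid.any():
        bad = sorted(set(zip(df.loc[off_grid, "patient_id"], df.loc[off_grid, "day"])))[:10]
        raise AlignmentError(
            f"visit days off the (1 + k*{epoch_days}) epoch grid: {bad}"
        )

    df = df.sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)
    if "death_flag" in df.columns:
        # keep rows up to and including the first death; death score is 29
        first_death = df.groupby("patient_id", sort=False)["death_flag"].cumsum()
        df = df.loc[first_death - df["death_flag"] == 0].reset_index(drop=True)
        df.loc[df["death_flag"] == 1, "score"] = DEATH_SCORE
    if df["score"].isna().any():
        raise IntegrityError("blank scores remain; run fill_missing first")

    grp = df.groupby("patient_id", sort=False)
    day = df["day"].to_numpy()
    score = df["score"].to_numpy(dtype=np.int64)
    next_day = grp["day"].shift(-1).to_numpy()
    next_score = grp["score"].shift(-1).to_numpy()

    starts = (
        ~np.isnan(next_day)
        & (next_day - day == epoch_days)
        & (day <= max_day)
    )
    # a step is terminal when no step starts at its endpoint (the row after
    # a valid start always belongs to the same patient)
    terminal = starts & ~np.roll(starts, -1)
    if len(starts):
        terminal[-1] = starts[-1]

    levels = _grade_vector(score)
    prefix = (
        df[attr_cols].astype(np.int64).astype(str).agg("".join, axis=1).to_numpy()
    )
    idx = np.flatnonzero(starts)
    next_levels = _grade_vector(next_score[idx].astype(np.int64))

    steps = [
        EpisodeStep(
            patient_id=str(pid),
            day=int(d),
            state=pref + str(lv),
            action=f"{int(a1)}{int(a2)}{int(a3)}",
            reward=int(s_before - s_after),
            next_state=pref + str(nlv),
            terminal=int(term),
        )
        for pid, d, pref, lv, a1, a2, a3, s_before, s_after, nlv, term in zip(
            df["patient_id"].to_numpy()[idx],
            day[idx],
            prefix[idx],
            levels[idx],
            df["a1"].to_numpy()[idx],
            df["a2"].to_numpy()[idx],
            df["a3"].to_numpy()[idx],
            score[idx],
            next_score[idx].astype(np.int64),
            next_levels,
            terminal[idx],
        )
    ]
    logger.info("build_episodes: %d step(s) from %d visit(s)", len(steps), len(df))
    return steps


def steps_to_frame(steps: list[EpisodeStep]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in steps], columns=list(EPISODE_COLUMNS))


def frame_to_steps(frame: pd.DataFrame) -> list[EpisodeStep]:
    return [
        EpisodeStep(
            patient_id=str(r.patient_id),
            day=int(r.day),
            state=str(r.state),
            action=str(r.action),
            reward=int(r.reward),
            next_state=str(r.next_state),
            terminal=int(r.terminal),
        )
        for r in frame.itertuples(index=False)
    ]


def write_episodes(steps: list[EpisodeStep], path) -> None:
    steps_to_frame(steps).to_csv(path, sep="\t", index=False)


def read_episodes(path) -> list[EpisodeStep]:
    frame = pd.read_csv(
        path, sep="\t", dtype={"patient_id": str, "state": str, "action": str, "next_state": str}
    )
    return frame_to_steps(frame)
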
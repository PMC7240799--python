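"""Stratified decision tables, cohort summaries, and pipeline orchestration.

Decision tables count the *states* (not patients) in a stratum whose
optimal action equals each action code, split by severity band — the
published two-row layout.  An optional weighting by per-state patient
counts is exposed for the alternative reading.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .cohort_model import (
    ATTRIBUTE_DOMAINS,
    SEVERITY_BANDS,
    STATE_FIELDS,
    PatientAttributes,
    decode_state,
    grade_score,
    severity_band,
)
from .errors import ConfigError, PipelineError, SummaryError
from .episode_builder import build_episodes, clean_records, fill_missing, write_episodes
from .mdp_estimation import estimate_model, state_inventory, write_model
from .mdp_solver import Policy, SolverConfig, run_mc_control, write_policy, write_q
from .synthetic_cohort import CohortConfig, generate_cohort, read_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StratumPredicate:
    """Partial constraints over the six state attributes.

    Each constrained attribute maps to a fixed category, a collection of
    allowed categories, or — for ``level`` (alias key ``band``) — a
    severity-band name.  Unconstrained attributes match anything.
    """

    constraints: Mapping[str, object]

    def __post_init__(self):
        normalized: dict[str, object] = {}
        for key, value in self.constraints.items():
            attr = "level" if key == "band" else key
            if attr not in STATE_FIELDS:
                raise ConfigError(f"unknown attribute {key!r} in stratum predicate")
            if attr == "level" and isinstance(value, str):
                if value not in SEVERITY_BANDS:
                    raise ConfigError(f"unknown severity band {value!r}")
                normalized[attr] = value
                continue
            cats = (value,) if isinstance(value, int) else tuple(value)
            bad = [c for c in cats if c not in ATTRIBUTE_DOMAINS[attr]]
            if bad or not cats:
                raise ConfigError(f"invalid categories {bad} for attribute {attr!r}")
            normalized[attr] = frozenset(cats)
        object.__setattr__(self, "constraints", normalized)

    def matches(self, attrs: PatientAttributes) -> bool:
        for attr, allowed in self.constraints.items():
            value = getattr(attrs, attr)
            if isinstance(allowed, str):  # severity band on level
                if severity_band(value) != allowed:
                    return False
            elif value not in allowed:
                return False
        return True


def stratified_decision_table(
    policy: Policy,
    predicate: StratumPredicate,
    band_split: bool = True,
    state_weights: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Frequency of each optimal action among the stratum's policy states.

    Counts states by default; pass ``state_weights`` (e.g. patients per
    state) for the weighted alternative.  Rows are ordered by (band,
    action code).
    """
    rows: dict[tuple[str, str], int] = {}
    for state, action in policy.items():
        attrs = decode_state(state)
        if not predicate.matches(attrs):
            continue
        band = severity_band(attrs.level) if band_split else "all"
        weight = int(state_weights.get(state, 0)) if state_weights is not None else 1
        rows[(band, action)] = rows.get((band, action), 0) + weight
    frame = pd.DataFrame(
        [{"band": b, "action": a, "frequency": f} for (b, a), f in rows.items()],
        columns=["band", "action", "frequency"],
    )
    if len(frame):
        frame = frame.sort_values(["band", "action"]).reset_index(drop=True)
    return frame


#: published-table-shaped default strata
DEFAULT_STRATA: tuple[tuple[str, dict], ...] = (
    ("age18_45_history_no_compl", {"age_band": 1, "history": (1, 2), "complication": 0}),
    ("age46_65_history_no_compl", {"age_band": 2, "history": (1, 2), "complication": 0}),
    ("age66plus_history_no_compl", {"age_band": 3, "history": (1, 2), "complication": 0}),
    ("age66plus_no_history_no_compl", {"age_band": 3, "history": 0, "complication": 0}),
    ("phlegm_blocking", {"syndrome": 2}),
    ("qi_deficiency_blood_stasis", {"syndrome": 4}),
)


def cohort_summary(patients: pd.DataFrame, visits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-attribute n (%) table over the cohort, n-(%) layout.

    Percentages use the full cohort size as denominator and are rounded
    to 2 decimals.  When ``visits`` is given, impairment level is graded
    from each patient's earliest score and summarised too.  Patients with
    any missing summarised cell are tallied in an ``incomplete_data``
    row.  A ``sex`` column, when present, adds per-sex groups.
    """
    if patients is None or patients.empty:
        raise SummaryError("cohort summary needs at least one patient")
    work = patients.copy()
    attr_cols = [c for c in STATE_FIELDS[:5] if c in work.columns]
    if visits is not None and not visits.empty:
        admission = (
            visits.sort_values(["patient_id", "day"]).groupby("patient_id", sort=False).first()
        )
        level = admission["score"].map(
            lambda s: grade_score(int(s)) if pd.notna(s) else pd.NA
        )
        work = work.merge(
            level.rename("level"), left_on="patient_id", right_index=True, how="left"
        )
        attr_cols = attr_cols + ["level"]
    if not attr_cols:
        raise SummaryError("no summarisable attribute columns found")

    groups = [("all", work)]
    if "sex" in work.columns:
        groups += [(str(s), work.loc[work["sex"] == s]) for s in sorted(work["sex"].dropna().unique())]

    rows = []
    for group, frame in groups:
        total = len(frame)
        for attr in attr_cols:
            col = frame[attr]
            for cat in ATTRIBUTE_DOMAINS[attr]:
                n = int((col == cat).sum())
                rows.append(
                    {"group": group, "attribute": attr, "category": cat,
                     "n": n, "pct": round(100.0 * n / total, 2)}
                )
        n_inc = int(frame[attr_cols].isna().any(axis=1).sum())
        rows.append(
            {"group": group, "attribute": "incomplete_data", "category": pd.NA,
             "n": n_inc, "pct": round(100.0 * n_inc / total, 2)}
        )
    return pd.DataFrame(rows, columns=["group", "attribute", "category", "n", "pct"])


def _stage(name: str):
    logger.info("stage=%s start", name)


def run_pipeline(config: Mapping, out_dir) -> dict:
    """Execute synthesize/load → clean → fill → episodes → estimate → solve → report.

    ``config`` mirrors the CLI YAML layout: a top-level ``seed``, either a
    ``synthesis`` section (CohortConfig fields) or an ``inputs`` section
    with ``patients``/``visits`` paths, plus optional ``episodes``,
    ``solver`` and ``report`` sections.  All artifacts land under
    ``out_dir`` together with a JSON manifest; the run is idempotent
    given identical inputs and seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {"seed": seed, "version": __version__, "stages": {}}

    if "inputs" in config:
        for key in ("patients", "visits"):
            path = Path(config["inputs"][key])
            if not path.exists():
                raise FileNotFoundError(f"input file not found: {path}")
    try:
        stage = "synthesize" if "synthesis" in config else "load"
        _stage(stage)
        if "synthesis" in config:
            synth = dict(config["synthesis"])
            synth.setdefault("seed", seed)
            cohort_config = CohortConfig.from_dict(synth)
            patients, visits = generate_cohort(cohort_config)
        else:
            patients, visits = read_cohort(config["inputs"]["patients"], config["inputs"]["visits"])
        write_cohort(patients, visits, out / "patients.tsv", out / "visits.tsv")
        manifest["stages"][stage] = {"n_patients": len(patients), "n_visits": len(visits)}

        stage = "clean"
        _stage(stage)
        n_before = len(visits)
        visits = clean_records(visits)
        manifest["stages"][stage] = {"n_removed": n_before - len(visits)}

        stage = "fill"
        _stage(stage)
        n_blank = int(visits.isna().sum().sum() + patients.isna().sum().sum())
        visits = fill_missing(visits, seed=seed + 1)
        patients = fill_missing(patients, seed=seed + 2)
        manifest["stages"][stage] = {"n_blank_cells": n_blank}

        stage = "episodes"
        _stage(stage)
        epi_cfg = dict(config.get("episodes", {}))
        steps = build_episodes(
            patients, visits,
            epoch_days=int(epi_cfg.get("epoch_days", 7)),
            max_day=int(epi_cfg.get("max_day", 147)),
        )
        write_episodes(steps, out / "episodes.tsv")
        manifest["stages"][stage] = {"n_steps": len(steps)}

        stage = "estimate"
        _stage(stage)
        model = estimate_model(steps)
        write_model(model, out / "model.tsv")
        state_inventory(steps).to_csv(out / "state_inventory.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_states": len(model.states), "n_pairs": len(model.support),
        }

        stage = "solve"
        _stage(stage)
        solver_cfg = dict(config.get("solver", {}))
        solver_cfg.setdefault("seed", seed + 3)
        solver_config = SolverConfig.from_dict(solver_cfg)
        q, policy = run_mc_control(model, solver_config)
        write_q(q, out / "q.tsv")
        write_policy(policy, out / "policy.tsv", q)
        manifest["stages"][stage] = {
            "n_episodes": solver_config.n_episodes,
            "horizon": solver_config.horizon,
            "visit_mode": solver_config.visit_mode,
            "solver_seed": solver_config.seed,
            "n_policy_states": len(policy),
        }

        stage = "report"
        _stage(stage)
        cohort_summary(patients, visits).to_csv(out / "cohort_summary.tsv", sep="\t", index=False)
        report_cfg = config.get("report", {})
        strata = report_cfg.get("strata")
        if strata is None:
            strata = [{"name": name, "constraints": cons} for name, cons in DEFAULT_STRATA]
        table_paths = {}
        for stratum in strata:
            predicate = StratumPredicate(stratum["constraints"])
            table = stratified_decision_table(
                policy, predicate, band_split=bool(stratum.get("band_split", True))
            )
            path = out / f"decisions_{stratum['name']}.tsv"
            table.to_csv(path, sep="\t", index=False)
            table_paths[stratum["name"]] = str(path)
        manifest["stages"][stage] = {"strata": sorted(table_paths)}
    except (PipelineError, FileNotFoundError):
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "out_dir": str(out),
        "manifest": manifest,
        "policy": policy,
        "q": q,
        "model": model,
        "steps": steps,
        "patients": patients,
        "visits": visits,
    }
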
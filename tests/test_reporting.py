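"""Stratified decision tables, cohort summaries, pipeline orchestration."""

import json

import numpy as np
import pandas as pd
import pytest

from strokemdp.cohort_model import ACTION_CODES, MILD, MODERATE_TO_SEVERE
from strokemdp.errors import ConfigError, SummaryError
from strokemdp.mdp_solver import Policy
from strokemdp.reporting import (
    StratumPredicate,
    cohort_summary,
    run_pipeline,
    stratified_decision_table,
)
from strokemdp.synthetic_cohort import REFERENCE_COUNTS


def table1_patients() -> pd.DataFrame:
    """A patient table realising the published marginal counts (N = 835)."""
    n = 835
    frame = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)]})
    for attr in ("age_band", "history", "complication", "diagnosis", "syndrome"):
        values = []
        for cat, count in sorted(REFERENCE_COUNTS[attr].items()):
            values += [cat] * count
        frame[attr] = values
    return frame


class TestStratumPredicate:
    def test_scalar_and_set_constraints(self):
        predicate = StratumPredicate({"age_band": 3, "history": (1, 2), "complication": 0})
        from strokemdp.cohort_model import decode_state

        assert predicate.matches(decode_state("320123"))
        assert not predicate.matches(decode_state("220123"))  # wrong age
        assert not predicate.matches(decode_state("300123"))  # no history
        assert not predicate.matches(decode_state("321123"))  # complication

    def test_band_constraint(self):
        predicate = StratumPredicate({"band": MILD})
        from strokemdp.cohort_model import decode_state

        assert predicate.matches(decode_state("320122"))
        assert not predicate.matches(decode_state("320123"))

    def test_unknown_attribute_rejected(self):
        with pytest.raises(ConfigError):
            StratumPredicate({"bogus": 1})

    def test_invalid_category_rejected(self):
        with pytest.raises(ConfigError):
            StratumPredicate({"age_band": 9})

    def test_invalid_band_rejected(self):
        with pytest.raises(ConfigError):
            StratumPredicate({"band": "severe-ish"})


class TestDecisionTable:
    def test_direct_count(self):
        policy = Policy(actions={"320122": "001", "320112": "001", "320123": "100"})
        predicate = StratumPredicate({"age_band": 3, "complication": 0})
        table = stratified_decision_table(policy, predicate)
        table = table.set_index(["band", "action"])["frequency"]
        assert table[(MILD, "001")] == 2
        assert table[(MODERATE_TO_SEVERE, "100")] == 1

    def test_empty_stratum(self):
        policy = Policy(actions={"320123": "001"})
        table = stratified_decision_table(policy, StratumPredicate({"age_band": 1}))
        assert table.empty

    def test_syndrome_stratum_ignores_other_attributes(self):
        policy = Policy(actions={"120223": "111", "320223": "111", "110113": "000"})
        table = stratified_decision_table(policy, StratumPredicate({"syndrome": 2}))
        assert table["frequency"].sum() == 2

    def test_conservation_over_actions_and_bands(self):
        rng = np.random.default_rng(0)
        from strokemdp.cohort_model import iter_states

        states = list(iter_states())
        policy = Policy(actions={s: ACTION_CODES[rng.integers(8)] for s in states})
        predicate = StratumPredicate({"complication": 0})
        table = stratified_decision_table(policy, predicate)
        matching = sum(1 for s in states if s[2] == "0")
        assert table["frequency"].sum() == matching

    def test_state_weights(self):
        policy = Policy(actions={"320122": "001", "320112": "001"})
        predicate = StratumPredicate({"age_band": 3})
        table = stratified_decision_table(
            policy, predicate, state_weights={"320122": 10, "320112": 5}
        )
        assert table["frequency"].sum() == 15

    def test_no_band_split(self):
        policy = Policy(actions={"320122": "001", "320123": "001"})
        table = stratified_decision_table(
            policy, StratumPredicate({}), band_split=False
        )
        assert list(table["band"]) == ["all"]
        assert table.iloc[0]["frequency"] == 2


class TestCohortSummary:
    def test_published_marginals_reproduced(self):
        summary = cohort_summary(table1_patients())
        rows = summary.set_index(["attribute", "category"])
        assert rows.loc[("age_band", 3), "n"].item() == 533
        assert rows.loc[("age_band", 3), "pct"].item() == 63.83
        assert rows.loc[("age_band", 1), "pct"].item() == 6.11
        assert rows.loc[("history", 2), "pct"].item() == 59.52
        assert rows.loc[("complication", 0), "pct"].item() == 73.53
        assert rows.loc[("diagnosis", 1), "pct"].item() == 76.29
        assert rows.loc[("syndrome", 2), "pct"].item() == 59.64

    def test_percentages_sum_to_100(self):
        summary = cohort_summary(table1_patients())
        for attr in ("age_band", "history", "complication", "diagnosis", "syndrome"):
            total = summary.loc[summary["attribute"] == attr, "pct"].sum()
            assert total == pytest.approx(100.0, abs=0.05)

    def test_single_patient(self):
        patients = pd.DataFrame(
            [("P1", 1, 2, 0, 2, 2)],
            columns=["patient_id", "age_band", "history", "complication", "diagnosis", "syndrome"],
        )
        summary = cohort_summary(patients).set_index(["attribute", "category"])
        assert summary.loc[("age_band", 1), "pct"].item() == 100.0

    def test_incomplete_rows_tallied(self):
        patients = table1_patients()
        patients.loc[:30, "syndrome"] = pd.NA  # 31 incomplete records
        summary = cohort_summary(patients)
        incomplete = summary.loc[summary["attribute"] == "incomplete_data"].iloc[0]
        assert incomplete["n"] == 31
        assert incomplete["pct"] == 3.71

    def test_by_sex_groups(self):
        patients = table1_patients()
        patients["sex"] = ["M"] * 501 + ["F"] * 334
        summary = cohort_summary(patients)
        assert set(summary["group"]) == {"all", "F", "M"}
        male = summary[(summary["group"] == "M") & (summary["attribute"] == "age_band")]
        assert male["n"].sum() == 501

    def test_level_from_admission_scores(self):
        patients = pd.DataFrame(
            [("P1", 1, 2, 0, 2, 2), ("P2", 3, 0, 0, 1, 4)],
            columns=["patient_id", "age_band", "history", "complication", "diagnosis", "syndrome"],
        )
        visits = pd.DataFrame(
            [("P1", 1, 8, 0, 0, 0, 0), ("P2", 1, 25, 0, 0, 0, 0), ("P2", 8, 1, 0, 0, 0, 0)],
            columns=["patient_id", "day", "score", "a1", "a2", "a3", "death_flag"],
        )
        summary = cohort_summary(patients, visits).set_index(["attribute", "category"])
        assert summary.loc[("level", 3), "n"].item() == 1  # score 8
        assert summary.loc[("level", 5), "n"].item() == 1  # score 25 at admission

    def test_empty_rejected(self):
        with pytest.raises(SummaryError):
            cohort_summary(pd.DataFrame())


PIPELINE_CONFIG = {
    "seed": 7,
    "synthesis": {
        "n_patients": 200,
        "effect_model": {
            "action_effects": {"111": 3.0, "001": 1.0},
            "baseline_mean": -0.5,
            "noise_sd": 0.5,
        },
        "missing_rate": 0.02,
    },
    "solver": {"n_episodes": 3000, "horizon": 21},
}


class TestRunPipeline:
    def test_artifacts_and_manifest(self, tmp_path):
        result = run_pipeline(PIPELINE_CONFIG, tmp_path / "run")
        out = tmp_path / "run"
        for name in (
            "patients.tsv", "visits.tsv", "episodes.tsv", "model.tsv",
            "state_inventory.tsv", "q.tsv", "policy.tsv", "cohort_summary.tsv",
            "manifest.json",
        ):
            assert (out / name).exists(), name
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 7
        assert manifest["stages"]["synthesize"]["n_patients"] == 200
        assert manifest["stages"]["solve"]["n_episodes"] == 3000
        assert len(result["policy"]) > 0

    def test_idempotent_across_reruns(self, tmp_path):
        run_pipeline(PIPELINE_CONFIG, tmp_path / "a")
        run_pipeline(PIPELINE_CONFIG, tmp_path / "b")
        for name in ("patients.tsv", "visits.tsv", "episodes.tsv", "model.tsv", "q.tsv", "policy.tsv"):
            assert (tmp_path / "a" / name).read_text() == (tmp_path / "b" / name).read_text(), name
        m_a = json.loads((tmp_path / "a" / "manifest.json").read_text())
        m_b = json.loads((tmp_path / "b" / "manifest.json").read_text())
        assert m_a == m_b

    def test_missing_input_file_raises_with_path(self, tmp_path):
        config = {"seed": 1, "inputs": {"patients": str(tmp_path / "nope.tsv"),
                                        "visits": str(tmp_path / "nope2.tsv")}}
        with pytest.raises(FileNotFoundError, match="nope"):
            run_pipeline(config, tmp_path / "run")

    def test_planted_action_is_modal_per_stratum(self, tmp_path):
        config = {
            "seed": 5,
            "synthesis": {
                "n_patients": 1200,
                "effect_model": {
                    "action_effects": {"111": 3.0, "001": 1.0},
                    "baseline_mean": -0.5,
                    "noise_sd": 0.5,
                },
            },
            "solver": {"n_episodes": 40_000},
            "report": {"strata": [
                {"name": "phlegm_blocking", "constraints": {"syndrome": 2}},
            ]},
        }
        run_pipeline(config, tmp_path / "run")
        table = pd.read_csv(
            tmp_path / "run" / "decisions_phlegm_blocking.tsv", sep="\t",
            dtype={"action": str},
        )
        modal = table.groupby("action")["frequency"].sum().idxmax()
        assert modal == "111"
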
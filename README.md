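# strokemdp

Comparative-effectiveness analysis of combined treatment regimens on
longitudinal patient records, cast as a finite Markov decision process
(MDP). The pipeline encodes visit records into six-digit patient states
and three-bit treatment actions, estimates the empirical transition
model, solves for the optimal per-state treatment by Monte Carlo control
with exploring starts, and reports stratified optimal-action frequency
tables. A seeded synthetic-cohort generator with a planted ground-truth
optimal action stands in for hospital EHR data.

## Model at a glance

- **State**: six digits — age band (1–3), disease history (0–2),
  complications (0–1), western diagnosis (1–2), TCM syndrome (1–5), and
  neurological-impairment level (1–5) graded from a 0–29 score
  (0–2 / 3–5 / 6–12 / 13–19 / 20–29). Death carries the default
  score 29. Example: `120223`.
- **Action**: three bits — rehabilitation, Chinese herbal decoction,
  acupuncture — giving 8 combinations (`111` … `000`).
- **Reward**: score before minus score after one 7-day epoch; positive
  means improvement. Decision epochs run from day 1 every 7 days, capped
  at day 147.
- **Solver**: tabular Monte Carlo control with exploring starts
  (default 500,000 episodes, undiscounted, 21-step horizon), verified
  against an exact finite-horizon backward-induction oracle.

## Command-line usage

Each stage is independently runnable, or the whole pipeline at once:

```bash
strokemdp simulate --config config.yaml --out run/            # synthetic cohort
strokemdp episodes --patients run/patients.tsv --visits run/visits.tsv \
                   --seed 1 --out run/                        # clean/fill/steps
strokemdp estimate --episodes run/episodes.tsv --out run/     # transition model
strokemdp solve    --model run/model.tsv --episodes 500000 --seed 1 --out run/
strokemdp report   --policy run/policy.tsv --patients run/patients.tsv \
                   --visits run/visits.tsv --out run/         # decision tables
strokemdp pipeline --config config.yaml --seed 7 --out run/   # all of the above
```

A minimal config:

```yaml
seed: 7
synthesis:
  n_patients: 2000
  effect_model:
    action_effects: {"111": 3.0, "001": 1.0}
    baseline_mean: -0.5
    noise_sd: 0.5
    death_prob: 0.01
solver:
  n_episodes: 500000
report:
  strata:
    - name: phlegm_blocking
      constraints: {syndrome: 2}
```

All tabular I/O is UTF-8 tab-separated text with headers; state and
action codes are stored as strings so leading zeros survive. The
pipeline writes a `manifest.json` with seeds and per-stage counts and is
bit-for-bit reproducible from (inputs, seed).

## Python API

```python
from strokemdp import (
    CohortConfig, EffectModel, generate_cohort, planted_policy,
    clean_records, fill_missing, build_episodes,
    estimate_model, joint_outcome_table,
    SolverConfig, run_mc_control, exact_q,
    StratumPredicate, stratified_decision_table, cohort_summary,
)

config = CohortConfig(
    n_patients=5000, seed=1,
    effect_model=EffectModel(action_effects={"111": 3.0, "001": 1.0},
                             baseline_mean=-0.5, noise_sd=0.5),
)
patients, visits = generate_cohort(config)
steps = build_episodes(patients, fill_missing(clean_records(visits), seed=2))
model = estimate_model(steps)
q, policy = run_mc_control(model, SolverConfig(n_episodes=500_000, seed=3))
table = stratified_decision_table(policy, StratumPredicate({"syndrome": 2}))
```

`planted_policy(config)` returns the generator's ground-truth optimal
action per state, used by the solver-recovery tests.

## Layout

- `src/strokemdp/cohort_model.py` — domain types, score grading, state/action codecs
- `src/strokemdp/synthetic_cohort.py` — seeded cohort generator, planted optimum, missingness
- `src/strokemdp/episode_builder.py` — cleaning, uniform random fill, visit → step conversion
- `src/strokemdp/mdp_estimation.py` — empirical transition model and outcome/inventory tables
- `src/strokemdp/mdp_solver.py` — Monte Carlo control, backward-induction oracle, policies
- `src/strokemdp/reporting.py` — stratified decision tables, cohort summary, pipeline
- `src/strokemdp/cli.py` — `strokemdp` command group
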
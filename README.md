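# stopnet

Inhibitory control depends on both how strongly brain regions respond
to stopping an action and how their coupling changes between successful
and failed stops — and in adult aging, these two channels can carry
different information about a person's stopping speed.  `stopnet` is a
testbed for that whole analysis chain.  It simulates stop-signal/no-go
(SNG) task behavior and multi-subject BOLD-like data with *known*
activity, connectivity and age effects, then recovers them with the
standard analysis machinery, so every stage can be validated against
ground truth:

- **Race-model behavior** — independent go and stop processes race on
  every Stop-Signal trial; a response occurs iff the go finishing time
  beats SSD + stop latency.  A 1-up/1-down staircase adapts the
  stop-signal delay (SSD) in 50 ms steps toward ~50% stopping success.
- **SSRT estimation** — the stop-signal reaction time is estimated by
  the block-based integration method: within blocks of 30 stop trials,
  SSRT = (the p(respond|signal) quantile of the ranked correct-Go RT
  distribution) − mean SSD, with premature responses (RT < SSD) removed
  from the response-rate formula:
  p(respond|signal) = (N_stop − N_succ − N_RT<SSD) / (N_stop − N_RT<SSD).
- **Group ICA** — temporally concatenated subject data are PCA-reduced
  to an MDL-selected order and decomposed by repeated fixed-point ICA
  with stability clustering; subject time courses come from spatial
  regression on the group maps.
- **Activity & connectivity** — per-component GLM responsivity
  (β_SuccStop − β_UnsuccStop), context-independent connectivity by
  task-controlled multiple regression between component time courses,
  and context-dependent connectivity by correlational PPI contrasting
  coupling during successful vs unsuccessful stop epochs.
- **Prediction & moderation** — SSRT is predicted from brain features
  by Ledoit-Wolf shrinkage regression inside a three-stage
  permutation-based 10-fold cross-validation (train weights → held-out
  subject scores → correlate scores with SSRT); models are compared via
  repartition distributions, and an age × subject-score interaction
  tests whether the brain-behavior association changes across the
  life span.

## Worked example

```python
from stopnet.simulate import generate_task_design, simulate_race_behavior, RaceParams
from stopnet.behavior import estimate_ssrt_block_integration, p_respond_given_signal, stop_counts

design = generate_task_design(seed=11)            # 360 Go / 80 Stop / 40 No-Go
behavior = simulate_race_behavior(design, RaceParams(ssrt_mu=200.0), seed=14)
p = p_respond_given_signal(stop_counts(behavior))
ssrt, blocks = estimate_ssrt_block_integration(behavior)
print(f"p(respond|signal) = {p:.3f}, SSRT = {ssrt:.1f} ms over {len(blocks)} blocks")
```

prints

```
p(respond|signal) = 0.487, SSRT = 184.6 ms over 3 blocks
```

— the staircase held the response rate near one half (slightly below,
because the tracker starts at a short 250 ms delay) and the integration
estimator recovered the 200 ms generative stop latency from a single
subject's 80 stop trials to within its single-subject sampling error
(about ±18 ms; averaging 100 simulated subjects recovers the mean to
within ±15 ms — see `tests/test_acceptance.py`).

The full pipeline — cohort simulation, behavior, ICA, activity,
connectivity, prediction, moderation, and a markdown report — runs from
one config:

```bash
stopnet run --seed 7 --out demo_out/
cat demo_out/report.md
```

On the default 20-subject demo cohort this takes well under a minute
and ends with ground-truth map recovery |r| ≥ 0.99, a significant
activity-based prediction of SSRT, and a null spontaneous-connectivity
model, mirroring the injected effects.

## Layout

```
src/stopnet/
  simulate/        task designs, race behavior, motion, BOLD forward model, cohorts
  behavior.py      p(respond|signal), block-integration SSRT, displacement, exclusions
  decomposition.py MDL order selection, group ICA + stability, noise classification
  activity.py      design matrices, component GLMs, responsivity, FDR, robust age fits
  connectivity.py  context-independent regression connectivity and cPPI
  prediction.py    shrinkage MLR, three-stage permutation CV, moderation
  pipeline.py      stage orchestration with manifests and a report
  cli.py           `stopnet` command-line interface
docs/methods.md    modelling and statistical choices in detail
```
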
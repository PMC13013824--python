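# tempope

Temporal prediction-error model-based fMRI analysis, end to end and fully
testable on synthetic data.

## The scientific problem

In Pavlovian reward learning, the brain learns not only *that* a cue
predicts a reward but *when* the reward will arrive. Violating the learned
timing — delivering a juice reward later than expected — produces *temporal
prediction errors*: a negative one when the reward fails to appear at the
expected moment, and a positive one when it finally arrives at an
unexpected moment. Blunted neural encoding of these signals in amygdala and
striatum is a candidate mechanism for diminished positive affect in
post-trauma psychopathology (PTP), and its study requires a chain of
machinery: a catch-trial task design, a temporal-difference (TD) learning
model of moment-by-moment prediction errors, voxelwise GLMs with parametric
PE modulators, permutation-corrected group inference within reward-circuit
ROIs, and brain–symptom association.

`tempope` implements that chain for researchers who want to develop,
validate and power such analyses against a ground-truth synthetic cohort
before touching (non-shareable) patient data. Real-data entry points (4D
NIfTI, BIDS-style events TSV, ROI masks) use the same code paths.

## The model in brief

A TD(0) learner with a complete-serial-compound (tapped delay line) state
predicts, at each time bin t after a cue, the discounted future reward
V(t) = w·x(t). The prediction error of the transition into bin t,

    δ(t) = r(t) + γ·V(t) − V(t−1),      w[x(t−1)] ← w[x(t−1)] + α·δ(t),

is sampled at cue onsets and at expected/unexpected outcome deliveries and
unexpected absences, and used as parametric modulators of the BOLD signal
(4 parametric regressors: cue and outcome × juice and visual). The
traditional analysis instead contrasts event classes directly, e.g. the
negative temporal PE contrast = (unexpected − expected absence). Group
inference converts t maps to Z, applies TFCE (E = 0.5, H = 2, dh = 0.1)
and controls FWE by max-statistic permutation within the ROI mask, at a
contrast-wise α = 0.05 and an experiment-wise α = 0.05/6 = 0.008333 across
the six examined contrasts. Regional summaries are associated with symptom
scores by Spearman correlation with a Bonferroni threshold of
0.05/(4 measures × 5 regions) = 0.0025.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from tempope import (
    generate_schedule, schedule_to_events, simulate_td, sample_pes, TDParams,
)

schedule = generate_schedule(seed=7)
print([len(r) for r in schedule.runs])        # [54, 72]
events = schedule_to_events(schedule)
trace = simulate_td(schedule, "juice", TDParams())
pes = sample_pes(trace, events)
print(pes.groupby("event_class")["pe_value"].mean().round(3))
```

prints

```
[54, 72]
event_class
cue                   0.190
expected_outcome      0.894
unexpected_absence   -0.159
unexpected_outcome    1.006
Name: pe_value, dtype: float64
```

— after learning, outcome delivery at unexpected (late) times carries the
largest positive PE, absence at the expected time a negative PE, and cue
onsets a moderate positive PE (rising across learning). Expected deliveries
retain positive PEs because the 2–4 s delay jitter keeps exact delivery
time uncertain.

A full synthetic study, from cohort to group maps and association table:

```python
from tempope import PipelineConfig, run_pipeline
cfg = PipelineConfig()
cfg.cohort.n_per_group = 8          # desk-scale demo; default is 45
cfg.group.n_perm = 200
results = run_pipeline(cfg, seed=1, out_dir="out/")
print(results["association"].head())
```

The CLI mirrors the stages: `tempope simulate-schedule`,
`simulate-cohort`, `fit`, `group`, `associate`, `run-all`.

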
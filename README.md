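# tonecloud

Change detection in statistically defined acoustic textures: the stimulus,
two decision models, and the behavioral statistics — as one tested,
reproducible Python pipeline running entirely on synthetic stimuli.

Listeners (and models) hear a *tone cloud*: a train of 30 ms chords whose
tones are drawn from a marginal probability distribution over eight spectral
bins spanning 2.2 octaves (400–1840 Hz, ~147 tones/s). At an exponentially
distributed, unpredictable time the probability of two bins increases by
30–140% of the uniform bin probability (with renormalization, so the overall
level never changes), and the task is to report that change as quickly as
possible. Detecting it requires estimating the baseline statistics first —
a minimal laboratory model of noticing that something changed in rain,
wind, or a busy street.

The package implements:

- **`tonecloud.stimulus`** — the texture generator: tone grid, random
  marginals, change injection, chord sampling, audio rendering (WAV), and
  the symbolic per-channel event/occupancy series the models consume.
- **`tonecloud.behavior`** — hit/miss/false-alarm classification,
  performance tables, instantaneous false-alarm hazard, time-resolved
  sensitivity d′(t) = Z(HR(t)) − Z(FAR(t)), Erlang-CDF performance-dynamics
  fits, and reaction-time ROC analysis.
- **`tonecloud.dual_model`** — a drift-diffusion-style statistical
  estimator: per-channel fast and slow leaky estimates of tone occupancy,
  dP/dt = (S − P)/τ, with the slow time constant relaxing from τ_f to τ_s
  over τ_a; a change is declared when |P_fast − P_slow| exceeds a threshold
  T. Includes whole-experiment simulation and exhaustive-search fitting.
- **`tonecloud.cortical`** — a simplified auditory-cortex model:
  constant-Q cochleogram with lateral inhibition, spectrotemporal modulation
  filtering (rate ω in Hz, scale Ω in cycles/octave), matched post-filter,
  and a collapsing decision bound T(t) = b·e^(−t/λ) + a with first-peak
  readout.
- **`tonecloud.experiment`** — config-driven end-to-end runs (generate →
  simulate → analyze → write CSV/JSON bundles), byte-reproducible from a
  seed.

The numbered scripts under `analysis/` run the pipeline as a narrative:
`01_generate_stimuli.py` (the stimulus set and its statistics),
`02_dual_model.py` (psychometrics of the estimation model),
`03_cortical_model.py` (change-locked cortical responses and the decision
stage), `04_fit_models.py` (self-consistency of both fitting routines).

## Worked example

```python
import numpy as np
from tonecloud import stimulus, dual_model, behavior

grid = stimulus.build_frequency_grid()          # 26 tones, 8 bins, 3.3 st wide
trials = stimulus.generate_trial_batch(seed=1)  # the 930-trial design
records = dual_model.simulate_experiment(trials, dual_model.DualParams(), grid=grid)
print(records["outcome"].value_counts(normalize=True).round(2))
table = behavior.performance_table(records[records["distance"] == 1], n_time_bins=4)
print(table.pivot(index="size", columns="time_bin", values="performance").round(2))
```

Running `python analysis/02_dual_model.py` (which adds the d′, hazard,
Erlang and ROC analyses) prints, at the published parameters
(τ_f = 0.2 s, τ_s = 1.1 s, τ_a = 0.65 s, T = 0.40):

```
930 trials simulated at the published parameters (tau_f=0.2, tau_s=1.1, tau_a=0.65 s, T=0.40): 34% hits, 13% false alarms

Performance (hits / (hits+misses)), localized changes, by change size x change-time bin:
time_bin     0     1     2     3     4     5
size
50        0.20  0.38  0.25  0.25  0.30  0.36
80        0.16  0.33  0.59  0.47  0.39  0.67
110       0.44  0.40  0.60  0.68  0.75  0.85
140       0.56  0.78  0.84  0.78  0.60  0.88

110% changes by spectral separation of the incremented bins:
 distance  performance
        2         0.31
        3         0.21
        5         0.27
        7         0.20

Median reaction time by change size: 50%: 1.10 s, 80%: 0.78 s, 110%: 0.71 s, 140%: 0.73 s

Instantaneous FA rate: 0.007/s in the first second (initial hesitation), ~0.097/s thereafter (flat hazard)
```

Read: detection performance rises with the size of the statistical change
(rows) and with the time available to estimate the baseline before the
change (columns, exponentially widening bins), and saturates for late
changes; changes spread across distant bins are harder than localized ones;
reaction times shorten for larger changes; and after an initial hesitation
the false-alarm hazard is flat — the model, like the listeners it mimics,
cannot exploit timing because the change-time law is exponential.

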
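# limbselect

A two-site stochastic dynamic model of how young children choose a hand
for a unimanual grasp — and why they sometimes keep using the hand they
just used, even when the object no longer favors it (perseveration).

The package is for researchers in motor development and dynamical-systems
modelling of behavior: it provides the model itself, the
perseveration-experiment protocol (training on one side, then neutral
midline probes), Monte-Carlo cohorts over three age-group parameter
presets, and the categorical statistics used with such trial-level data
(handedness classification, preferred-frame transform, chi-squared,
McNemar).

## The model

Each hand is a neural site with activation `u`, coupled to its rival by
sigmoidal mutual inhibition:

    tau * du_P/dt  = -u_P  + h - c_P  * sigma(u_NP) + I_P  + n * xi_P(t)
    tau * du_NP/dt = -u_NP + h - c_NP * sigma(u_P)  + I_NP + n * xi_NP(t)

`P`/`NP` are the preferred and nonpreferred hand, `h` the resting level,
`sigma` a logistic of steepness `beta`, and `xi` Gaussian white noise of
strength `n`. Handedness is the inhibition asymmetry `c_P < c_NP`. The
input `I` to each site is sensory (6.0 on the presentation side, 1.0
opposite; 6.0 to both at midline) plus an accumulating motor-memory trace:
each selection adds 1.2 to the chosen site's input for subsequent trials
of the same condition. Trials are integrated by forward Euler (400 steps,
2 s); the more active site at trial end selects the hand. Age-group
presets (14, 24, 36 months) vary only the inhibition asymmetry and noise:
handedness strengthens and variability shrinks with age.

## Worked example

Simulate one trial of a 24-month-old model child with the object on the
preferred side:

```
$ limbselect simulate-trial --preset 24mo --seed 5 --drive-p 6 --drive-np 1
{"selected": "P", "u_P_final": 4.6943298891806835, "u_NP_final": -5.961435858206921, "tie_broken": false, "seed": 5}
```

The cued site relaxes to a high activation (~4.7), the other is
suppressed below rest (~-6.0), and the preferred hand is selected.

Run the full study simulation — 500 participants of the youngest preset
through both conditions, restricted to the subgroup that trained
perfectly on the nonpreferred hand:

```
$ limbselect reference-table --seed 1
Filtered 14mo cohort (perfect test-condition training):
condition trial   n  n_preferred  prop_preferred
  control    T3 210          201        0.957143
  control    T4 210          204        0.971429
  control    N1 210          188        0.895238
  control    N2 210          183        0.871429
     test    T3 210            0        0.000000
     test    T4 210            0        0.000000
     test    N1 210           73        0.347619
     test    N2 210           73        0.347619
```

210 of 500 simulated 14-month-olds trained perfectly in the test
condition. In the control condition they use the preferred hand in ~96% of
the late training trials and still ~87–90% of the neutral trials:
handedness and the accumulated memory trace both favor that hand, so the
trained bias persists at midline. In the test condition the neutral-trial
proportions (~0.35 preferred) show the competition of the two forces: the
+4.8 memory trace on the nonpreferred site outweighs the handedness
asymmetry, so most model children perseverate with the trained
(nonpreferred) hand. See `docs/methods.md` for where this cumulative
memory rule does and does not match the reference pattern.

The same pieces are available as a library:

```python
from limbselect import get_preset, run_cohort, filter_perfect_training, summarize

cohort = run_cohort(get_preset("36mo"), n_participants=500, seed=7)
print(summarize(filter_perfect_training(cohort)))
```

`limbselect run-cohort --preset 36mo --n 500 --seed 7 --out trials.csv`
writes the trial-level records (selection, memory and final activations
per trial) as tidy CSV with the resolved configuration embedded, and
`limbselect stats --records trials.csv` computes proportion tables and
McNemar tests from such records (simulated or observed).

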
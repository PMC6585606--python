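# Methods

## The model

`limbselect` implements a two-site dynamic model of hand choice for
unimanual grasping in young children. Each hand is represented by one
neural site whose activation `u` evolves by

    tau * du_P/dt  = -u_P  + h - c_P  * sigma(u_NP) + I_P  + n * xi_P(t)
    tau * du_NP/dt = -u_NP + h - c_NP * sigma(u_P)  + I_NP + n * xi_NP(t)

with `sigma(u) = 1 / (1 + exp(-beta * u))`. The site with the higher
activation at the end of a trial selects the corresponding hand. The model
embodies three forces:

* **Handedness** — the asymmetry of mutual inhibition, `c_P < c_NP`: the
  preferred-hand site suppresses its rival more strongly than it is
  suppressed. Under laterally neutral input the preferred site therefore
  wins unless other forces intervene.
* **Sensory input** — where the object is. A lateral presentation drives
  the ipsilateral site with strength 6.0 and the contralateral site with
  1.0; a midline presentation drives both with 6.0.
* **Motor memory** — a trial-to-trial trace: every selection adds 1.2 to
  the chosen site's input for the remaining trials of the condition. This
  is the mechanism of perseveration: recent use of a hand biases the next
  choice toward it. Memory is cleared before and between conditions.

Noise `n * xi` makes selection probabilistic; its strength, together with
the inhibition asymmetry, carries the developmental story: the parameter
presets are

| preset | c_P | c_NP | n   |
|--------|-----|------|-----|
| 14mo   | 0.5 | 3.5  | 3.3 |
| 24mo   | 2.0 | 5.0  | 2.0 |
| 36mo   | 3.0 | 7.0  | 1.7 |

with `tau = 3`, `h = -2`, `beta = 2` shared. Older children have stronger
handedness (larger asymmetry) and less variable selection (less noise).

## Integration and units

Trials are integrated by forward Euler with 400 steps from the resting
state `u_P = u_NP = h`. We place `tau = 3` and the step on a common model
time unit with `dt = 0.05` and map one model unit to 0.1 s, so a trial
spans 2 s of selection time and `dt/tau ~ 0.017` keeps the scheme stable
and well relaxed within the trial (endpoint drift residual < 1e-2; the
convergence test verifies first-order behavior by step halving).

Two noise dialects are provided, because the discrete-time reading of the
noise term is the one genuinely underdetermined ingredient:

* `sqrt-dt` (default): `du = (dt/tau)*drift + n*sqrt(dt)*xi`, the
  Euler–Maruyama scaling with the fluctuation entering the rate of change
  directly. Per-step noise sd at the defaults: `n * 0.224`.
* `per-step`: `du = (dt/tau)*(drift + n*xi)`, a literal per-step reading of
  the printed equation. Its effective noise vanishes as `dt -> 0` and at
  the default step it yields nearly deterministic cohorts.

`limbselect.cohort.calibration_sweep` scores both dialects over a grid of
step sizes against the reference filtered-cohort table; the `sqrt-dt`
dialect at `dt = 0.05` reproduces the reference control-condition row to
within ~0.02–0.04 and is therefore the package default.

Other closures of gaps the reference description leaves open, each exposed
as an explicit choice:

* **Sigmoid form** — logistic with `beta = 2`; only "sigmoid shape" is
  specified, and the logistic is the standard choice in this model family.
* **Initial condition** — both sites start each trial at the resting level
  `h`; trials are separated by inter-trial intervals long enough for decay.
* **Readout** — argmax of the final state, with a fair random tie-break
  (flagged in the output). No selection threshold is specified, and a
  threshold-crossing readout would add a free parameter.
* **Random streams** — participant `i` draws from
  `SeedSequence((seed, i))`, so cohorts are reproducible, participants are
  independent, and results do not depend on cohort size or run order. The
  vectorised cohort engine consumes the identical streams as the scalar
  path and is tested to be bit-identical to it.

## The simulated experiment

Each simulated participant runs two conditions of six trials: four
training trials (lateral presentation; preferred side in the control
condition, nonpreferred side in the test condition) then two neutral
trials (midline). Drives are fixed before each trial (sensory + current
memory) and constant during it. The cohort layer applies the subgroup
filter used for the youngest group — keep participants with no
preferred-hand selections in the four test-condition training trials — and
tabulates preferred-hand proportions per condition and trial. The filter
is defined on the test condition only; control training may be imperfect
in the retained subset (an option filters both conditions for sensitivity
analysis).

## Known limitation: cumulative memory vs. the fading reference pattern

The memory rule implemented here is literal and cumulative: +1.2 per
selection, no decay, no bound. This has a provable consequence: after
perfect nonpreferred training the trained site enters the neutral trials
with +4.8 input, which exceeds the largest possible inhibition-asymmetry
advantage of the preferred site (`c_NP - c_P` is at most 4.0 across
presets, and the sigmoid factors only shrink it). The deterministic
balance in the test-condition neutral trials therefore always favors the
trained hand, and zero-mean noise can only push the preferred-hand
proportion toward 0.5 from below. The reference simulation table instead
reports 0.54 and 0.65 for these two cells — above 0.5 — and shows the
control-condition proportion and the condition difference *fading* from N1
to N2, which a cumulative trace cannot produce (it reinforces itself: each
perseverative choice adds more memory). Reproducing those specific cells
would require a decaying or saturating memory trace; no decay constant is
reported, so we do not fit one, and the package reports what the literal
rule yields (~0.33–0.38 at N1). The noise-free limit — deterministic
perseveration in both conditions, driven purely by the memory trace — and
the control-condition cells, the age trend in training success, and the
positive N1 perseveration difference for the older presets are all
reproduced.

## The synthetic behavioral fixture

`generate_fixture_cohort` emulates trial-level behavioral records:
independent Bernoulli hand choices per trial with configurable
preferred-hand probabilities, a per-participant handedness direction, and
output in the raw left/right frame so the preferred-frame transform is
exercised. It deliberately omits features of real infant data — bimanual
grasps arise only if injected, there is no sequential dependence within a
participant beyond what the probabilities encode, and no missing trials —
so tests built on it validate the statistics layer's arithmetic, not its
robustness to messy recordings.

## Statistics layer

Handedness direction is classified by strict majority over neutral-trial
hand choices ("both" counts toward neither; ties are undetermined).
Chi-squared tests use uncorrected Pearson by default (Yates correction is
an option for 2x2; a single-row table is tested against uniform), via
scipy. The McNemar test defaults to the exact two-sided binomial form on
the discordant pairs, appropriate for subgroup sizes of 14–26; with no
discordant pairs p = 1 by convention. Both are cross-checked in the test
suite against independent brute-force evaluations (textbook Pearson sums;
direct binomial tail summation; statsmodels' exact McNemar).

## Problem sizes

Cohort tables use the reference 500 participants. CI-based ordering
checks (age trend, perseveration signature) use 2000 participants per
preset so that 99% intervals separate cleanly. The vectorised engine runs
a 500-participant, 12-trial, 400-step cohort in about a second.
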
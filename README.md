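# beliefpupil

Belief-updating models and pupillometry analysis for two-source
auditory predictive-inference tasks.

## The scientific problem

In an adaptive decision-making task, a hidden sound source sits on the
left or right and switches sides between trials with a hazard rate
*H*.  On each trial the subject predicts which side will produce the
next tone; the tone then plays on the active source's side with
probability *p* = 0.8.  The hazard rate itself changes in unannounced
blocks between *H* = 0.01 (sources almost never switch), *H* = 0.3,
and *H* = 0.99 (sources switch almost every trial), so doing well
requires learning the current hazard and using it to temper how much
each tone should update one's beliefs.

This package provides, as a tested and reusable pipeline, the models
and measurements needed to study that process and its pupil-linked
arousal correlates:

- **task** — simulation of the hazard-switching task environment;
- **normative** — the fixed-hazard ideal observer.  Beliefs are
  log-posterior-odds `L_t = ψ_t + LLR_t`, where the prior odds pass
  through the hazard nonlinearity
  `ψ(L, H) = L + log[(1−H)/H + e^(−L)] − log[(1−H)/H + e^(L)]`
  and each tone contributes `LLR = ±log[p/(1−p)]`.  Choices follow
  `Pr(right) = 1/(1 + e^(−ψ/v))` and fits minimize the cross entropy
  between choices and these probabilities.  Includes per-condition
  subjective-hazard fits and the "adaptivity" model
  `J_subjective = J_default + m_H · J_objective` relating subjective
  to objective log-hazard-odds;
- **learner** — a hierarchical Bayesian learner that infers source
  *and* hazard jointly: `H ~ Beta(μφ, (1−μ)φ)` a priori, redrawn with
  probability *K* per trial, tracked on a discretized hazard grid.
  Outputs the trial-wise decision variable ψ, **belief strength**
  |ψ| and **surprisal** −ln Pr(tone), plus cross-entropy fitting of
  (μ, φ, K, v) from choices;
- **complexity** — the information-bottleneck measure of
  belief-updating complexity:
  `I_past = I(F_{t−1}; R_t) = Σ Pr(r,f) log₂[Pr(r,f)/(Pr(r)Pr(f))]`
  bits between previous-trial features (tone side × hazard condition)
  and the current prediction, corrected by subtracting the information
  intrinsic to the tone sequence, `I(x_{t−1}; x_t)`;
- **pupil** — pupillometry preprocessing (derivative- and gaze-based
  artifact rejection, gaze regression, interpolation, zero-phase 4 Hz
  first-order Butterworth filtering) and trial epoching into baseline
  (100 ms pre-tone) and evoked (2 s post-tone, 121 samples at 60 Hz)
  measures with a >50%-interpolated exclusion rule;
- **regression** — trial-wise regression of baseline/evoked pupil and
  log RT on model variables with the standard nuisance regressors,
  two-stage group inference (per-subject OLS, then a two-tailed group
  test), max-statistic sign-flip permutation FWE over evoked
  timepoints, and Spearman complexity-modulation analyses;
- **synth** — synthetic cohorts of heterogeneous simulated subjects
  with planted pupil and RT couplings (baseline negatively coupled to
  belief strength, evoked response positively coupled to surprisal),
  so the entire pipeline is testable without any external data.

## Worked example

Simulate a 1000-trial session pairing the low and intermediate hazard
conditions, run a hazard-tracking Bayesian learner over it, sample
choices, and characterize the agent's behavior:

```python
import numpy as np
from beliefpupil import task, learner, normative, complexity as cx

cfg = task.make_fixed_schedule(1, seed=0)
session = task.generate_session(cfg)

params = learner.LearnerParams(mu=0.5, phi=2.0, K=0.01, v=0.5)
trace = learner.run(session.tone, params)
choices = normative.simulate_choices(trace.psi, params.v, np.random.default_rng(0))

fit = normative.fit_adaptivity(choices, session.tone, session.j_objective, seed=0)
res = cx.complexity(choices, session.tone, session.hazard_label)
print(f"adaptivity m_H = {fit.m_h:.2f}, choice noise v = {fit.v:.2f}")
print(f"complexity: I_past = {res.i_past_raw:.3f} bits, "
      f"I_seq = {res.i_seq:.3f} bits, corrected = {res.i_past_corrected:.3f} bits")
```

prints

```
adaptivity m_H = 0.54, choice noise v = 1.28
complexity: I_past = 0.183 bits, I_seq = 0.035 bits, corrected = 0.147 bits
```

The agent is partially adaptive (`m_H` between 0, hazard-blind, and 1,
fully adaptive — this learner tracks hazard changes only through its
slow leak *K*), and its predictions carry ≈0.15 bits about the
previous trial's task conditions beyond what the tone sequence itself
provides.

A full synthetic-cohort run (task → agents → pupil traces →
preprocessing → complexity → regressions) is available from the
command line:

```bash
beliefpupil run-all --seed 7 --out results/
beliefpupil make-cohort --n 30 --seed 7 --out cohort/
beliefpupil analyze --cohort cohort/ --model computational --target baseline --out betas.csv
```

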
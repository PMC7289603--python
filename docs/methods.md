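# Methods

This note documents the models implemented in `beliefpupil`, the
defaults and numerical choices they use, what the synthetic-data
generator does and does not emulate, and the known limitations of each
measure.

## Task model

The environment is a two-state hidden Markov process.  The active
source `z_t ∈ {left=0, right=1}` switches between trials with the
current hazard rate `H_t`; the tone `x_t` equals the source side with
probability `p = 0.8`, independently across trials.  Hazard rates take
the values 0.01 (low), 0.3 (intermediate), and 0.99 (high) and change
in unannounced blocks; each 1000-trial default session pairs two of
the three conditions.  Side coding is left=0 / right=1 throughout, and
positive log-odds favor the right source.

The exact block layouts used in the original study are not published,
so `make_fixed_schedule` ships reproducible stand-in schedules with
the same structure (two hazards per session, four blocks of 190–310
trials summing to 1000).  Explicit schedules and random block layouts
(uniform lengths in a configurable range, default 100–400 trials) are
both supported.  The first trial of a session has no defined switch;
switch statistics start at trial 2.

## Fixed-hazard ideal observer (`normative`)

Belief is the log-posterior-odds `L_t` that the right source is
active.  Before each tone the previous posterior passes through the
hazard nonlinearity

    ψ(L, H) = L + log[(1−H)/H + exp(−L)] − log[(1−H)/H + exp(L)]

computed with log-sum-exp so it is stable for |L| up to the float64
overflow limit.  For `H < 0.5` this shrinks beliefs toward zero
(|ψ| ≤ |L|); for `H > 0.5` strong beliefs flip sign and saturate at
±log[(1−H)/H].  Each tone adds `LLR = ±log[p/(1−p)]` and
`L_t = ψ_t + LLR_t`.  Sessions start at `L_0 = 0` and the belief is
**not** reset at hazard-block boundaries, which are unannounced.

Predictions are made before the tone, so ψ is the decision variable:
`Pr(right) = logistic(ψ/v)` with choice-variability `v`.  Fits
minimize the cross entropy between binary choices and these
probabilities, with probabilities clipped to `[1e−12, 1−1e−12]`.

Two behavioral fits:

- **Per-condition subjective hazards.**  One free `H` per hazard
  condition, unit choice variability.  For each condition the
  recursion runs over the whole session with the candidate `H` and the
  cross entropy is scored on that condition's trials only (how trials
  of the other condition were treated in the original fits is not
  documented; scoring-masked full-session runs keep the recursion's
  history intact).  Optimization is multi-start (10 seeded starts)
  L-BFGS-B on logit(H).  Conditions with fewer than 50 trials are
  flagged unstable.  Note a property of this fit worth knowing: for
  tone-independent choices (e.g. a constant responder) the optimum is
  `H ≈ 0.5`, where ψ vanishes and every trial costs ln 2 — not a
  boundary value — and for a generator noisier than the unit-noise
  choice rule the fitted `H` is biased away from 0.5, because a more
  extreme hazard produces stronger beliefs that mimic the noise.
- **Adaptivity model.**  Subjective log-hazard-odds are affine in the
  objective ones, `J_subj = J_default + m_H · J_obj`, with free noise
  scale `v` (10-start Nelder-Mead on `(J_default, m_H, log v)`).
  `m_H = 1` is full adaptivity, `m_H = 0` hazard blindness; the slope
  is unidentifiable (and raises) on single-condition sessions.  No
  lapse parameter is included in either model.

## Hierarchical Bayesian learner (`learner`)

The learner knows the task structure but not the hazard.  Its prior is
`H ~ Beta(α, β)` with `α = μφ`, `β = (1−μ)φ`; with probability `K` per
trial the hazard is redrawn from that prior (a leak that lets the
learner re-adapt across unannounced hazard blocks).  The joint
posterior over (hazard, source) lives on a midpoint grid on (0, 1)
(default 100 points; the 100→200-point difference in ψ is <1e−3 at
`K = 0` on intermediate-hazard sessions, but grows to ~3e−3 with a
leak because redraws keep mass at the grid-limited hazard extremes).
Each trial:

1. hazard kernel: stay with `1−K`, redraw from the prior with `K`;
2. source kernel: switch with the grid hazard;
3. emit ψ (log-odds of the propagated source marginal) — the pre-tone
   decision variable — and the surprisal of the observed tone;
4. multiply by the tone likelihood (`p` on-side, `1−p` off-side) and
   renormalize.

All computation is in linear space with per-trial renormalization;
an all-zero joint raises rather than silently propagating garbage.
The recursion is validated against an independent brute-force oracle
(exhaustive summation over all source paths) to 1e−10, and against the
fixed-hazard observer in the concentrated-prior limit (`φ = 1e6`,
`K = 0`) to machine precision.

**Belief strength** is |ψ| in nats.  **Surprisal** is reported two
ways: the default regressor is the marginal predictive surprisal
`−ln Σ_{z,H} Pr(x_t|z) Pr_pred(z, H)` (the negative log probability
the model assigned to the tone it heard); the state-conditional
variant `E_pred[−ln Pr(x_t|z)]` is exposed as
`surprisal_conditional`.  The two differ only through the posterior
uncertainty over the source and are nearly interchangeable as
regressors; analyses here default to the marginal form because it is
the model's actual predictive probability.

Fitting (μ, φ, K, v) minimizes the same cross entropy, with
multi-start Nelder-Mead on `(logit μ, log φ, logit K, log v)` (clamped
at ±14), a 50-point grid during optimization, and `p` fixed at 0.8
(task-known).  When the best fit explains choices no better than
chance (within 0.01 nats/trial of ln 2) or absorbs them into a very
large `v`, μ and φ are flagged weakly identified.  On 3000-trial
sessions spanning all three hazards, rank correlations between true
and recovered parameters across a 50-agent cohort exceed 0.9 for both
μ and φ.

The **reference model** (`reference_trace`) fixes μ = 0.5, φ = 2 — the
uniform Beta(1, 1) prior that weighs all hazard rates equally — with
`K = 0` and `p = 0.8`.  It supplies subject-independent belief and
surprisal regressors for individual-difference analyses.  With
`K = 0` this model integrates the whole session, so on multi-hazard
sessions its late-session hazard estimate settles near the session's
overall switch rate; agents meant to *track* hazard blocks should use
a small leak (the synthetic cohorts default to `K = 0.01`).

## Belief-updating complexity (`complexity`)

`I_past` is the plug-in mutual information (base-2, `0·log 0 := 0`)
between the previous trial's features — tone side × hazard condition,
six levels — and the current binary prediction.  The general "features
from trials t′ < t" is realized at lag 1, and the first trial of each
session is dropped.  The tone-sequence information `I(x_{t−1}; x_t)`
is computed per session on the same trials, pooled by trial-weighted
average, and subtracted; no further small-sample bias correction is
applied.  The corrected value can be slightly negative in finite
samples.  Hazard in the feature coding is the objective block hazard.

Terciles split subjects by corrected complexity with ties resolved by
stable input order.

**Construct behavior.**  On sessions pairing the low and high hazards,
corrected complexity separates strategy classes: constant responders
sit at ≈0 raw bits, and wide-prior hazard-tracking learners sit above
narrow-prior learners (complexity increases with prior *width*; rank
correlation with 1/φ ≈ 0.9 across a φ-graded cohort).  One caveat: a
fixed-hazard observer is *not* near zero — its hazard-blind
repeat-last-tone-like policy still encodes the previous tone side, and
the sequence correction removes only the tone–tone information, not
tone-driven response information.  Its median therefore lands between
the constant responder and the wide-prior learner, and whether it
falls above or below a narrow-prior learner depends on the particular
tone sequence.

## Pupil preprocessing (`pupil`)

Cleaning order: (1) mark samples whose first difference deviates from
the median derivative by more than 3 robust SDs (1.4826×MAD, falling
back to the ordinary SD when the MAD is zero); paired spikes closer
than 0.5 s bracket a blink, so the span between them is masked too;
(2) mark samples with gaze farther than 10% of the screen diagonal
from fixation (gaze in screen fractions, unit-square screen);
(3) regress gaze x/y out of the surviving diameter samples (fitted on
the whole session) and keep residual + mean; (4) linearly interpolate
masked samples, edges filled with the nearest valid value; (5) apply a
first-order Butterworth low-pass at 4 Hz forward-backward (zero
phase).  Recordings with >90% of samples marked are rejected.
Higher-rate recordings are first resampled to 60 Hz with a polyphase
anti-aliasing filter.

Epoching: baseline is the mean diameter 0–100 ms before tone onset;
the evoked timecourse is the baseline-subtracted diameter over the 2 s
after onset (121 samples at 60 Hz).  Trials with more than 50% of
their window interpolated, or windows extending beyond the recording,
are flagged excluded.  Cleaned diameters are z-scored per session
before regression analyses (tracker units are arbitrary and differ
across devices); this is switchable.

## Trial-wise regression (`regression`)

Group inference uses the two-stage summary-statistics approach:
ordinary least squares per subject (independently at each evoked
timepoint for timecourse targets), then a two-tailed one-sample t-test
(or signed-rank) of the per-subject coefficients against zero.  This
replaces a mixed-effects model with random slopes: at cohort scale the
two give the same sign/direction inference, and the per-subject slopes
are exactly what the individual-difference analyses consume.  The
cost is that the group test does not pool within-subject uncertainty,
so its coefficients are not numerically comparable to mixed-effects
estimates.

Baseline-type targets carry the previous trial's evoked peak as a
nuisance regressor; evoked-type targets carry the current baseline,
previous evoked peak, and previous baseline.  Binary regressors are
coded 0/1; continuous regressors are z-scored within subject × hazard
condition.  The first trial of each session and excluded pupil trials
are dropped.  A first-temporal-derivative variant of the evoked
target is available (`evoked_derivative`).

Familywise error across the 121 evoked timepoints is controlled by a
max-statistic sign-flip permutation test (1000 seeded permutations):
the null distribution of the maximum |t| over timepoints calibrates
each timepoint's corrected p-value.

Complexity-modulation analyses report the Spearman correlation (with
two-tailed p) between per-subject corrected complexity and per-subject
regression slopes, e.g. the belief-strength modulation of baseline
pupil computed against the reference-model regressors.

RT analyses apply the same machinery to log RT with belief strength
(current trial) and surprisal (previous trial) as regressors;
nonpositive RTs are dropped with a reported count.

## Synthetic cohorts (`synth`)

The generator emulates the study conditions: 1000-trial sessions with
two hazard conditions in unannounced blocks, `p = 0.8`, tone sequences
shared across subjects, and heterogeneous subjects.  Strategy classes:
wide-prior learner (φ = 2), narrow-prior learner (φ = 20), fixed-
hazard observer (H = 0.3), repeat-last-tone, and constant; learner
classes use μ = 0.5, a hazard leak `K = 0.01`, and choice noise
`v = 0.5` (default cohorts draw v ∈ [0.3, 0.8] and φ log-spaced in
[1, 100] to create a complexity spectrum).

RTs are lognormal, `rt = exp(−0.6 − 0.08·belief + 0.06·prev_surprisal
+ ε)` seconds (ε ~ N(0, 0.15)), matching the use of log RT as the
regression target and giving plausible 0.4–0.8 s predictions.  Task
timing follows the paradigm: a prediction, then 3 s to the tone, then
the next trial immediately, so tone onsets are `rt + 3` s apart.

Pupil traces at 60 Hz are a sum of: a tonic level interpolating
per-trial baseline targets `5.0 − 0.15·belief + drift` (drift =
smoothed noise, SD 0.15); an evoked response after each tone — a
peak-normalized gamma kernel (shape 2, scale 0.4 s, a standard
surrogate for the pupillary impulse response) scaled by
`0.25·surprisal − 0.05·belief − 0.15·(baseline deviation) + noise`;
white measurement noise (SD 0.03); and three artifact types chosen to
exercise each cleaning rule — short square blink dropouts (~0.1/trial),
brief gaze excursions (~0.05/trial), and long 2.2 s signal losses
(~0.05/trial) that drive the >50%-interpolation exclusions, so the
exclusion rate tracks the planted artifact rate.

What the generator does **not** emulate: biophysical pupil dynamics
(light reflex, nonlinear saturation), real blink morphology,
saccade-related transients, slow vigilance drifts correlated with task
variables, or any misspecification of the subjects' generative model
(synthetic agents are exactly the models fit to them).  Passing
effect-recovery tests therefore demonstrates that the pipeline is
correct and calibrated, not that real data will show these effects.

A note on the null condition used for calibration tests: "no planted
effects" zeroes both the pupil gains *and* the latent→RT couplings.
RTs set the inter-tone intervals, intervals set how much of the
previous evoked response spills into the next trial's window, and a
peak statistic has variance-dependent expectation — so latent-coupled
RTs are themselves a pathway from the latents to measured pupil.
With all couplings zeroed the group tests reject at ≈5% at α = 0.05.

## Problem sizes

The validation suite runs at the sizes its claims are stated for:
generator statistics on 100,000-trial simulations, oracle equivalences
on 1000- and 12-trial problems, parameter recovery on 50 agents ×
3000 trials, effect recovery on a 30-subject cohort of full
1000-trial sessions, and null calibration over 100 replicate cohorts
of 12 subjects × 300 trials (the smallest cohort for which the group
test is well powered, chosen to keep the 100-replicate study quick).

## Known limitations

- The mixed-effects replacement (two-stage OLS) cannot reproduce the
  numerical coefficients of a random-slope mixed model, only their
  signs and group-level significance structure.
- The information-bottleneck measure at lag 1 under-counts strategies
  with longer memories, and the sequence correction does not remove
  tone-driven *response* information (see the fixed-hazard caveat
  above).
- The hazard grid cannot represent hazards closer to 0 or 1 than half
  a grid step; with a hazard leak this limits the precision of ψ in
  extreme-hazard blocks.
- `load_osf_export` expects a documented flat-table layout; native
  eye-tracker formats are out of scope.
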
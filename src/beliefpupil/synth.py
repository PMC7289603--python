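"""Synthetic cohorts: task sessions, simulated subjects, RTs, pupil traces.

Every pipeline stage in this package can be exercised without any
external data.  A cohort consists of simulated subjects who perform
the two-source task with heterogeneous belief-updating strategies:

``bayesian_wide`` / ``bayesian_narrow``
    hierarchical Bayesian learners differing in prior precision phi
    (a wide prior adapts readily to the hazard context and produces
    complex, context-dependent behavior; a narrow prior anchored at
    mu resists updating),
``fixed_hazard``
    a normative observer with one fixed subjective hazard rate,
    blind to the hazard context,
``repeat_last_tone`` and ``constant``
    heuristics (echo the previous tone; always predict one side).

Each subject also gets response times and a 60 Hz pupil trace with
planted couplings: baseline pupil is negatively coupled to belief
strength, the evoked response is positively coupled to surprisal and
negatively to both belief strength and the current baseline, and
blink-like square artifacts are injected so the cleaning rules in
:mod:`beliefpupil.pupil` are exercised.  The ground-truth record keeps
every generating parameter and per-trial latent variable, so planted
effects can be computed exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from . import learner as learner_mod
from . import normative
from .pupil import PupilRecording
from .task import TaskConfig, TrialSequence, generate_session, make_fixed_schedule

__all__ = [
    "AgentSpec",
    "PupilGenSpec",
    "RTGenSpec",
    "SubjectData",
    "SyntheticCohort",
    "default_agent_grid",
    "simulate_agent",
    "make_cohort",
    "write_cohort",
    "read_cohort",
]

STRATEGY_CLASSES = (
    "bayesian_wide",
    "bayesian_narrow",
    "fixed_hazard",
    "repeat_last_tone",
    "constant",
)


@dataclass
class AgentSpec:
    """One simulated subject's belief-updating strategy."""

    strategy: str = "bayesian_wide"
    mu: float = 0.5
    phi: float = 2.0
    K: float = 0.01
    v: float = 0.5
    fixed_h: float = 0.3  # subjective hazard of the fixed_hazard class

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGY_CLASSES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; choose from {STRATEGY_CLASSES}"
            )

    @classmethod
    def for_class(cls, strategy: str, v: float = 0.5) -> "AgentSpec":
        """Canonical representative of a strategy class.

        Wide-prior learners use phi=2 (the uniform Beta(1,1) prior),
        narrow-prior learners phi=20 (anchored near mu=0.5, hence weak
        hazard adaptation); both leak hazard knowledge at K=0.01 so
        they re-adapt across unannounced hazard blocks.  The
        fixed-hazard observer uses the intermediate hazard 0.3.
        """
        phi = {"bayesian_wide": 2.0, "bayesian_narrow": 20.0}.get(strategy, 2.0)
        return cls(strategy=strategy, mu=0.5, phi=phi, K=0.01, v=v)

    def learner_params(self, p: float = 0.8) -> learner_mod.LearnerParams:
        return learner_mod.LearnerParams(
            mu=self.mu, phi=self.phi, K=self.K, v=self.v, p=p
        )


@dataclass
class PupilGenSpec:
    """Planted pupil-generation parameters (arbitrary diameter units).

    The evoked impulse response is a gamma-family kernel (shape 2,
    scale 0.4 s), peak-normalized so the planted trial amplitude is
    the peak of the noiseless evoked bump.
    """

    baseline_intercept: float = 5.0
    baseline_belief_gain: float = -0.15  # a.u. per nat, negative
    evoked_surprise_gain: float = 0.25  # a.u. per nat, positive
    evoked_belief_gain: float = -0.05  # a.u. per nat, small negative
    baseline_evoked_coupling: float = -0.15  # per a.u. baseline deviation
    kernel_shape: float = 2.0
    kernel_scale_s: float = 0.4
    slow_noise_sd: float = 0.15  # tonic drift amplitude
    evoked_noise_sd: float = 0.05  # trial-amplitude noise
    noise_sd: float = 0.03  # white measurement noise
    blink_rate: float = 0.10  # short square dropouts per trial
    gaze_excursion_rate: float = 0.05  # brief fixation breaks per trial
    artifact_rate: float = 0.05  # long signal losses per trial (exclude trials)
    rate: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.artifact_rate <= 0.2:
            raise ValueError("artifact_rate must lie in [0, 0.2]")
        if self.kernel_shape <= 0 or self.kernel_scale_s <= 0:
            raise ValueError("kernel parameters must be positive")


@dataclass
class RTGenSpec:
    """Lognormal response-time generator: strong beliefs speed the
    prediction, a surprising previous tone slows the next one.

    rt = exp(intercept - belief_coef * belief + surprise_coef *
    prev_surprisal + noise), in seconds.
    """

    intercept: float = -0.6  # exp(-0.6) ~ 0.55 s
    belief_coef: float = 0.08
    surprise_coef: float = 0.06
    noise_sd: float = 0.15


@dataclass
class SubjectData:
    """Everything generated for one simulated subject."""

    subject_id: int
    spec: AgentSpec
    session: TrialSequence
    choices: np.ndarray
    rt_s: np.ndarray
    tone_onsets_ms: np.ndarray
    pupil_raw: PupilRecording | None
    latent: pd.DataFrame  # belief_strength, surprisal, baseline_true, evoked_amp_true


@dataclass
class SyntheticCohort:
    subjects: list[SubjectData]
    pupil_spec: PupilGenSpec
    rt_spec: RTGenSpec
    seed: int
    ground_truth: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subjects)


def default_agent_grid(n_subjects: int, rng: np.random.Generator) -> list[AgentSpec]:
    """Heterogeneous Bayesian cohort spanning a graded range of prior
    widths (phi log-spaced from wide to narrow) to create a
    belief-updating complexity spectrum."""
    phis = np.geomspace(1.0, 100.0, n_subjects)
    vs = rng.uniform(0.3, 0.8, n_subjects)
    return [
        AgentSpec(strategy="bayesian_wide", mu=0.5, phi=float(phi), K=0.01, v=float(v))
        for phi, v in zip(phis, vs)
    ]


def simulate_agent(
    spec: AgentSpec,
    session: TrialSequence,
    rng: np.random.Generator,
    n_grid: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one agent on a session.

    Returns (choices, belief_strength, surprisal).  Choices are made
    before each tone; model-based agents sample them from
    logistic(psi/v).  Heuristic agents (repeat_last_tone, constant)
    have no internal belief model, so the wide-prior reference model
    supplies their latent regressors.
    """
    tones = session.tone
    n = len(tones)
    if spec.strategy in ("bayesian_wide", "bayesian_narrow"):
        trace = learner_mod.run(tones, spec.learner_params(session.p), n_grid=n_grid)
        choices = normative.simulate_choices(trace.psi, spec.v, rng)
        return choices, trace.belief_strength, trace.surprisal
    if spec.strategy == "fixed_hazard":
        trace = normative.run_fixed_hazard(tones, spec.fixed_h, session.p)
        choices = normative.simulate_choices(trace.psi, spec.v, rng)
        pz = special.expit(trace.psi)
        p_right = session.p * pz + (1.0 - session.p) * (1.0 - pz)
        p_obs = np.where(tones == 1, p_right, 1.0 - p_right)
        return choices, np.abs(trace.psi), -np.log(p_obs)
    ref = learner_mod.reference_trace(tones, n_grid=n_grid)
    if spec.strategy == "repeat_last_tone":
        choices = np.empty(n, dtype=int)
        choices[0] = rng.integers(2)
        choices[1:] = tones[:-1]
    else:  # constant
        choices = np.ones(n, dtype=int)
    return choices, ref.belief_strength, ref.surprisal


def _gamma_kernel(spec: PupilGenSpec) -> np.ndarray:
    """Peak-normalized gamma impulse response sampled at the pupil rate."""
    t = np.arange(0.0, 3.0, 1.0 / spec.rate)
    k = stats.gamma.pdf(t, spec.kernel_shape, scale=spec.kernel_scale_s)
    return k / k.max()


def _smooth_noise(n: int, rate: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Slow tonic drift: heavily smoothed white noise, unit-free."""
    if sd == 0.0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    # moving-average over ~5 s gives drift well below the trial rate
    width = max(int(5.0 * rate), 1)
    kernel = np.ones(width) / width
    smooth = np.convolve(w, kernel, mode="same")
    s = np.std(smooth)
    return sd * smooth / (s if s > 0 else 1.0)


def generate_pupil(
    belief: np.ndarray,
    surprisal: np.ndarray,
    rt_s: np.ndarray,
    spec: PupilGenSpec,
    rng: np.random.Generator,
) -> tuple[PupilRecording, np.ndarray, np.ndarray, np.ndarray]:
    """Generate a raw 60 Hz pupil trace for one session.

    Tone onsets follow the task timing (prediction, then a 3 s delay
    to the tone; the next trial starts immediately, so inter-tone
    intervals are rt + 3 s).  Returns (recording, tone_onsets_ms,
    baseline_true, evoked_amp_true).
    """
    n = len(belief)
    onsets_s = 3.0 + np.cumsum(np.concatenate([[rt_s[0]], rt_s[1:] + 3.0]))
    duration = onsets_s[-1] + 2.5
    n_samp = int(np.ceil(duration * spec.rate))
    t = np.arange(n_samp) / spec.rate

    drift = _smooth_noise(n_samp, spec.rate, spec.slow_noise_sd, rng)
    baseline_true = (
        spec.baseline_intercept
        + spec.baseline_belief_gain * belief
        + np.interp(onsets_s, t, drift)
    )
    # tonic level interpolates through the per-trial baseline targets
    tonic = np.interp(t, onsets_s, baseline_true)

    amp = (
        spec.evoked_surprise_gain * surprisal
        + spec.evoked_belief_gain * belief
        + spec.baseline_evoked_coupling * (baseline_true - spec.baseline_intercept)
        + spec.evoked_noise_sd * rng.standard_normal(n)
    )
    kernel = _gamma_kernel(spec)
    evoked = np.zeros(n_samp)
    onset_idx = np.round(onsets_s * spec.rate).astype(int)
    for i, a in zip(onset_idx, amp):
        stop = min(i + len(kernel), n_samp)
        evoked[i:stop] += a * kernel[: stop - i]

    diam = tonic + evoked + spec.noise_sd * rng.standard_normal(n_samp)
    gaze_x = 0.5 + 0.01 * rng.standard_normal(n_samp)
    gaze_y = 0.5 + 0.01 * rng.standard_normal(n_samp)

    # short blink-like square dropouts: sharp edges trip the
    # derivative rule, the depressed block is bracketed and replaced
    for _ in range(rng.binomial(n, spec.blink_rate)):
        start = int(rng.integers(0, max(n_samp - 20, 1)))
        width = int(rng.integers(6, 16))  # 100-250 ms at 60 Hz
        diam[start : start + width] -= spec.baseline_intercept * 0.4

    # brief fixation breaks: gaze wanders beyond the rejection radius
    for _ in range(rng.binomial(n, spec.gaze_excursion_rate)):
        start = int(rng.integers(0, max(n_samp - 40, 1)))
        width = int(rng.integers(12, 40))
        gaze_x[start : start + width] += rng.choice([-1.0, 1.0]) * 0.25

    # long signal losses (tracker drops the eye): these exclude the
    # trials they cover via the >50%-interpolated rule
    n_long = rng.binomial(n, spec.artifact_rate)
    long_width = int(2.2 * spec.rate)
    for _ in range(n_long):
        start = int(rng.integers(0, max(n_samp - long_width, 1)))
        diam[start : start + long_width] = np.nan
    rec = PupilRecording(
        time=t * 1000.0, diameter=diam, gaze_x=gaze_x, gaze_y=gaze_y, rate=spec.rate
    )
    return rec, onsets_s * 1000.0, baseline_true, amp


def make_cohort(
    n_subjects: int = 30,
    task_config: TaskConfig | None = None,
    agent_specs: list[AgentSpec] | None = None,
    pupil_spec: PupilGenSpec | None = None,
    rt_spec: RTGenSpec | None = None,
    seed: int = 7,
    with_pupil: bool = True,
    n_grid: int = 100,
) -> SyntheticCohort:
    """Generate a complete synthetic cohort.

    All subjects share the same tone sequence (as in the study, where
    sequences were fixed across subjects); agents, choices, RTs and
    pupil noise are drawn per subject from streams derived from
    ``seed``.
    """
    if n_subjects < 3:
        raise ValueError("a cohort needs at least 3 subjects")
    rng = np.random.default_rng(seed)
    if task_config is None:
        task_config = make_fixed_schedule(1, seed=seed)
    if pupil_spec is None:
        pupil_spec = PupilGenSpec()
    if rt_spec is None:
        rt_spec = RTGenSpec()
    session = generate_session(task_config)
    if agent_specs is None:
        agent_specs = default_agent_grid(n_subjects, rng)
    if len(agent_specs) != n_subjects:
        raise ValueError("agent_specs length must equal n_subjects")

    subjects = []
    for sid, spec in enumerate(agent_specs):
        srng = np.random.default_rng([seed, sid])
        choices, belief, surprisal = simulate_agent(spec, session, srng, n_grid=n_grid)
        prev_surp = np.concatenate([[0.0], surprisal[:-1]])
        rt_s = np.exp(
            rt_spec.intercept
            - rt_spec.belief_coef * belief
            + rt_spec.surprise_coef * prev_surp
            + rt_spec.noise_sd * srng.standard_normal(len(belief))
        )
        if with_pupil:
            rec, onsets_ms, base_true, amp_true = generate_pupil(
                belief, surprisal, rt_s, pupil_spec, srng
            )
        else:
            rec = None
            onsets_ms = np.array([])
            base_true = np.full(len(belief), np.nan)
            amp_true = np.full(len(belief), np.nan)
        latent = pd.DataFrame(
            {
                "belief_strength": belief,
                "surprisal": surprisal,
                "baseline_true": base_true,
                "evoked_amp_true": amp_true,
                "rt_s": rt_s,
            }
        )
        subjects.append(
            SubjectData(
                subject_id=sid,
                spec=spec,
                session=session,
                choices=choices,
                rt_s=rt_s,
                tone_onsets_ms=onsets_ms,
                pupil_raw=rec,
                latent=latent,
            )
        )
    ground_truth = {
        "seed": seed,
        "pupil_spec": asdict(pupil_spec),
        "rt_spec": asdict(rt_spec),
        "agents": [asdict(s.spec) for s in subjects],
    }
    return SyntheticCohort(
        subjects=subjects,
        pupil_spec=pupil_spec,
        rt_spec=rt_spec,
        seed=seed,
        ground_truth=ground_truth,
    )


def write_cohort(cohort: SyntheticCohort, directory) -> None:
    """Write a cohort as flat CSV tables plus a ground-truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "ground_truth.json").write_text(
        json.dumps(cohort.ground_truth, indent=2)
    )
    for s in cohort.subjects:
        stem = directory / f"sub{s.subject_id:03d}"
        s.session.to_frame().to_csv(
            f"{stem}_session.csv", index=False, float_format="%.17g"
        )
        beh = s.latent.copy()
        beh.insert(0, "trial", np.arange(len(s.choices)))
        beh.insert(1, "choice", s.choices)
        beh.to_csv(f"{stem}_behavior.csv", index=False, float_format="%.17g")
        if s.pupil_raw is not None:
            s.pupil_raw.to_frame().to_csv(
                f"{stem}_pupil.csv", index=False, float_format="%.17g"
            )
            pd.DataFrame(
                {"trial": np.arange(len(s.tone_onsets_ms)), "onset_ms": s.tone_onsets_ms}
            ).to_csv(f"{stem}_events.csv", index=False, float_format="%.17g")


def read_cohort(directory) -> SyntheticCohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    gt_path = directory / "ground_truth.json"
    if not gt_path.exists():
        raise FileNotFoundError(f"missing ground-truth table: {gt_path}")
    ground_truth = json.loads(gt_path.read_text())
    pupil_spec = PupilGenSpec(**ground_truth["pupil_spec"])
    rt_spec = RTGenSpec(**ground_truth["rt_spec"])
    subjects = []
    for sid, spec_dict in enumerate(ground_truth["agents"]):
        stem = directory / f"sub{sid:03d}"
        for suffix in ("session", "behavior"):
            if not Path(f"{stem}_{suffix}.csv").exists():
                raise FileNotFoundError(f"missing table: {stem}_{suffix}.csv")
        session = TrialSequence.from_frame(pd.read_csv(f"{stem}_session.csv", float_precision="round_trip"))
        beh = pd.read_csv(f"{stem}_behavior.csv", float_precision="round_trip")
        pupil_path = Path(f"{stem}_pupil.csv")
        if pupil_path.exists():
            events_path = Path(f"{stem}_events.csv")
            if not events_path.exists():
                raise FileNotFoundError(f"missing table: {events_path}")
            rec = PupilRecording.from_frame(pd.read_csv(pupil_path, float_precision="round_trip"))
            onsets = pd.read_csv(events_path, float_precision="round_trip")["onset_ms"].to_numpy(float)
        else:
            rec = None
            onsets = np.array([])
        subjects.append(
            SubjectData(
                subject_id=sid,
                spec=AgentSpec(**spec_dict),
                session=session,
                choices=beh["choice"].to_numpy(int),
                rt_s=beh["rt_s"].to_numpy(float),
                tone_onsets_ms=onsets,
                pupil_raw=rec,
                latent=beh.drop(columns=["trial", "choice"]),
            )
        )
    return SyntheticCohort(
        subjects=subjects,
        pupil_spec=pupil_spec,
        rt_spec=rt_spec,
        seed=ground_truth["seed"],
        ground_truth=ground_truth,
    )
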
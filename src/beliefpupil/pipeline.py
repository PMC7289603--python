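"""End-to-end orchestration: synthesize -> preprocess -> model -> infer.

The helpers here glue the single-purpose modules into cohort-level
analyses and are shared by the command-line interface, the test suite
and the reproduction script.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import complexity as cx
from . import learner as learner_mod
from . import normative, pupil, regression
from .io_ import RunConfig
from .synth import (
    PupilGenSpec,
    RTGenSpec,
    SubjectData,
    SyntheticCohort,
    make_cohort,
)
from .task import TaskConfig, make_fixed_schedule

__all__ = [
    "preprocess_subject",
    "subject_trace",
    "trials_frame",
    "cohort_betas",
    "cohort_complexity",
    "null_calibration",
    "run_pipeline",
]


def preprocess_subject(
    subject: SubjectData, zscore: bool = True
) -> tuple[pupil.TrialPupil, np.ndarray]:
    """Clean, optionally z-score, and epoch one subject's pupil trace."""
    if subject.pupil_raw is None:
        raise ValueError(f"subject {subject.subject_id} has no pupil recording")
    cleaned, mask = pupil.clean(subject.pupil_raw)
    if zscore:
        cleaned = pupil.zscore_recording(cleaned)
    return pupil.epoch(cleaned, mask, subject.tone_onsets_ms), mask


def subject_trace(
    subject: SubjectData, source: str = "true", n_grid: int = 100
) -> learner_mod.LearnerTrace:
    """Per-trial model regressors for one subject.

    source='true' runs the learner at the subject's generating
    parameters (synthetic cohorts only); 'fit' refits the learner to
    the subject's choices first; 'reference' uses the fixed wide-prior
    benchmark model, identical for all subjects.
    """
    tones = subject.session.tone
    if source == "reference":
        return learner_mod.reference_trace(tones, n_grid=n_grid)
    if source == "fit":
        params = learner_mod.fit_learner(subject.choices, tones, p=subject.session.p)
        return learner_mod.run(tones, params, n_grid=n_grid)
    if source == "true":
        spec = subject.spec
        if spec.strategy == "fixed_hazard":
            trace = normative.run_fixed_hazard(tones, spec.fixed_h, subject.session.p)
            surp = subject.latent["surprisal"].to_numpy(float)
            return learner_mod.LearnerTrace(
                psi=trace.psi,
                L=trace.L,
                belief_strength=np.abs(trace.psi),
                surprisal=surp,
                surprisal_conditional=surp,
                posterior_mean_h=np.full(len(tones), spec.fixed_h),
            )
        return learner_mod.run(tones, spec.learner_params(subject.session.p), n_grid=n_grid)
    raise ValueError(f"unknown trace source {source!r}")


def trials_frame(subject: SubjectData) -> pd.DataFrame:
    """Per-trial behavioral table used by the regression builders."""
    return pd.DataFrame(
        {
            "tone": subject.session.tone,
            "choice": subject.choices,
            "hazard": subject.session.hazard,
            "rt_s": subject.rt_s,
        }
    )


def cohort_betas(
    cohort: SyntheticCohort,
    target_kind: str,
    regressors: list[str] | None = None,
    trace_source: str = "true",
    zscore: bool = True,
) -> pd.DataFrame | dict[str, np.ndarray]:
    """Per-subject regression coefficients across a cohort.

    Scalar targets return a (subjects x regressors) DataFrame; the
    'evoked' timecourse target returns {regressor: subjects x 121}.
    """
    rows = []
    for subject in cohort.subjects:
        trace = subject_trace(subject, trace_source)
        pup = None
        if target_kind != "log_rt":
            pup, _ = preprocess_subject(subject, zscore=zscore)
        design = regression.build_design(
            trials_frame(subject), trace, pup, target_kind, regressors=regressors
        )
        rows.append(regression.fit_subject(design))
    if isinstance(rows[0], pd.Series):
        return pd.DataFrame(rows).reset_index(drop=True)
    names = rows[0].columns
    return {name: np.stack([r[name].to_numpy() for r in rows]) for name in names}


def cohort_complexity(cohort: SyntheticCohort) -> np.ndarray:
    """Corrected belief-updating complexity (bits) per subject."""
    out = []
    for subject in cohort.subjects:
        res = cx.complexity(
            subject.choices, subject.session.tone, subject.session.hazard_label
        )
        out.append(res.i_past_corrected)
    return np.array(out)


def null_calibration(
    n_replicates: int = 100,
    n_subjects: int = 12,
    n_trials: int = 300,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """False-positive rate of the group tests on null cohorts.

    Cohorts are generated with every planted coupling set to zero --
    the pupil gains and also the latent->RT couplings, because RTs set
    the inter-tone intervals and hence how much of the previous evoked
    response spills into the next trial's window; a latent-dependent
    interval is itself a planted pathway from the latents to the
    measured pupil.  The belief->baseline and surprisal->evoked group
    tests are run on each cohort and the fraction of rejections at
    ``alpha`` returned.
    """
    null_spec = PupilGenSpec(
        baseline_belief_gain=0.0,
        evoked_surprise_gain=0.0,
        evoked_belief_gain=0.0,
        baseline_evoked_coupling=0.0,
    )
    null_rt = RTGenSpec(belief_coef=0.0, surprise_coef=0.0)
    task = TaskConfig(
        hazard_values=(0.01, 0.99), n_trials=n_trials, block_length_range=(60, 120)
    )
    rej_base = 0
    rej_evoked = 0
    for rep in range(n_replicates):
        rep_seed = (seed * 100003 + rep) % 2**31
        cohort = make_cohort(
            n_subjects=n_subjects,
            task_config=TaskConfig(**{**task.__dict__, "seed": rep_seed}),
            pupil_spec=null_spec,
            rt_spec=null_rt,
            seed=rep_seed,
            n_grid=50,
        )
        b = cohort_betas(cohort, "baseline", ["belief_strength", "surprisal"])
        res_b = regression.group_inference(b)
        e = cohort_betas(cohort, "peak_evoked", ["belief_strength", "surprisal"])
        res_e = regression.group_inference(e)
        rej_base += res_b.p["belief_strength"] < alpha
        rej_evoked += res_e.p["surprisal"] < alpha
    return {
        "fp_rate_baseline_belief": rej_base / n_replicates,
        "fp_rate_evoked_surprisal": rej_evoked / n_replicates,
        "n_replicates": n_replicates,
        "alpha": alpha,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic pipeline and write report tables.

    Stages: synthesize cohort -> preprocess pupil -> belief-updating
    complexity -> switch and computational regressions -> adaptivity
    fits -> group summaries.  Reports are flat CSV tables plus a JSON
    summary and a log with seeds and parameters.  A stage failure
    raises with the stage name.
    """
    out_dir = Path(config.paths["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed={config.seed} n_subjects={config.n_subjects}"]
    report: dict = {}

    def stage(name: str):
        log.append(f"[{time.strftime('%H:%M:%S')}] stage: {name}")
        return name

    current = stage("synthesize")
    try:
        task = make_fixed_schedule(
            config.task.get("session_index", 1), seed=config.seed, p=config.task["p"]
        )
        cohort = make_cohort(
            n_subjects=config.n_subjects,
            task_config=task,
            seed=config.seed,
            n_grid=config.learner["n_grid"],
        )

        current = stage("complexity")
        comp = cohort_complexity(cohort)
        terciles = cx.tercile_groups(comp)
        pd.DataFrame(
            {"subject": np.arange(len(comp)), "complexity_bits": comp, "tercile": terciles}
        ).to_csv(out_dir / "complexity.csv", index=False)
        report["complexity_median_bits"] = float(np.median(comp))

        current = stage("regression_switches")
        b_sw = cohort_betas(
            cohort, "baseline", ["tone_switch", "prediction_switch"]
        )
        res_sw = regression.group_inference(
            b_sw, seed=config.seed, n_perm=config.regression["n_permutations"]
        )
        b_sw.to_csv(out_dir / "betas_switches_baseline.csv", index=False)

        current = stage("regression_computational")
        b_base = cohort_betas(cohort, "baseline", ["belief_strength", "surprisal"])
        res_base = regression.group_inference(b_base, seed=config.seed)
        b_evoked = cohort_betas(cohort, "peak_evoked", ["belief_strength", "surprisal"])
        res_evoked = regression.group_inference(b_evoked, seed=config.seed)
        b_base.to_csv(out_dir / "betas_computational_baseline.csv", index=False)
        b_evoked.to_csv(out_dir / "betas_computational_evoked.csv", index=False)
        report["baseline_belief_beta"] = float(res_base.mean_beta["belief_strength"])
        report["baseline_belief_p"] = float(res_base.p["belief_strength"])
        report["evoked_surprisal_beta"] = float(res_evoked.mean_beta["surprisal"])
        report["evoked_surprisal_p"] = float(res_evoked.p["surprisal"])

        current = stage("adaptivity")
        m_h = []
        for subject in cohort.subjects:
            fit = normative.fit_adaptivity(
                subject.choices,
                subject.session.tone,
                subject.session.j_objective,
                p=subject.session.p,
                n_starts=5,
                seed=config.seed,
            )
            m_h.append(fit.m_h)
        pd.DataFrame({"subject": np.arange(len(m_h)), "m_h": m_h}).to_csv(
            out_dir / "adaptivity.csv", index=False
        )
        report["median_m_h"] = float(np.median(m_h))

        current = stage("complexity_modulation")
        mod = regression.complexity_modulation(
            b_base["belief_strength"].to_numpy(), comp
        )
        report["complexity_baseline_rho"] = mod["rho"]
        report["complexity_baseline_rho_p"] = mod["p"]
    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed in stage {current!r}: {err}") from err

    (out_dir / "summary.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    return report
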
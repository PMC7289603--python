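"""Trial-wise regression of pupil measures and RT on task/model variables.

Group inference uses a two-stage summary-statistics approach: ordinary
least squares per subject (independently at each of the 121 evoked
timepoints for timecourse targets), then a two-tailed one-sample test
of the per-subject coefficients against zero.  The per-subject slopes
double as the individual-difference measures for the complexity
analyses.  Familywise error over evoked timepoints is controlled with
a max-statistic sign-flip permutation test.

Targets and their nuisance regressors follow pupillometry convention:
baseline-type targets carry the previous trial's evoked peak as a
nuisance; evoked-type targets carry the current baseline, the previous
evoked peak and the previous baseline.  Continuous regressors are
z-scored within subject and hazard condition; binary regressors are
coded 0/1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .learner import LearnerTrace
from .pupil import TrialPupil

__all__ = [
    "TrialDesign",
    "RegressionResult",
    "build_design",
    "fit_subject",
    "group_inference",
    "complexity_modulation",
    "rt_models",
]

BASELINE_TARGETS = ("baseline", "next_baseline")
EVOKED_TARGETS = ("evoked", "evoked_derivative", "peak_evoked")
N_PERMUTATIONS = 1000


@dataclass
class TrialDesign:
    """Standardized per-subject design matrix and target."""

    X: pd.DataFrame
    y: np.ndarray  # (n,) scalar target or (n, 121) evoked timecourse
    regressor_names: list[str]
    nuisance_names: list[str]
    target_kind: str


@dataclass
class RegressionResult:
    """Group-level inference over per-subject coefficients."""

    mean_beta: pd.Series | pd.DataFrame
    stat: pd.Series | pd.DataFrame
    p: pd.Series | pd.DataFrame
    per_subject: pd.DataFrame | dict[str, np.ndarray] = field(repr=False, default=None)
    fwe_mask: dict[str, np.ndarray] | None = None
    n_dropped: int = 0


def _zscore_by_group(x: np.ndarray, groups: np.ndarray) -> np.ndarray:
    out = np.array(x, dtype=float)
    for g in np.unique(groups):
        m = groups == g
        sd = np.std(out[m])
        out[m] = (out[m] - np.mean(out[m])) / (sd if sd > 0 else 1.0)
    return out


def build_design(
    trials: pd.DataFrame,
    trace: LearnerTrace | None,
    pupil: TrialPupil | None,
    target_kind: str,
    regressors: list[str] | None = None,
    use_conditional_surprisal: bool = False,
) -> TrialDesign:
    """Assemble one subject's design matrix for a given target.

    ``trials`` needs columns ``tone``, ``choice`` and ``hazard`` (plus
    ``rt_s`` for RT targets).  Available regressors: ``tone_switch``,
    ``prediction_switch``, ``error`` (current prediction vs current
    tone), ``prev_error``, ``belief_strength``, ``surprisal``,
    ``prev_surprisal``.  The first trial (no previous-trial variables)
    and pupil-excluded trials are dropped.
    """
    n = len(trials)
    if trace is not None and len(trace.psi) != n:
        raise ValueError("trace and trials are misaligned")
    if pupil is not None and len(pupil) != n:
        raise ValueError("pupil measures and trials are misaligned")
    tone = trials["tone"].to_numpy(int)
    choice = trials["choice"].to_numpy(int)
    hazard = trials["hazard"].to_numpy(float)

    cols: dict[str, np.ndarray] = {}
    cols["tone_switch"] = np.concatenate([[0], (tone[1:] != tone[:-1])]).astype(float)
    cols["prediction_switch"] = np.concatenate(
        [[0], (choice[1:] != choice[:-1])]
    ).astype(float)
    cols["error"] = (choice != tone).astype(float)
    cols["prev_error"] = np.concatenate([[0], cols["error"][:-1]])
    if trace is not None:
        surp = trace.surprisal_conditional if use_conditional_surprisal else trace.surprisal
        cols["belief_strength"] = _zscore_by_group(trace.belief_strength, hazard)
        cols["surprisal"] = _zscore_by_group(surp, hazard)
        cols["prev_surprisal"] = np.concatenate([[0.0], cols["surprisal"][:-1]])

    if regressors is None:
        regressors = (
            ["belief_strength", "surprisal"]
            if trace is not None
            else ["tone_switch", "prediction_switch"]
        )
    missing = [r for r in regressors if r not in cols]
    if missing:
        raise ValueError(f"unknown regressors: {missing}")

    if target_kind in BASELINE_TARGETS:
        nuisance_names = ["prev_evoked_peak"]
    elif target_kind in EVOKED_TARGETS:
        nuisance_names = ["current_baseline", "prev_evoked_peak", "prev_baseline"]
    elif target_kind == "log_rt":
        nuisance_names = []
    else:
        raise ValueError(f"unknown target kind {target_kind!r}")

    if target_kind == "log_rt":
        rt = trials["rt_s"].to_numpy(float)
        keep = rt > 0
        n_nonpos = int((~keep).sum())
        if n_nonpos:
            warnings.warn(f"dropping {n_nonpos} nonpositive RTs", stacklevel=2)
        y = np.where(keep, np.log(np.where(keep, rt, 1.0)), np.nan)
    else:
        if pupil is None:
            raise ValueError(f"target {target_kind!r} requires pupil measures")
        cols["prev_evoked_peak"] = np.concatenate([[np.nan], pupil.peak_evoked[:-1]])
        cols["current_baseline"] = pupil.baseline
        cols["prev_baseline"] = np.concatenate([[np.nan], pupil.baseline[:-1]])
        if target_kind == "baseline":
            y = pupil.baseline
        elif target_kind == "next_baseline":
            y = pupil.next_baseline
        elif target_kind == "peak_evoked":
            y = pupil.peak_evoked
        elif target_kind == "evoked":
            y = pupil.evoked
        else:  # evoked_derivative: first temporal derivative variant
            y = np.gradient(pupil.evoked, axis=1)

    X = pd.DataFrame({k: cols[k] for k in [*regressors, *nuisance_names]})
    keep = np.ones(n, dtype=bool)
    keep[0] = False  # no previous-trial variables on the first trial
    if pupil is not None:
        keep &= ~pupil.excluded
        keep[:-1] &= ~pupil.excluded[1:] if target_kind == "next_baseline" else True
    keep &= ~X.isna().any(axis=1).to_numpy()
    y = np.asarray(y, dtype=float)
    keep &= ~np.isnan(y).any(axis=1) if y.ndim == 2 else ~np.isnan(y)
    return TrialDesign(
        X=X.loc[keep].reset_index(drop=True),
        y=y[keep],
        regressor_names=list(regressors),
        nuisance_names=nuisance_names,
        target_kind=target_kind,
    )


def fit_subject(design: TrialDesign) -> pd.Series | pd.DataFrame:
    """Per-subject OLS coefficients (per timepoint for evoked targets).

    Returns a Series indexed by regressor name for scalar targets, or
    a (n_timepoints x regressors) DataFrame for timecourse targets.
    Collinear columns are dropped with a warning and get NaN betas.
    """
    n = len(design.y)
    if n < 30:
        raise ValueError(f"only {n} usable trials; need at least 30")
    names = list(design.X.columns)
    X = np.column_stack([np.ones(n), design.X.to_numpy(float)])

    keep = list(range(X.shape[1]))
    rank = np.linalg.matrix_rank(X)
    while rank < len(keep):
        # drop the last collinear (non-intercept) column until full rank
        for j in range(len(keep) - 1, 0, -1):
            sub = [k for k in keep if k != keep[j]]
            if np.linalg.matrix_rank(X[:, sub]) == rank:
                warnings.warn(
                    f"dropping collinear column {names[keep[j] - 1]!r}", stacklevel=2
                )
                keep = sub
                break
        rank = np.linalg.matrix_rank(X[:, keep])

    beta_full = np.full((X.shape[1], design.y.ndim == 2 and design.y.shape[1] or 1), np.nan)
    sol, *_ = np.linalg.lstsq(X[:, keep], design.y.reshape(n, -1), rcond=None)
    beta_full[keep] = sol
    beta = beta_full[1:]  # drop intercept
    if design.y.ndim == 1:
        return pd.Series(beta[:, 0], index=names)
    return pd.DataFrame(beta.T, columns=names)


def _max_stat_fwe(
    betas: np.ndarray, n_perm: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sign-flip max-statistic FWE over timepoints for one regressor.

    ``betas``: (n_subjects, n_timepoints).  Returns (p_fwe, mask).
    """
    rng = np.random.default_rng(seed)
    n_sub = betas.shape[0]
    se = betas.std(axis=0, ddof=1) / np.sqrt(n_sub)
    se = np.where(se > 0, se, np.inf)
    t_obs = np.abs(betas.mean(axis=0) / se)
    max_null = np.empty(n_perm)
    for i in range(n_perm):
        flips = rng.choice([-1.0, 1.0], n_sub)[:, None]
        b = betas * flips
        se_p = b.std(axis=0, ddof=1) / np.sqrt(n_sub)
        se_p = np.where(se_p > 0, se_p, np.inf)
        max_null[i] = np.max(np.abs(b.mean(axis=0) / se_p))
    p_fwe = (1 + np.sum(max_null[None, :] >= t_obs[:, None], axis=1)) / (1 + n_perm)
    return p_fwe, p_fwe < 0.05


def group_inference(
    per_subject_betas,
    method: str = "ttest",
    n_perm: int = N_PERMUTATIONS,
    seed: int = 0,
) -> RegressionResult:
    """Two-tailed group test of per-subject coefficients against zero.

    ``per_subject_betas``: DataFrame (subjects x regressors) for scalar
    targets, or dict {regressor: (subjects x timepoints) array} for
    evoked timecourses (the latter also gets an FWE-corrected
    significance mask from the max-statistic permutation test).
    ``method`` is 'ttest' (default) or 'wilcoxon' (signed-rank).
    """
    if isinstance(per_subject_betas, dict):
        mean = {}
        stat = {}
        p = {}
        fwe = {}
        for name, b in per_subject_betas.items():
            b = np.asarray(b, float)
            if b.shape[0] < 5:
                raise ValueError("group inference needs at least 5 subjects")
            mean[name] = b.mean(axis=0)
            if method == "wilcoxon":
                res = [stats.wilcoxon(b[:, j]) for j in range(b.shape[1])]
                stat[name] = np.array([r.statistic for r in res])
                p[name] = np.array([r.pvalue for r in res])
            else:
                res = stats.ttest_1samp(b, 0.0, axis=0)
                stat[name] = res.statistic
                p[name] = res.pvalue
            p_fwe, mask = _max_stat_fwe(b, n_perm, seed)
            fwe[name] = mask
        return RegressionResult(
            mean_beta=pd.DataFrame(mean),
            stat=pd.DataFrame(stat),
            p=pd.DataFrame(p),
            per_subject=per_subject_betas,
            fwe_mask=fwe,
        )

    betas = pd.DataFrame(per_subject_betas)
    if len(betas) < 5:
        raise ValueError("group inference needs at least 5 subjects")
    if method == "wilcoxon":
        res = {c: stats.wilcoxon(betas[c].dropna()) for c in betas.columns}
        stat = pd.Series({c: r.statistic for c, r in res.items()})
        p = pd.Series({c: r.pvalue for c, r in res.items()})
    else:
        stat = pd.Series(
            {c: stats.ttest_1samp(betas[c].dropna(), 0.0).statistic for c in betas.columns}
        )
        p = pd.Series(
            {c: stats.ttest_1samp(betas[c].dropna(), 0.0).pvalue for c in betas.columns}
        )
    return RegressionResult(
        mean_beta=betas.mean(), stat=stat, p=p, per_subject=betas, fwe_mask=None
    )


def complexity_modulation(per_subject_betas, complexities) -> dict:
    """Spearman correlation between complexity and per-subject betas.

    ``per_subject_betas`` is one coefficient per subject (e.g. the
    belief-strength modulation of baseline pupil computed against the
    wide-prior reference regressors); ``complexities`` the matching
    corrected complexity values in bits.
    """
    b = np.asarray(per_subject_betas, float)
    c = np.asarray(complexities, float)
    if len(b) != len(c):
        raise ValueError("need one beta and one complexity per subject")
    if len(b) < 10:
        warnings.warn(
            f"Spearman correlation over only {len(b)} subjects is unstable",
            stacklevel=2,
        )
    rho, p = stats.spearmanr(c, b)
    return {"rho": float(rho), "p": float(p), "n": int(len(b))}


def rt_models(
    trials: pd.DataFrame,
    trace: LearnerTrace,
    regressors: list[str] | None = None,
) -> pd.Series:
    """Per-subject log-RT regression.

    Defaults to belief strength on the current trial (certain beliefs
    speed responses) and surprisal on the previous trial (a surprising
    tone slows the next prediction).
    """
    if regressors is None:
        regressors = ["belief_strength", "prev_surprisal"]
    design = build_design(trials, trace, None, "log_rt", regressors=regressors)
    return fit_subject(design)
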
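"""Normative fixed-hazard choice model and its behavioral fits.

The observer tracks the log-posterior-odds L_t that the right (vs left)
source is active.  Before each tone the prior log-odds are obtained by
passing the previous posterior through a hazard-dependent nonlinearity

    psi(L, H) = L + log[(1-H)/H + exp(-L)] - log[(1-H)/H + exp(L)]

which shrinks beliefs toward 0 when H < 0.5 and flips/saturates them at
+/- log[(1-H)/H] when H > 0.5.  Each tone then contributes a
log-likelihood ratio +/- log[p/(1-p)] and L_t = psi_t + LLR_t.

Predictions are made before the tone, so the decision variable for
choice is psi_t; choices follow a logistic in psi_t / v where v is a
choice-variability (temperature) parameter.  Models are fit to binary
choices by minimizing the cross entropy between choices and predicted
choice probabilities.

Two behavioral fits are provided: per-condition subjective hazard rates
(H free, one per hazard condition, unit choice variability) and the
"adaptivity" variant in which the subjective log-hazard-odds are an
affine function of the objective log-hazard-odds,
J_subjective = J_default + m_H * J_objective, with free noise scale v.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import optimize, special

__all__ = [
    "NormativeBeliefTrace",
    "SubjectiveHazardFit",
    "AdaptivityParams",
    "log_prior_odds",
    "tone_llr",
    "run_fixed_hazard",
    "choice_prob",
    "cross_entropy",
    "simulate_choices",
    "fit_subjective_hazards",
    "fit_adaptivity",
]

#: Probabilities are clipped to [CLIP_EPS, 1 - CLIP_EPS] inside the
#: cross entropy to avoid log(0).
CLIP_EPS = 1e-12


@dataclass
class NormativeBeliefTrace:
    """Per-trial belief variables of a fixed-hazard run.

    ``L`` is the post-tone log-posterior-odds, ``psi`` the pre-tone
    log-prior-odds (the decision variable), ``llr`` the tone evidence;
    L_t = psi_t + llr_t exactly.  Positive values favor the right source.
    """

    L: np.ndarray
    psi: np.ndarray
    llr: np.ndarray

    @property
    def belief_strength(self) -> np.ndarray:
        return np.abs(self.psi)


@dataclass
class SubjectiveHazardFit:
    """Per-condition subjective hazard rates fitted to choices."""

    h_subjective: dict[str, float]
    fit_loss: dict[str, float]
    unstable: dict[str, bool] = field(default_factory=dict)


@dataclass
class AdaptivityParams:
    """Parameters of the hazard-adaptivity model.

    ``m_h`` = 1 means the subject's subjective hazard tracks the
    objective hazard fully; 0 means hazard-blind behavior with a fixed
    subjective hazard logistic(j_default).
    """

    j_default: float
    m_h: float
    v: float
    fit_loss: float = np.nan

    def subjective_hazard(self, j_objective: np.ndarray) -> np.ndarray:
        """Per-trial subjective hazard from objective log-hazard-odds."""
        return special.expit(self.j_default + self.m_h * np.asarray(j_objective))


def log_prior_odds(l_prev, h):
    """Hazard-dependent prior log-odds psi(L_prev, H).

    Vectorized in either argument; numerically stable for |L| up to the
    float64 overflow limit (~700) via log-sum-exp.
    """
    l_prev = np.asarray(l_prev, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0.0) or np.any(h >= 1.0):
        raise ValueError("hazard rate must lie strictly in (0, 1)")
    r = np.log1p(-h) - np.log(h)  # log[(1-H)/H]
    out = l_prev + np.logaddexp(r, -l_prev) - np.logaddexp(r, l_prev)
    return out if out.ndim else float(out)


def tone_llr(tone, p: float):
    """Tone evidence: +log[p/(1-p)] for a right tone, - for left."""
    if not 0.5 < p <= 1.0:
        raise ValueError(f"emission probability p={p} outside (0.5, 1]")
    lam = np.log(p) - np.log1p(-p) if p < 1.0 else np.inf
    tone = np.asarray(tone)
    out = np.where(tone == 1, lam, -lam)
    return out if out.ndim else float(out)


@njit(cache=True)
def _psi_recursion(tones, hazards, p):  # pragma: no cover - numba kernel
    n = tones.size
    lam = np.log(p / (1.0 - p))
    psi = np.empty(n)
    L = np.empty(n)
    llr = np.empty(n)
    l_prev = 0.0
    for t in range(n):
        h = hazards[t]
        r = np.log((1.0 - h) / h)
        ps = l_prev + np.logaddexp(r, -l_prev) - np.logaddexp(r, l_prev)
        lr = lam if tones[t] == 1 else -lam
        l_prev = ps + lr
        psi[t] = ps
        llr[t] = lr
        L[t] = l_prev
    return psi, L, llr


def run_fixed_hazard(tones, h, p: float = 0.8) -> NormativeBeliefTrace:
    """Run the normative recursion over a session.

    ``tones`` may be a :class:`~beliefpupil.task.TrialSequence` or an
    array of 0/1 tone sides.  ``h`` is a single hazard rate or a
    per-trial array (used by the adaptivity model).  The belief starts
    uninformative (L_0 = 0) and is not reset at hazard-block
    boundaries, which are unannounced to the subject.
    """
    tone_arr = np.asarray(getattr(tones, "tone", tones), dtype=np.int64)
    if tone_arr.size == 0:
        z = np.empty(0)
        return NormativeBeliefTrace(L=z.copy(), psi=z.copy(), llr=z.copy())
    hazards = np.broadcast_to(np.asarray(h, dtype=float), tone_arr.shape).copy()
    if np.any(hazards <= 0.0) or np.any(hazards >= 1.0):
        raise ValueError("hazard rate must lie strictly in (0, 1)")
    if not 0.5 < p < 1.0:
        # p = 1 gives infinite LLRs; disallow in the recursion
        raise ValueError(f"emission probability p={p} outside (0.5, 1)")
    psi, L, llr = _psi_recursion(tone_arr, hazards, p)
    return NormativeBeliefTrace(L=L, psi=psi, llr=llr)


def choice_prob(psi, v: float = 1.0):
    """Probability of predicting the right source: logistic(psi / v)."""
    if v <= 0:
        raise ValueError(f"choice variability v={v} must be positive")
    out = special.expit(np.asarray(psi, dtype=float) / v)
    return out if out.ndim else float(out)


def cross_entropy(choices, probs, eps: float = CLIP_EPS) -> float:
    """Cross entropy (nats) between binary choices and probabilities."""
    c = np.asarray(choices, dtype=float)
    pr = np.asarray(probs, dtype=float)
    if c.shape != pr.shape:
        raise ValueError(f"length mismatch: {c.shape} choices vs {pr.shape} probs")
    pr = np.clip(pr, eps, 1.0 - eps)
    return float(-np.sum((1.0 - c) * np.log1p(-pr) + c * np.log(pr)))


def simulate_choices(psi, v: float, rng: np.random.Generator) -> np.ndarray:
    """Sample binary choices from the logistic choice rule."""
    pr = choice_prob(np.asarray(psi), v)
    return (rng.random(len(pr)) < pr).astype(int)


def _condition_loss(logit_h, tones, choices, score_mask, p):
    h = special.expit(logit_h)
    psi, _, _ = _psi_recursion(tones, np.full(tones.size, h), p)
    pr = special.expit(psi[score_mask])
    return cross_entropy(choices[score_mask], pr)


def fit_subjective_hazards(
    choices,
    tones,
    hazard_labels,
    p: float = 0.8,
    n_starts: int = 10,
    seed: int = 0,
) -> SubjectiveHazardFit:
    """Fit one subjective hazard rate per hazard condition.

    For each condition the recursion is run over the whole session with
    the candidate hazard and the cross entropy is scored on that
    condition's trials only, with the pre-tone psi as the decision
    variable (Pr(right) = logistic(psi), unit choice variability).
    Optimization is multi-start L-BFGS-B on logit(H).
    """
    tones = np.asarray(getattr(tones, "tone", tones), dtype=np.int64)
    choices = np.asarray(choices, dtype=np.int64)
    hazard_labels = np.asarray(hazard_labels)
    rng = np.random.default_rng(seed)

    h_fit: dict[str, float] = {}
    loss: dict[str, float] = {}
    unstable: dict[str, bool] = {}
    for label in pd_unique(hazard_labels):
        mask = hazard_labels == label
        n_cond = int(mask.sum())
        if n_cond < 50:
            warnings.warn(
                f"condition {label!r} has only {n_cond} trials; "
                "fitted hazard may be unstable",
                stacklevel=2,
            )
        unstable[str(label)] = n_cond < 50
        starts = special.logit(rng.uniform(0.02, 0.98, n_starts))
        best = None
        for x0 in starts:
            res = optimize.minimize(
                _condition_loss,
                x0=[x0],
                args=(tones, choices, mask, p),
                method="L-BFGS-B",
                bounds=[(-12.0, 12.0)],
            )
            if best is None or res.fun < best.fun:
                best = res
        h_fit[str(label)] = float(special.expit(best.x[0]))
        loss[str(label)] = float(best.fun)
    return SubjectiveHazardFit(h_subjective=h_fit, fit_loss=loss, unstable=unstable)


def pd_unique(values: np.ndarray) -> list:
    """Unique values in order of first appearance."""
    seen: list = []
    for v in values:
        if v not in seen:
            seen.append(v)
    return seen


def _adaptivity_loss(theta, tones, choices, j_objective, p):
    j_default, m_h, log_v = theta
    h_subj = special.expit(j_default + m_h * j_objective)
    h_subj = np.clip(h_subj, 1e-8, 1.0 - 1e-8)
    psi, _, _ = _psi_recursion(tones, h_subj, p)
    pr = special.expit(psi / np.exp(log_v))
    return cross_entropy(choices, pr)


def fit_adaptivity(
    choices,
    tones,
    j_objective,
    p: float = 0.8,
    n_starts: int = 10,
    seed: int = 0,
) -> AdaptivityParams:
    """Fit the adaptivity model (J_default, m_H, v) to choices.

    ``j_objective`` is the per-trial objective log-hazard-odds.  The
    session must span at least two hazard conditions, otherwise the
    slope m_H is unidentifiable.
    """
    tones = np.asarray(getattr(tones, "tone", tones), dtype=np.int64)
    choices = np.asarray(choices, dtype=np.int64)
    j_objective = np.asarray(j_objective, dtype=float)
    if np.unique(j_objective).size < 2:
        raise ValueError(
            "adaptivity slope m_H is unidentifiable with a single hazard condition"
        )
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        x0 = np.array(
            [rng.normal(0, 1.5), rng.uniform(0.0, 1.2), rng.normal(-0.5, 0.7)]
        )
        res = optimize.minimize(
            _adaptivity_loss,
            x0=x0,
            args=(tones, choices, j_objective, p),
            method="Nelder-Mead",
            options={"maxiter": 600, "xatol": 1e-4, "fatol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
    j_default, m_h, log_v = best.x
    return AdaptivityParams(
        j_default=float(j_default),
        m_h=float(m_h),
        v=float(np.exp(log_v)),
        fit_loss=float(best.fun),
    )
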
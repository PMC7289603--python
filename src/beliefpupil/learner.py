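"""Hierarchical Bayesian on-line inference over source and hazard rate.

The learner does not know the hazard rate H with which the hidden
source switches sides.  It assumes H ~ Beta(alpha, beta) a priori, with
alpha = mu * phi and beta = (1 - mu) * phi, and that H itself is
redrawn from that prior with a small per-trial probability K.  Before
each tone the learner propagates a joint posterior over (H, source)
through the hazard-change and source-switch kernels; the log-odds of
the propagated (predictive) source marginal is the pre-tone decision
variable psi_t.  After the tone the joint is multiplied by the tone
likelihood (p for a tone on the source's own side) and renormalized.

Belief strength is |psi_t| (nats).  Surprisal is reported two ways:
``surprisal`` (default regressor) is the negative log of the marginal
predictive probability of the observed tone,
-ln sum_{z,H} Pr(x_t | z) Pr_predictive(z, H); ``surprisal_conditional``
is the predictive expectation of the state-conditional surprisal
-ln Pr(x_t | z), which conditions on the latent source.

The posterior over H lives on a fixed midpoint grid on (0, 1); all
computation is in linear space with per-trial renormalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import optimize, special, stats

from .normative import cross_entropy

__all__ = [
    "LearnerParams",
    "PosteriorGrid",
    "LearnerTrace",
    "REFERENCE_PARAMS",
    "init_grid",
    "step",
    "run",
    "fit_learner",
    "reference_trace",
]

DEFAULT_N_GRID = 100


@dataclass
class LearnerParams:
    """Generative/inference parameters of the hierarchical learner.

    mu, phi : mean and precision of the Beta prior over hazard rate
    K       : per-trial probability that H is redrawn from the prior
    v       : choice-variability (logistic temperature) for choices
    p       : tone emission probability (task-known, fixed at 0.8)
    """

    mu: float
    phi: float
    K: float = 0.0
    v: float = 1.0
    p: float = 0.8
    fit_loss: float | None = None
    converged: bool | None = None
    weakly_identified: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu={self.mu} outside (0, 1)")
        if self.phi <= 0.0:
            raise ValueError(f"phi={self.phi} must be positive")
        if not 0.0 <= self.K < 1.0:
            raise ValueError(f"K={self.K} outside [0, 1)")
        if self.v <= 0.0:
            raise ValueError(f"v={self.v} must be positive")
        if not 0.5 < self.p <= 1.0:
            raise ValueError(f"p={self.p} outside (0.5, 1]")

    @property
    def alpha(self) -> float:
        return self.mu * self.phi

    @property
    def beta(self) -> float:
        return (1.0 - self.mu) * self.phi


#: Wide-prior reference model (weighs all hazard rates equally):
#: Beta mean 0.5, precision 2 (i.e. Beta(1, 1), uniform), fixed hazard
#: within the inference (K = 0), task emission probability 0.8.
REFERENCE_PARAMS = LearnerParams(mu=0.5, phi=2.0, K=0.0, v=1.0, p=0.8)


@dataclass
class PosteriorGrid:
    """Joint posterior over (hazard grid x source side).

    ``h`` are midpoint grid values on (0, 1); ``prior0`` the Beta prior
    masses on the grid (summing to 1); ``joint`` an (n_grid, 2) array of
    masses over (H, source in {left=0, right=1}) summing to 1.
    """

    h: np.ndarray
    prior0: np.ndarray
    joint: np.ndarray

    def source_marginal(self) -> np.ndarray:
        return self.joint.sum(axis=0)

    def hazard_mean(self) -> float:
        return float(self.h @ self.joint.sum(axis=1))


@dataclass
class LearnerTrace:
    """Per-trial outputs of a learner run (all length n_trials)."""

    psi: np.ndarray
    L: np.ndarray
    belief_strength: np.ndarray
    surprisal: np.ndarray
    surprisal_conditional: np.ndarray
    posterior_mean_h: np.ndarray


def init_grid(params: LearnerParams, n_grid: int = DEFAULT_N_GRID) -> PosteriorGrid:
    """Initial joint posterior: Beta(alpha, beta) on H, uniform on source."""
    if n_grid < 25:
        raise ValueError(f"n_grid={n_grid} too coarse; need at least 25 points")
    h = (np.arange(n_grid) + 0.5) / n_grid
    logpdf = stats.beta.logpdf(h, params.alpha, params.beta)
    prior0 = np.exp(logpdf - logpdf.max())
    prior0 /= prior0.sum()
    joint = prior0[:, None] * np.array([0.5, 0.5])
    return PosteriorGrid(h=h, prior0=prior0, joint=joint)


def step(
    grid: PosteriorGrid, tone: int, params: LearnerParams
) -> tuple[PosteriorGrid, float, float]:
    """One trial of predictive inference.

    Propagates the joint through the hazard-change and source-switch
    kernels, emits the pre-tone log-prior-odds psi and the surprisal of
    the observed tone, then applies the tone likelihood and
    renormalizes.  Returns (updated grid, psi, surprisal).
    """
    h, prior0, joint = grid.h, grid.prior0, grid.joint
    # hazard transition: stay with 1-K, redraw from the prior with K
    z_marg = joint.sum(axis=0)
    q = (1.0 - params.K) * joint + params.K * prior0[:, None] * z_marg[None, :]
    # source transition: switch with probability H
    pred = np.empty_like(q)
    pred[:, 0] = (1.0 - h) * q[:, 0] + h * q[:, 1]
    pred[:, 1] = (1.0 - h) * q[:, 1] + h * q[:, 0]
    pz = pred.sum(axis=0)
    psi = float(np.log(pz[1]) - np.log(pz[0]))
    # marginal predictive probability of the observed tone
    p = params.p
    like = np.where(np.array([0, 1]) == tone, p, 1.0 - p)
    p_tone = float(like @ pz)
    surprisal = -np.log(p_tone)
    post = pred * like[None, :]
    total = post.sum()
    if total <= 0.0 or not np.isfinite(total):
        raise FloatingPointError("posterior mass underflowed to zero")
    post /= total
    return PosteriorGrid(h=h, prior0=prior0, joint=post), psi, float(surprisal)


@njit(cache=True)
def _learner_filter(tones, h, prior0, K, p):  # pragma: no cover - numba kernel
    n = tones.size
    g = h.size
    psi = np.empty(n)
    L = np.empty(n)
    surp = np.empty(n)
    surp_cond = np.empty(n)
    pmh = np.empty(n)
    w0 = prior0 * 0.5  # joint mass over (H, z=left)
    w1 = prior0 * 0.5
    for t in range(n):
        m0 = 0.0
        m1 = 0.0
        for i in range(g):
            m0 += w0[i]
            m1 += w1[i]
        p0 = 0.0
        p1 = 0.0
        for i in range(g):
            q0 = (1.0 - K) * w0[i] + K * prior0[i] * m0
            q1 = (1.0 - K) * w1[i] + K * prior0[i] * m1
            w0[i] = (1.0 - h[i]) * q0 + h[i] * q1
            w1[i] = (1.0 - h[i]) * q1 + h[i] * q0
            p0 += w0[i]
            p1 += w1[i]
        psi[t] = np.log(p1) - np.log(p0)
        if tones[t] == 1:
            l0, l1 = 1.0 - p, p
        else:
            l0, l1 = p, 1.0 - p
        p_tone = l0 * p0 + l1 * p1
        surp[t] = -np.log(p_tone)
        surp_cond[t] = -(p0 * np.log(l0) + p1 * np.log(l1)) / (p0 + p1)
        tot = 0.0
        hm = 0.0
        for i in range(g):
            w0[i] *= l0
            w1[i] *= l1
            tot += w0[i] + w1[i]
        for i in range(g):
            w0[i] /= tot
            w1[i] /= tot
            hm += h[i] * (w0[i] + w1[i])
        pmh[t] = hm
        q0s = 0.0
        q1s = 0.0
        for i in range(g):
            q0s += w0[i]
            q1s += w1[i]
        L[t] = np.log(q1s) - np.log(q0s)
    return psi, L, surp, surp_cond, pmh


def run(tones, params: LearnerParams, n_grid: int = DEFAULT_N_GRID) -> LearnerTrace:
    """Run the learner over a full session of tones.

    psi_t is the pre-tone quantity (the decision variable for the
    subject's prediction, made before hearing the tone); L_t the
    post-tone log-posterior-odds.
    """
    tone_arr = np.asarray(getattr(tones, "tone", tones), dtype=np.int64)
    grid = init_grid(params, n_grid)
    psi, L, surp, surp_cond, pmh = _learner_filter(
        tone_arr, grid.h, grid.prior0, params.K, params.p
    )
    return LearnerTrace(
        psi=psi,
        L=L,
        belief_strength=np.abs(psi),
        surprisal=surp,
        surprisal_conditional=surp_cond,
        posterior_mean_h=pmh,
    )


_THETA_BOUND = 14.0  # clamp on transformed parameters during fitting


def _learner_loss(theta, tones, choices, n_grid, p, fit_k):
    logit_mu, log_phi, logit_k, log_v = np.clip(theta, -_THETA_BOUND, _THETA_BOUND)
    mu = special.expit(logit_mu)
    phi = np.exp(log_phi)
    K = special.expit(logit_k) if fit_k else 0.0
    h = (np.arange(n_grid) + 0.5) / n_grid
    alpha, beta = mu * phi, (1.0 - mu) * phi
    logpdf = stats.beta.logpdf(h, alpha, beta)
    prior0 = np.exp(logpdf - logpdf.max())
    prior0 /= prior0.sum()
    psi, _, _, _, _ = _learner_filter(tones, h, prior0, K, p)
    pr = special.expit(psi / np.exp(log_v))
    return cross_entropy(choices, pr)


def fit_learner(
    choices,
    tones,
    p: float = 0.8,
    n_grid: int = 50,
    n_starts: int = 8,
    fit_k: bool = True,
    seed: int = 0,
) -> LearnerParams:
    """Fit (mu, phi, K, v) to binary choices by cross-entropy minimization.

    Choices are modeled as logistic(psi_t / v) with psi_t from the
    learner run under the candidate (mu, phi, K); p is task-known and
    held fixed.  Multi-start Nelder-Mead on transformed parameters
    (logit mu, log phi, logit K, log v).  When the best fit explains
    the choices no better than chance (cross entropy within 0.01
    nats/trial of ln 2) or absorbs them into a huge noise scale, the
    choices carry no information about the learning process and mu/phi
    are flagged weakly identified.
    """
    tones = np.asarray(getattr(tones, "tone", tones), dtype=np.int64)
    choices = np.asarray(choices, dtype=np.int64)
    if tones.size < 1000:
        warnings.warn(
            f"fitting the learner on {tones.size} trials; at least 1000 recommended",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    for _ in range(n_starts):
        x0 = np.array(
            [
                rng.normal(0.0, 1.0),  # logit mu
                rng.normal(1.0, 1.0),  # log phi
                rng.normal(-4.0, 1.5),  # logit K
                rng.normal(-0.5, 0.7),  # log v
            ]
        )
        res = optimize.minimize(
            _learner_loss,
            x0=x0,
            args=(tones, choices, n_grid, p, fit_k),
            method="Nelder-Mead",
            options={"maxiter": 500, "xatol": 1e-3, "fatol": 1e-5},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_converged:
        warnings.warn(
            "no optimization start converged; reporting best parameters found",
            stacklevel=2,
        )
    logit_mu, log_phi, logit_k, log_v = np.clip(best.x, -_THETA_BOUND, _THETA_BOUND)
    v = float(np.exp(log_v))
    return LearnerParams(
        mu=float(special.expit(logit_mu)),
        phi=float(np.exp(log_phi)),
        K=float(special.expit(logit_k)) if fit_k else 0.0,
        v=v,
        p=p,
        fit_loss=float(best.fun),
        converged=any_converged,
        weakly_identified=bool(
            v > 5.0 or best.fun / tones.size > np.log(2) - 0.01
        ),
    )


def reference_trace(tones, n_grid: int = DEFAULT_N_GRID) -> LearnerTrace:
    """Learner trace under the wide-prior reference model (mu=0.5, phi=2).

    This is the fixed benchmark model used to define
    subject-independent belief-strength and surprisal regressors.
    """
    return run(tones, REFERENCE_PARAMS, n_grid=n_grid)
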
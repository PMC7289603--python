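"""Two-source, hazard-switching auditory task environment.

A hidden source sits on the left (0) or right (1) and switches sides
between trials with a per-trial hazard rate H.  On each trial the active
source emits a tone on its own side with probability ``p`` (0.8 by
default), i.e. on ``1 - p`` of trials the tone plays opposite the
generating source.  Hazard rate itself changes in unannounced blocks.

Side coding is left=0 / right=1 everywhere in this package; positive
log-odds favor the right source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "TrialSequence",
    "generate_session",
    "make_fixed_schedule",
    "DEFAULT_HAZARDS",
]

#: The three hazard-rate conditions of the task: low, intermediate, high.
DEFAULT_HAZARDS = (0.01, 0.30, 0.99)

#: Hazard value -> condition label used throughout the package.
HAZARD_LABELS = {0.01: "low", 0.30: "int", 0.99: "high"}


@dataclass
class TaskConfig:
    """Configuration of one simulated session.

    Parameters
    ----------
    hazard_values
        Hazard-rate conditions available to random schedules.
    p
        Probability the active source emits the tone on its own side;
        must lie in (0.5, 1].
    n_trials
        Trials per session (ignored when ``block_schedule`` is given,
        in which case block lengths define the session length).
    block_schedule
        Explicit ``[(hazard, length), ...]``.  When ``None``, block
        lengths are drawn uniformly from ``block_length_range`` and
        hazards cycle through a random permutation of ``hazard_values``
        avoiding immediate repeats.
    block_length_range
        Inclusive bounds for random block lengths.
    seed
        Seed for all randomness in :func:`generate_session`.
    """

    hazard_values: tuple[float, ...] = DEFAULT_HAZARDS
    p: float = 0.8
    n_trials: int = 1000
    block_schedule: list[tuple[float, int]] | None = None
    block_length_range: tuple[int, int] = (100, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        for h in self.hazard_values:
            if not 0.0 < h < 1.0:
                raise ValueError(f"hazard value {h} outside (0, 1)")
        if self.block_schedule is not None:
            for h, n in self.block_schedule:
                if not 0.0 <= h <= 1.0:
                    raise ValueError(f"scheduled hazard {h} outside [0, 1]")
                if n <= 0:
                    raise ValueError("block lengths must be positive")
        if not 0.5 < self.p <= 1.0:
            raise ValueError(f"emission probability p={self.p} outside (0.5, 1]")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")


@dataclass
class TrialSequence:
    """Per-trial generative state of one session.

    Attributes are aligned ``numpy`` arrays of length ``n_trials``:
    ``source`` and ``tone`` are 0/1 sides, ``hazard`` the per-trial
    hazard rate, ``block_id`` the 0-based block index and
    ``j_objective`` the objective log-hazard-odds log[H/(1-H)].
    """

    source: np.ndarray
    tone: np.ndarray
    hazard: np.ndarray
    block_id: np.ndarray
    p: float = 0.8
    j_objective: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        h = np.asarray(self.hazard, dtype=float)
        with np.errstate(divide="ignore"):
            self.j_objective = np.log(h / (1.0 - h))

    def __len__(self) -> int:
        return len(self.tone)

    @property
    def hazard_label(self) -> np.ndarray:
        """Condition label per trial ('low'/'int'/'high', or 'H=x')."""
        return np.array(
            [HAZARD_LABELS.get(round(h, 6), f"H={h:g}") for h in self.hazard]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self)),
                "block_id": self.block_id,
                "hazard": self.hazard,
                "source": self.source,
                "tone": self.tone,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, p: float = 0.8) -> "TrialSequence":
        return cls(
            source=df["source"].to_numpy(int),
            tone=df["tone"].to_numpy(int),
            hazard=df["hazard"].to_numpy(float),
            block_id=df["block_id"].to_numpy(int),
            p=p,
        )


def _random_schedule(cfg: TaskConfig, rng: np.random.Generator) -> list[tuple[float, int]]:
    lo, hi = cfg.block_length_range
    schedule: list[tuple[float, int]] = []
    total = 0
    prev_h: float | None = None
    while total < cfg.n_trials:
        n = int(rng.integers(lo, hi + 1))
        n = min(n, cfg.n_trials - total)
        choices = [h for h in cfg.hazard_values if h != prev_h] or list(cfg.hazard_values)
        h = float(choices[rng.integers(len(choices))])
        schedule.append((h, n))
        prev_h = h
        total += n
    return schedule


def generate_session(config: TaskConfig) -> TrialSequence:
    """Simulate one session of the two-source task.

    The source follows a Markov chain whose switch probability on each
    trial is that trial's hazard rate; the tone equals the source side
    with probability ``config.p``, independently per trial.  The first
    trial's source is drawn uniformly.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    schedule = config.block_schedule
    if schedule is None:
        schedule = _random_schedule(config, rng)
    else:
        if sum(n for _, n in schedule) != config.n_trials:
            raise ValueError("explicit block lengths must sum to n_trials")

    hazard = np.concatenate([np.full(n, h) for h, n in schedule])
    block_id = np.concatenate(
        [np.full(n, i, dtype=int) for i, (_, n) in enumerate(schedule)]
    )
    n = len(hazard)

    switch = rng.random(n) < hazard
    switch[0] = False  # no switch defined on the first trial
    source = np.empty(n, dtype=int)
    source[0] = int(rng.integers(2))
    # cumulative XOR of switch indicators gives the source path
    source = (source[0] + np.cumsum(switch)) % 2

    flip = rng.random(n) >= config.p
    tone = np.where(flip, 1 - source, source)
    return TrialSequence(
        source=source, tone=tone, hazard=hazard, block_id=block_id, p=config.p
    )


# Reproducible default schedules: two hazard conditions per 1000-trial
# session, several unannounced blocks.  The study's exact sequences are
# not published, so these are statistical stand-ins with the same
# structure (two hazards per session, infrequent hazard switches).
_FIXED_SCHEDULES: dict[int, list[tuple[float, int]]] = {
    1: [(0.01, 240), (0.30, 190), (0.01, 310), (0.30, 260)],
    2: [(0.30, 280), (0.99, 210), (0.30, 230), (0.99, 280)],
    3: [(0.99, 260), (0.01, 290), (0.99, 200), (0.01, 250)],
}


def make_fixed_schedule(session_index: int, seed: int = 0, p: float = 0.8) -> TaskConfig:
    """Default schedule for session 1, 2 or 3.

    Each session pairs two of the three hazard conditions and contains
    four unannounced hazard blocks summing to 1000 trials.  The same
    index always yields the same schedule.
    """
    if session_index not in _FIXED_SCHEDULES:
        raise ValueError(f"session_index must be in {{1, 2, 3}}, got {session_index}")
    schedule = _FIXED_SCHEDULES[session_index]
    return TaskConfig(
        p=p,
        n_trials=sum(n for _, n in schedule),
        block_schedule=list(schedule),
        seed=seed,
    )
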
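"""Pupillometry preprocessing: artifact rejection, filtering, epoching.

The cleaning pipeline follows standard practice for video-based eye
trackers sampling at 60 Hz:

1. reject samples with abnormally fast diameter changes (first
   difference beyond 3 robust SDs from the median temporal
   derivative), which flags blink edges;
2. reject samples with gaze more than 10% of the screen diagonal from
   the fixation point;
3. regress gaze x/y out of the surviving diameter samples (pupil
   foreshortening covaries with eye position) and keep residual + mean;
4. linearly interpolate rejected/missing samples (edges filled with
   the nearest valid value);
5. low-pass with a first-order Butterworth at 4 Hz, applied
   forward-backward for zero phase.

Per-trial measures are the baseline (mean diameter 0-100 ms before
tone onset) and the baseline-subtracted evoked timecourse over the 2 s
after onset (121 samples at 60 Hz).  Trials with more than 50% of
their samples interpolated are flagged excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "PupilRecording",
    "TrialPupil",
    "clean",
    "downsample_to_60",
    "epoch",
    "zscore_recording",
]

EVOKED_WINDOW_S = 2.0
BASELINE_WINDOW_MS = 100.0
FILTER_CUTOFF_HZ = 4.0
GAZE_REJECT_FRACTION = 0.10
DERIV_SD_MULTIPLE = 3.0
EXCLUDE_INTERP_FRACTION = 0.5
#: two derivative spikes closer than this bracket one blink: the lid
#: sweep produces a fast down- and up-stroke with a depressed plateau
#: in between, all of which must be replaced
BLINK_BRIDGE_S = 0.5


@dataclass
class PupilRecording:
    """A continuous eye-tracker recording.

    time is in ms and uniformly sampled at ``rate`` Hz; gaze is in
    screen fractions with the screen modeled as a unit square
    (diagonal sqrt(2)) unless stated otherwise.
    """

    time: np.ndarray
    diameter: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    rate: float = 60.0
    fixation_point: tuple[float, float] = (0.5, 0.5)
    screen_diagonal: float = float(np.sqrt(2.0))

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.time,
                "diameter": self.diameter,
                "gaze_x": self.gaze_x,
                "gaze_y": self.gaze_y,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rate: float = 60.0, **kwargs) -> "PupilRecording":
        return cls(
            time=df["time_ms"].to_numpy(float),
            diameter=df["diameter"].to_numpy(float),
            gaze_x=df["gaze_x"].to_numpy(float),
            gaze_y=df["gaze_y"].to_numpy(float),
            rate=rate,
            **kwargs,
        )


@dataclass
class TrialPupil:
    """Per-trial pupil measures for one session (arrays over trials)."""

    baseline: np.ndarray  # (n,)
    evoked: np.ndarray  # (n, 121) baseline-subtracted
    peak_evoked: np.ndarray  # (n,)
    next_baseline: np.ndarray  # (n,) baseline of trial t+1 (NaN on last)
    frac_interpolated: np.ndarray  # (n,)
    excluded: np.ndarray  # (n,) bool

    def __len__(self) -> int:
        return len(self.baseline)

    def to_frame(self) -> pd.DataFrame:
        n_samp = self.evoked.shape[1]
        df = pd.DataFrame(
            {
                "trial": np.arange(len(self)),
                "baseline": self.baseline,
                "peak_evoked": self.peak_evoked,
                "next_baseline": self.next_baseline,
                "frac_interpolated": self.frac_interpolated,
                "excluded": self.excluded.astype(int),
            }
        )
        evoked = pd.DataFrame(
            self.evoked, columns=[f"evoked_{i}" for i in range(n_samp)]
        )
        return pd.concat([df, evoked], axis=1)


def _robust_sd(x: np.ndarray) -> float:
    """1.4826 x MAD, falling back to the ordinary SD when degenerate."""
    mad = np.nanmedian(np.abs(x - np.nanmedian(x)))
    sd = 1.4826 * mad
    if sd == 0.0:
        sd = float(np.nanstd(x))
    return sd


def clean(recording: PupilRecording) -> tuple[PupilRecording, np.ndarray]:
    """Clean a recording; returns (cleaned recording, interpolation mask).

    The mask marks samples that were rejected (derivative spike, gaze
    excursion, or missing) and replaced by interpolation.  Raises if
    more than 90% of samples are rejected.
    """
    n = len(recording)
    if n < int(2 * recording.rate):
        raise ValueError("need at least 2 s of data to clean a recording")
    diam = np.asarray(recording.diameter, dtype=float).copy()
    mask = ~np.isfinite(diam)

    # 1) derivative spikes (blink edges): mark both endpoints of any
    # first difference beyond 3 robust SDs from the median derivative
    d = np.diff(diam)
    med = np.nanmedian(d)
    sd = _robust_sd(d)
    if sd > 0:
        bad = np.abs(d - med) > DERIV_SD_MULTIPLE * sd
        bad = np.flatnonzero(bad & np.isfinite(d))
        mask[bad] = True
        mask[bad + 1] = True
        # bridge paired spikes: a blink's down- and up-stroke flank a
        # depressed plateau that must be replaced as well
        bridge = int(BLINK_BRIDGE_S * recording.rate)
        for a, b in zip(bad[:-1], bad[1:]):
            if b - a <= bridge:
                mask[a : b + 2] = True

    # 2) gaze excursions beyond 10% of the screen diagonal
    fx, fy = recording.fixation_point
    dist = np.hypot(recording.gaze_x - fx, recording.gaze_y - fy)
    with np.errstate(invalid="ignore"):
        mask |= ~np.isfinite(dist) | (dist > GAZE_REJECT_FRACTION * recording.screen_diagonal)

    if mask.mean() > 0.9:
        raise ValueError(
            f"{100 * mask.mean():.0f}% of samples rejected; recording unusable"
        )

    # 3) regress gaze out of the surviving samples, keep residual + mean
    good = ~mask
    X = np.column_stack(
        [np.ones(n), recording.gaze_x, recording.gaze_y]
    )
    beta, *_ = np.linalg.lstsq(X[good], diam[good], rcond=None)
    diam[good] = diam[good] - X[good] @ beta + np.mean(diam[good])

    # 4) linear interpolation of rejected samples; edges -> nearest valid
    idx = np.arange(n)
    diam = np.interp(idx, idx[good], diam[good])

    # 5) zero-phase first-order Butterworth low-pass at 4 Hz
    b, a = signal.butter(1, FILTER_CUTOFF_HZ, fs=recording.rate)
    diam = signal.filtfilt(b, a, diam)

    return replace(recording, diameter=diam), mask


def downsample_to_60(recording: PupilRecording) -> PupilRecording:
    """Anti-aliased resampling of a high-rate recording to 60 Hz."""
    if recording.rate < 60:
        raise ValueError(f"input rate {recording.rate} Hz is below 60 Hz")
    if recording.rate == 60:
        return recording
    frac = Fraction(60, int(round(recording.rate))).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    diam = signal.resample_poly(recording.diameter, up, down, padtype="line")
    gx = signal.resample_poly(recording.gaze_x, up, down, padtype="line")
    gy = signal.resample_poly(recording.gaze_y, up, down, padtype="line")
    t0 = recording.time[0]
    time = t0 + np.arange(len(diam)) * (1000.0 / 60.0)
    return replace(
        recording, time=time, diameter=diam, gaze_x=gx, gaze_y=gy, rate=60.0
    )


def zscore_recording(recording: PupilRecording) -> PupilRecording:
    """Z-score the diameter within the session (tracker units differ)."""
    d = recording.diameter
    sd = np.std(d)
    z = (d - np.mean(d)) / (sd if sd > 0 else 1.0)
    return replace(recording, diameter=z)


def epoch(
    cleaned: PupilRecording,
    mask: np.ndarray,
    tone_onsets_ms,
) -> TrialPupil:
    """Extract per-trial baseline and evoked measures.

    Baseline: mean diameter over the 100 ms before tone onset.  Evoked:
    baseline-subtracted diameter over the 2 s after onset (121 samples
    at 60 Hz).  Trials whose window falls outside the recording or has
    more than 50% interpolated samples are flagged excluded.
    """
    onsets = np.asarray(tone_onsets_ms, dtype=float)
    n = len(onsets)
    n_evoked = int(round(EVOKED_WINDOW_S * 60)) + 1  # 121 samples
    time = cleaned.time
    diam = cleaned.diameter

    baseline = np.full(n, np.nan)
    evoked = np.full((n, n_evoked), np.nan)
    peak = np.full(n, np.nan)
    frac = np.ones(n)
    excluded = np.ones(n, dtype=bool)

    for t, onset in enumerate(onsets):
        b0 = np.searchsorted(time, onset - BASELINE_WINDOW_MS, side="left")
        b1 = np.searchsorted(time, onset, side="left")
        e0 = np.searchsorted(time, onset, side="left")
        e1 = e0 + n_evoked
        if onset - BASELINE_WINDOW_MS < time[0] or b1 <= b0 or e1 > len(time):
            continue  # too close to the recording edge: stays excluded
        baseline[t] = np.mean(diam[b0:b1])
        evoked[t] = diam[e0:e1] - baseline[t]
        peak[t] = np.max(evoked[t])
        window_mask = mask[b0:e1]
        frac[t] = float(np.mean(window_mask))
        excluded[t] = frac[t] > EXCLUDE_INTERP_FRACTION

    next_baseline = np.append(baseline[1:], np.nan)
    return TrialPupil(
        baseline=baseline,
        evoked=evoked,
        peak_evoked=peak,
        next_baseline=next_baseline,
        frac_interpolated=frac,
        excluded=excluded,
    )
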
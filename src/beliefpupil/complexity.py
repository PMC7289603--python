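"""Information-bottleneck measure of belief-updating complexity.

How much information about past task conditions does a subject's
current prediction carry?  The measure is the mutual information (in
bits) between the previous trial's task features F — the six
combinations of tone side (left/right) and hazard condition
(low/intermediate/high) — and the current binary prediction R:

    I_past = I(F_{t-1}; R_t) = sum_{r,f} Pr(r,f) log2[Pr(r,f) / (Pr(r) Pr(f))]

Part of that information is carried by the tone sequence itself (e.g.
tones repeat under a low hazard), so the sequence information
I(x_{t-1}; x_t), estimated on the same trials, is subtracted.  The
remainder quantifies what the subject encodes about the hazard context
beyond the stimuli.  More complex updating strategies (e.g. a learner
with a wide prior over hazard) encode more past information than
simple ones (a fixed-hazard or constant responder).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ComplexityResult",
    "mutual_information",
    "contingency",
    "complexity",
    "tercile_groups",
]


@dataclass
class ComplexityResult:
    """Raw, sequence, and corrected mutual information (bits)."""

    i_past_raw: float
    i_seq: float
    i_past_corrected: float
    n_trials_used: int


def mutual_information(joint_counts) -> float:
    """Plug-in mutual information (bits) of a 2-way contingency table.

    Cells with zero joint probability contribute 0 (the 0*log 0 := 0
    convention).  Raises on an all-zero table.
    """
    counts = np.asarray(joint_counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("joint_counts must be a 2-way table")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("contingency table is all zero")
    pj = counts / total
    pr = pj.sum(axis=1, keepdims=True)
    pc = pj.sum(axis=0, keepdims=True)
    nz = pj > 0
    ratio = np.ones_like(pj)
    ratio[nz] = pj[nz] / (pr @ pc)[nz]
    return float(np.sum(pj[nz] * np.log2(ratio[nz])))


def contingency(a, b, levels_a, levels_b) -> np.ndarray:
    """Joint count table of two aligned categorical sequences."""
    a = np.asarray(a)
    b = np.asarray(b)
    table = np.zeros((len(levels_a), len(levels_b)))
    for i, la in enumerate(levels_a):
        for j, lb in enumerate(levels_b):
            table[i, j] = np.sum((a == la) & (b == lb))
    return table


def complexity(
    predictions,
    tones,
    hazard_labels,
    session_ids=None,
) -> ComplexityResult:
    """Belief-updating complexity of one subject's predictions.

    ``predictions``, ``tones`` and ``hazard_labels`` are aligned
    per-trial sequences (possibly concatenated over sessions, with
    ``session_ids`` marking the boundaries).  Features are taken from
    the trial immediately preceding each prediction; the first trial of
    each session is dropped.  I_past is computed on the pooled 6x2
    table; the tone-sequence information I(x_{t-1}; x_t) is computed
    per session on the same trials and pooled by trial-weighted
    average.
    """
    predictions = np.asarray(predictions)
    tones = np.asarray(tones)
    hazard_labels = np.asarray(hazard_labels)
    n = len(predictions)
    if not (len(tones) == n == len(hazard_labels)):
        raise ValueError("predictions, tones and hazard_labels must be aligned")
    if session_ids is None:
        session_ids = np.zeros(n, dtype=int)
    session_ids = np.asarray(session_ids)

    hl = np.unique(hazard_labels)
    hz_index = np.searchsorted(hl, hazard_labels)
    # feature code: tone side x hazard condition, 2 * len(hl) levels
    feat = tones * len(hl) + hz_index
    feat_levels = np.arange(2 * len(hl))

    table_past = np.zeros((len(feat_levels), 2))
    i_seq_parts: list[tuple[float, int]] = []
    n_used = 0
    for sid in np.unique(session_ids):
        m = session_ids == sid
        tn, pred, ft = tones[m], predictions[m], feat[m]
        if len(tn) < 2:
            continue
        table_past += contingency(ft[:-1], pred[1:], feat_levels, (0, 1))
        seq_table = contingency(tn[:-1], tn[1:], (0, 1), (0, 1))
        i_seq_parts.append((mutual_information(seq_table), len(tn) - 1))
        n_used += len(tn) - 1

    if n_used < 100:
        warnings.warn(
            f"only {n_used} usable trials; mutual-information estimates "
            "carry substantial finite-sample bias",
            stacklevel=2,
        )
    if n_used == 0:
        raise ValueError("no usable trials (need at least 2 trials per session)")
    i_past = mutual_information(table_past)
    i_seq = sum(v * w for v, w in i_seq_parts) / n_used
    return ComplexityResult(
        i_past_raw=i_past,
        i_seq=i_seq,
        i_past_corrected=i_past - i_seq,
        n_trials_used=n_used,
    )


def tercile_groups(complexities) -> np.ndarray:
    """Split subjects into lower/middle/upper complexity terciles.

    Returns an integer label per subject (0 = lower, 1 = middle,
    2 = upper).  Ties and non-divisible cohort sizes are resolved by a
    stable sort on subject order: subjects are ranked by complexity
    (equal values keep input order) and the ranking is cut into three
    nearly equal groups, the earlier groups taking any extra member.
    """
    c = np.asarray(complexities, dtype=float)
    n = len(c)
    if n < 3:
        raise ValueError(f"need at least 3 subjects for terciles, got {n}")
    order = np.argsort(c, kind="stable")
    sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    labels = np.empty(n, dtype=int)
    start = 0
    for g, size in enumerate(sizes):
        labels[order[start : start + size]] = g
        start += size
    return labels
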
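"""Independent brute-force oracles used to validate the recursions.

These deliberately avoid the package's filtering code paths: the joint
posterior over (hazard, source) is obtained by exhaustively summing
over every possible source path, marginalizing the hazard dimension
with explicit kernel matrix products along each path.
"""

import itertools

import numpy as np


def enumerate_posterior(
    tones: np.ndarray,
    h_grid: np.ndarray,
    prior0: np.ndarray,
    K: float,
    p: float,
) -> np.ndarray:
    """Exact joint posterior Pr(H_T, z_T | x_{1:T}) by path enumeration.

    The generative model: z_0 uniform, H_0 ~ prior0; each trial H_t
    either stays (prob 1-K) or is redrawn from prior0, z_t switches
    with probability H_t, and tone x_t matches z_t with probability p.
    For every source path (z_0, ..., z_T) the hazard dimension is
    marginalized by a per-step vector recursion; the paths are then
    summed.  Complexity O(2^(T+1) * T * len(h_grid)).
    """
    T = len(tones)
    g = len(h_grid)
    joint = np.zeros((g, 2))
    for path in itertools.product((0, 1), repeat=T + 1):
        u = prior0 * 0.5  # Pr(H_0) * Pr(z_0)
        for t in range(T):
            u = (1.0 - K) * u + K * prior0 * u.sum()  # hazard kernel
            stay = path[t + 1] == path[t]
            u = u * np.where(stay, 1.0 - h_grid, h_grid)  # source kernel
            u = u * (p if tones[t] == path[t + 1] else 1.0 - p)  # likelihood
        joint[:, path[-1]] += u
    return joint / joint.sum()
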
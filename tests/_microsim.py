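"""Independent microsimulation oracle for the cohort engine.

Walks individual patients through the same per-cycle transition matrices the
cohort engine builds, by direct multinomial sampling. Shares only the matrix
construction with the implementation under test; the propagation path
(individual sampling vs deterministic recursion) is fully independent.
"""

import numpy as np

from gscea.cohort_engine import build_cycle_matrices


def microsimulate(branch, config, n_walkers, seed):
    """Simulate *n_walkers* individuals; returns occupancy fractions of the
    five collapsed states at every cycle boundary, shape (K+1, 5)."""
    rng = np.random.default_rng(seed)
    M = build_cycle_matrices(branch, config)
    K, S, _ = M.shape
    n_chf = S - 4  # internal CHF tenure substates

    cum = np.cumsum(M, axis=2)
    states = np.zeros(n_walkers, dtype=np.int64)
    occupancy = np.zeros((K + 1, S))
    occupancy[0] = np.bincount(states, minlength=S) / n_walkers
    for k in range(K):
        u = rng.random(n_walkers)
        rows = cum[k, states]  # (n, S)
        states = (u[:, None] > rows).sum(axis=1)
        occupancy[k + 1] = np.bincount(states, minlength=S) / n_walkers

    out = np.zeros((K + 1, 5))
    out[:, 0] = occupancy[:, 0]
    out[:, 1] = occupancy[:, 1]
    out[:, 2] = occupancy[:, 2]
    out[:, 3] = occupancy[:, 3 : 3 + n_chf].sum(axis=1)
    out[:, 4] = occupancy[:, -1]
    return out


def binomial_se(p, n):
    return np.sqrt(np.maximum(p * (1.0 - p), 1e-12) / n)
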
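"""Numba kernels for the Monte Carlo coalescent engine.

The single hot loop of the whole package lives here: sampling
inter-coalescence waiting times under a piecewise-exponential Ne(t)
trajectory.  With ``k`` active lineages the instantaneous pairwise merger
rate is ``k(k-1)/(4 Ne(t))``; waiting times are obtained by inverting the
integrated rate in closed form within each epoch (exact time rescaling, no
Euler discretisation) applied to unit-exponential draws.

Several candidate trajectories are evaluated simultaneously against the
*same* matrix of unit-exponential draws (common random numbers), which is
what makes noisy likelihood comparisons between nearby parameter proposals
reliable.  Two structural shortcuts keep the kernel fast without changing
the estimator:

- a single-epoch (constant-size) trajectory has ``W_k`` exactly
  proportional to the draw, so only the per-``k`` column means of the draw
  matrix are needed;
- once a simulation's time has entered the final (constant, infinite)
  epoch every remaining waiting time is again proportional to its draw,
  so the remaining steps collapse to multiply-adds.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["mean_intercoal_times"]


@njit(cache=True)
def _mean_wk_from_draws(t_start, t_end, size0, rate, n_ep, n_lineages, E):
    n_cand = t_start.shape[0]
    n_sims, nk = E.shape
    w_mean = np.zeros((n_cand, nk))

    # inv_rate[j] = 4 / (k (k - 1)) for the j-th event (k = n_lineages - j)
    inv_rate = np.empty(nk)
    for j in range(nk):
        k = n_lineages - j
        inv_rate[j] = 4.0 / (k * (k - 1.0))

    e_bar = np.zeros(nk)
    for s in range(n_sims):
        for j in range(nk):
            e_bar[j] += E[s, j]
    for j in range(nk):
        e_bar[j] /= n_sims

    for c in range(n_cand):
        ne = n_ep[c]
        if ne == 1:
            n0 = size0[c, 0]
            for j in range(nk):
                w_mean[c, n_lineages - j - 2] = e_bar[j] * inv_rate[j] * n0
            continue
        n_last = size0[c, ne - 1]
        for s in range(n_sims):
            t = 0.0
            e = 0
            for j in range(nk):
                if e == ne - 1:
                    # remaining history is a plain constant-size coalescent
                    for jj in range(j, nk):
                        w_mean[c, n_lineages - jj - 2] += E[s, jj] * inv_rate[jj] * n_last
                    break
                ccoef = 1.0 / inv_rate[j]
                rem = E[s, j]
                t0 = t
                while True:
                    r = rate[c, e]
                    n0 = size0[c, e]
                    te = t_end[c, e]
                    if r == 0.0:
                        w = rem * n0 / ccoef
                        if t + w < te:
                            t = t + w
                            break
                        rem -= ccoef * (te - t) / n0
                    else:
                        ts = t_start[c, e]
                        a = np.exp(-r * (t - ts))
                        b = np.exp(-r * (te - ts))
                        h_full = ccoef * (a - b) / (r * n0)
                        if rem < h_full:
                            t = ts - np.log(a - rem * r * n0 / ccoef) / r
                            break
                        rem -= h_full
                    t = te
                    e += 1
                w_mean[c, n_lineages - j - 2] += t - t0
        for j in range(nk):
            if n_ep[c] > 1:
                w_mean[c, j] /= n_sims
    return w_mean


def mean_intercoal_times(
    epoch_arrays: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    n_lineages: int,
    n_sims: int,
    seed: int,
) -> np.ndarray:
    """Monte Carlo means of the waiting times spent with k active lineages.

    Parameters
    ----------
    epoch_arrays
        ``(t_start, t_end, size0, rate, n_ep)`` packed candidate
        trajectories, shapes ``(n_candidates, max_epochs)`` and
        ``(n_candidates,)``.
    n_lineages
        Sampled chromosomes (2n).
    n_sims
        Number of simulated genealogies.
    seed
        Seed for the draw stream (< 2**31); identical seeds give identical
        draws, shared across all candidates.

    Returns
    -------
    ndarray of shape ``(n_candidates, n_lineages - 1)`` — column ``j`` is
    the mean time with ``k = j + 2`` lineages.
    """
    t_start, t_end, size0, rate, n_ep = epoch_arrays
    rng = np.random.default_rng(int(seed))
    draws = rng.standard_exponential((int(n_sims), int(n_lineages) - 1))
    return _mean_wk_from_draws(t_start, t_end, size0, rate, n_ep, int(n_lineages), draws)
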
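"""Monte Carlo coalescent engine: expected (folded) SFS under a model.

The expected SFS is obtained by branch-length linearisation: under the
infinite-sites model with per-site mutation rate ``mu`` small enough that
``mu * E[tree length] << 1``, the probability that a site carries a variant
at unfolded frequency ``i`` is ``p_i = mu * E[t_i]`` where ``t_i`` is the
total genealogy branch length subtending exactly ``i`` of the ``2n``
sampled chromosomes.

``E[t_i]`` is estimated by simulating inter-coalescence waiting times and
marginalising the tree topology analytically: conditional on ``k`` active
ancestral lineages, a given lineage subtends ``i`` of ``n`` leaves with
probability ``C(n-i-1, k-2) / C(n-1, k-1)`` (a classical exchangeable-
coalescent identity), so

    E[t_i] = sum_k  k * E[W_k] * C(n-i-1, k-2) / C(n-1, k-1),

with ``W_k`` the time during which exactly ``k`` lineages are active.
Only the ``W_k`` need Monte Carlo; the analytic topology marginalisation
removes the (large) variance contributed by random pair merging.
``simulate_genealogy`` provides the fully explicit single-genealogy
simulator (random topology included) used for cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from sfsdemog._kernels import mean_intercoal_times
from sfsdemog.demography import DemographicModel
from sfsdemog.sfs import SpectrumData

__all__ = [
    "BranchLengthProfile",
    "ExpectedSFS",
    "simulate_genealogy",
    "branch_length_profile",
    "expected_sfs",
    "expected_sfs_multi",
    "draw_sfs",
    "leaf_subtending_probabilities",
]


@dataclass(frozen=True)
class BranchLengthProfile:
    """Mean per-frequency-class branch lengths over simulated genealogies.

    ``t_i[i-1]`` is the mean total branch length (generations) subtending
    exactly ``i`` of the ``n_lineages`` sampled chromosomes.
    """

    n_lineages: int
    t_i: np.ndarray
    n_sims: int

    @property
    def total_length(self) -> float:
        return float(self.t_i.sum())


@dataclass(frozen=True)
class ExpectedSFS:
    """Per-site frequency-class probabilities under a demographic model.

    ``probs[0]`` is the monomorphic class.  Folded spectra have ``n + 1``
    classes for ``2n`` chromosomes; unfolded spectra ``2n + 1`` (the
    fixed-derived class carries no branch length and is always 0).
    Monte Carlo zeros are floored at ``1 / (10 * n_sims * n_classes)`` so
    that downstream log-likelihoods stay finite.
    """

    probs: np.ndarray
    n_chromosomes: int
    mu: float
    folded: bool
    n_sims: int
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected_len = (
            self.n_chromosomes // 2 + 1 if self.folded else self.n_chromosomes + 1
        )
        if len(self.probs) != expected_len:
            raise ValueError(
                f"probs length {len(self.probs)} does not match "
                f"{'folded' if self.folded else 'unfolded'} 2n={self.n_chromosomes}"
            )


@lru_cache(maxsize=32)
def leaf_subtending_probabilities(n_lineages: int) -> np.ndarray:
    """Matrix ``P[k-2, i-1] = P(branch subtends i of n leaves | k lineages)``.

    Computed with log-gamma for numerical safety at large n; each row sums
    to 1.
    """
    n = n_lineages
    k = np.arange(2, n + 1)[:, None]  # rows
    i = np.arange(1, n)[None, :]  # columns

    def log_binom(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    with np.errstate(invalid="ignore"):
        logp = log_binom(n - i - 1, k - 2) - log_binom(n - 1, k - 1)
    p = np.exp(logp)
    # C(n-i-1, k-2) is zero whenever k-2 > n-i-1
    p[(k - 2) > (n - i - 1)] = 0.0
    return p


def _pack_models(models: list[DemographicModel]) -> tuple:
    max_ep = max(len(m.epochs) for m in models)
    n_cand = len(models)
    t_start = np.zeros((n_cand, max_ep))
    t_end = np.full((n_cand, max_ep), np.inf)
    size0 = np.ones((n_cand, max_ep))
    rate = np.zeros((n_cand, max_ep))
    n_ep = np.zeros(n_cand, dtype=np.int64)
    for c, m in enumerate(models):
        if m.epochs[-1].rate != 0.0:
            raise ValueError("final (infinite) epoch must be constant-size")
        n_ep[c] = len(m.epochs)
        for e, ep in enumerate(m.epochs):
            t_start[c, e] = ep.t_start
            t_end[c, e] = ep.t_end
            size0[c, e] = ep.size_start
            rate[c, e] = ep.rate
    return t_start, t_end, size0, rate, n_ep


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def _advance_time(epochs, t: float, rem: float, ccoef: float) -> float:
    """Invert the integrated pairwise coalescence rate from time ``t``.

    ``rem`` is a unit-exponential draw; ``ccoef = k(k-1)/4``.  Returns the
    event time (exact time rescaling, closed form in every epoch).
    """
    e = 0
    while e < len(epochs) - 1 and t >= epochs[e].t_end:
        e += 1
    while True:
        ep = epochs[e]
        if ep.rate == 0.0:
            w = rem * ep.size_start / ccoef
            if t + w < ep.t_end:
                return t + w
            rem -= ccoef * (ep.t_end - t) / ep.size_start
        else:
            a = math.exp(-ep.rate * (t - ep.t_start))
            b = math.exp(-ep.rate * (ep.t_end - ep.t_start))
            h_full = ccoef * (a - b) / (ep.rate * ep.size_start)
            if rem < h_full:
                x = a - rem * ep.rate * ep.size_start / ccoef
                return ep.t_start - math.log(x) / ep.rate
            rem -= h_full
        t = ep.t_end
        e += 1


def simulate_genealogy(model: DemographicModel, n_lineages: int, rng) -> np.ndarray:
    """Simulate one explicit coalescent genealogy; return per-class branch lengths.

    Random pair merging is simulated explicitly (no topology
    marginalisation).  Returns an array of length ``n_lineages - 1`` whose
    entry ``i-1`` is the branch length subtending ``i`` leaves.
    """
    if n_lineages < 2:
        raise ValueError("need at least 2 lineages")
    rng = _as_rng(rng)
    epochs = model.epochs
    if epochs[-1].rate != 0.0:
        raise ValueError("final (infinite) epoch must be constant-size")
    t_i = np.zeros(n_lineages - 1)
    blocks = [1] * n_lineages  # leaves subtended by each active lineage
    t = 0.0
    for k in range(n_lineages, 1, -1):
        rem = float(rng.standard_exponential())
        t_new = _advance_time(epochs, t, rem, k * (k - 1) / 4.0)
        w = t_new - t
        for size in blocks:
            t_i[size - 1] += w
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        blocks[i] += blocks[j]
        del blocks[j]
        t = t_new
    return t_i


def branch_length_profile(
    model: DemographicModel, n_lineages: int, n_sims: int, rng
) -> BranchLengthProfile:
    """Average per-class branch lengths over ``n_sims`` explicit genealogies."""
    rng = _as_rng(rng)
    acc = np.zeros(n_lineages - 1)
    for _ in range(n_sims):
        acc += simulate_genealogy(model, n_lineages, rng)
    return BranchLengthProfile(n_lineages=n_lineages, t_i=acc / n_sims, n_sims=n_sims)


def _fold_probs(p_unfolded: np.ndarray, n_chrom: int) -> np.ndarray:
    n = n_chrom // 2
    folded = np.empty(n + 1)
    folded[0] = p_unfolded[0] + p_unfolded[n_chrom]
    for i in range(1, n):
        folded[i] = p_unfolded[i] + p_unfolded[n_chrom - i]
    folded[n] = p_unfolded[n]
    return folded


def _probs_from_wk(
    w_mean: np.ndarray, n_lineages: int, mu: float, fold: bool
) -> np.ndarray:
    """Map mean waiting times (per candidate) to SFS class probabilities."""
    k = np.arange(2, n_lineages + 1)
    t_i = (w_mean * k) @ leaf_subtending_probabilities(n_lineages)  # (C, n-1)
    p_var = mu * t_i
    n_cand = w_mean.shape[0]
    p = np.zeros((n_cand, n_lineages + 1))
    p[:, 1:n_lineages] = p_var
    p[:, 0] = 1.0 - p_var.sum(axis=1)
    if np.any(p[:, 0] < 0):
        raise ValueError(
            "mu * E[tree length] too large for the infinite-sites linearisation; "
            "use a smaller mu or rescale the analysis"
        )
    if fold:
        p = np.stack([_fold_probs(row, n_lineages) for row in p])
    return p


def _floor_probs(p: np.ndarray, n_sims: int, folded: bool) -> np.ndarray:
    floor = 1.0 / (10.0 * n_sims * p.shape[-1])
    out = np.where(p <= 0.0, floor, p)
    if not folded:
        # the fixed-derived class carries no branch length; leave it at zero
        out[..., -1] = p[..., -1]
    return out


def expected_sfs(
    model: DemographicModel,
    n_lineages: int,
    mu: float,
    n_sims: int,
    rng,
    fold: bool = True,
    n_batches: int = 1,
) -> ExpectedSFS:
    """Monte Carlo expected SFS for one model.

    With ``n_batches > 1`` the simulations are split into equal batches and
    the returned ``se`` holds per-class standard errors of the batch means,
    which is what the engine's own convergence checks use.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if mu <= 0:
        raise ValueError("mu must be positive")
    rng = _as_rng(rng)
    packed = _pack_models([model])
    if n_batches <= 1:
        w = mean_intercoal_times(packed, n_lineages, n_sims, _kernel_seed(rng))
        probs = _probs_from_wk(w, n_lineages, mu, fold)[0]
        se = None
    else:
        per = max(1, n_sims // n_batches)
        batch_probs = []
        for _ in range(n_batches):
            w = mean_intercoal_times(packed, n_lineages, per, _kernel_seed(rng))
            batch_probs.append(_probs_from_wk(w, n_lineages, mu, fold)[0])
        batch_probs = np.stack(batch_probs)
        probs = batch_probs.mean(axis=0)
        se = batch_probs.std(axis=0, ddof=1) / math.sqrt(n_batches)
    probs = _floor_probs(probs, n_sims, fold)
    return ExpectedSFS(
        probs=probs, n_chromosomes=n_lineages, mu=mu, folded=fold, n_sims=n_sims, se=se
    )


def expected_sfs_multi(
    models: list[DemographicModel],
    n_lineages: int,
    mu: float,
    n_sims: int,
    seed: int,
    fold: bool = True,
) -> np.ndarray:
    """Expected-SFS probability rows for several candidate models at once.

    All candidates are driven by a *common* stream of exponential draws,
    so differences between rows reflect the trajectories, not Monte Carlo
    noise — the estimator the likelihood optimizer relies on.
    """
    w = mean_intercoal_times(_pack_models(models), n_lineages, n_sims, seed)
    return _floor_probs(_probs_from_wk(w, n_lineages, mu, fold), n_sims, fold)


def draw_sfs(exp_sfs: ExpectedSFS, n_sites: int, rng) -> SpectrumData:
    """Multinomial draw of ``n_sites`` independent sites from an expected SFS."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = _as_rng(rng)
    p = np.asarray(exp_sfs.probs, dtype=float)
    counts = rng.multinomial(n_sites, p / p.sum())
    return SpectrumData(
        counts=counts.astype(float),
        folded=exp_sfs.folded,
        n_chromosomes=exp_sfs.n_chromosomes,
    )
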
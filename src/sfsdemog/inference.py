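"""Composite-likelihood fitting of demographic models to a folded SFS.

The composite likelihood treats sites as independent draws from the
expected SFS of the candidate model: ``ln CL = sum_i m_i ln p_i`` over
unmasked classes ``i`` with observed counts ``m_i`` and (renormalised)
expected class probabilities ``p_i``.  Likelihoods are reported in log10
units, and model support is summarised with AIC = -2 ln L + 2K.

Because the expected SFS is itself a Monte Carlo estimate, each proposal
comparison inside the optimizer evaluates the incumbent and its
alternatives with a common stream of coalescent draws (see
:mod:`sfsdemog.engine`), and all final likelihoods inside one fit — and
across model families in :func:`fit_models` — share one evaluation stream
so that AIC differences are not dominated by simulation noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from sfsdemog.demography import (
    DEFAULT_MU,
    DemographicModel,
    SearchRange,
    build_bottleneck_model,
    build_null_model,
    default_search_ranges,
)
from sfsdemog.engine import ExpectedSFS, expected_sfs_multi
from sfsdemog.sfs import SpectrumData, mask_singletons

__all__ = [
    "FitResult",
    "ModelComparison",
    "composite_log_likelihood",
    "max_observed_likelihood",
    "aic",
    "fit_model",
    "fit_models",
    "compare_models",
]

_LN10 = math.log(10.0)

#: Hard lower floor for any diploid size parameter during optimisation.
MIN_SIZE = 2.0

_FAMILIES = {
    "bottleneck": (("Ne_pre", "Ne_bot", "Ne_post"), lambda p: build_bottleneck_model(p["Ne_pre"], p["Ne_bot"], p["Ne_post"])),
    "null": (("Ne_post",), lambda p: build_null_model(p["Ne_post"])),
}


def _family(model_family: str):
    try:
        return _FAMILIES[model_family]
    except KeyError:
        raise ValueError(f"unknown model family {model_family!r}") from None


def build_family_model(model_family: str, params: dict[str, float]) -> DemographicModel:
    """Instantiate a model of the given family from named size parameters."""
    _, builder = _family(model_family)
    return builder(params)


def _ll_from_probs(counts: np.ndarray, unmasked: np.ndarray, probs: np.ndarray) -> float:
    """log10 composite likelihood from raw class probabilities."""
    p = probs[unmasked]
    p = p / p.sum()
    m = counts[unmasked]
    nz = m > 0
    return float(np.sum(m[nz] * np.log(p[nz])) / _LN10)


def composite_log_likelihood(obs: SpectrumData, expected: ExpectedSFS) -> float:
    """log10 composite likelihood of an observed SFS under an expected SFS.

    Expected probabilities are renormalised over the unmasked classes, so
    masked classes (e.g. singletons) contribute nothing and the remaining
    classes form a proper multinomial.
    """
    if expected.folded != obs.folded or expected.n_chromosomes != obs.n_chromosomes:
        raise ValueError("observed and expected spectra have mismatched shape")
    if len(expected.probs) != obs.n_classes:
        raise ValueError("observed and expected spectra have mismatched length")
    return _ll_from_probs(obs.counts, ~obs.mask, np.asarray(expected.probs, dtype=float))


def max_observed_likelihood(obs: SpectrumData) -> float:
    """log10 likelihood of the saturated multinomial (entropy bound).

    ``sum_i m_i ln(m_i / M)`` over unmasked classes with ``0 ln 0 = 0``;
    no expected SFS can exceed this for the same observed spectrum.
    """
    m = obs.counts[~obs.mask]
    total = m.sum()
    if total <= 0:
        raise ValueError("spectrum has no unmasked sites")
    nz = m > 0
    return float(np.sum(m[nz] * np.log(m[nz] / total)) / _LN10)


def aic(log10_cl: float, k: int) -> float:
    """Akaike information criterion from a log10 likelihood.

    ``AIC = -2 ln L + 2K`` with ``ln L = log10_cl * ln 10``.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    return -2.0 * log10_cl * _LN10 + 2.0 * k


@dataclass(frozen=True)
class FitResult:
    """Best-replicate composite-likelihood fit of one model family."""

    model_name: str
    estimates: dict[str, float]
    log10_cl: float
    delta_lhood: float
    aic: float
    n_replicates: int
    n_loops: int
    n_sims: int
    seed: int
    best_replicate_index: int
    obs_fingerprint: str = ""

    @property
    def k(self) -> int:
        return len(self.estimates)

    def model(self) -> DemographicModel:
        return build_family_model(self.model_name, self.estimates)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model_name,
                "estimates": self.estimates,
                "log10_cl": self.log10_cl,
                "delta_lhood": self.delta_lhood,
                "aic": self.aic,
                "k": self.k,
                "n_replicates": self.n_replicates,
                "n_loops": self.n_loops,
                "n_sims": self.n_sims,
                "seed": self.seed,
                "best_replicate_index": self.best_replicate_index,
            },
            indent=2,
        )

    def summary_row(self) -> dict:
        """One table row: model, likelihood, K, AIC and the size estimates."""
        return {
            "model": self.model_name,
            "max_log10_likelihood": self.log10_cl,
            "k": self.k,
            "aic": self.aic,
            "Ne_pre": self.estimates.get("Ne_pre"),
            "Ne_bot": self.estimates.get("Ne_bot"),
            "Ne_post": self.estimates.get("Ne_post"),
        }


@dataclass(frozen=True)
class ModelComparison:
    """AIC ranking of fits of different families to the same spectrum."""

    fits: tuple[FitResult, ...]
    preferred: str = field(init=False, default="")

    def __post_init__(self) -> None:
        if len(self.fits) < 2:
            raise ValueError("model comparison needs at least two fits")
        prints = {f.obs_fingerprint for f in self.fits}
        if len(prints) > 1:
            raise ValueError("fits were computed on different observed spectra")
        best = min(self.fits, key=lambda f: (f.aic, f.k))
        object.__setattr__(self, "preferred", best.model_name)

    def __getitem__(self, model_name: str) -> FitResult:
        for f in self.fits:
            if f.model_name == model_name:
                return f
        raise KeyError(model_name)

    def delta_aic(self) -> dict[str, float]:
        amin = min(f.aic for f in self.fits)
        return {f.model_name: f.aic - amin for f in self.fits}


def compare_models(fits: list[FitResult]) -> ModelComparison:
    """Rank fits by AIC (ties broken toward fewer parameters)."""
    return ModelComparison(fits=tuple(fits))


def _fingerprint(obs: SpectrumData) -> str:
    h = hash((obs.counts.tobytes(), obs.n_chromosomes, obs.folded))
    return f"{obs.total_sites:.1f}:{h & 0xFFFFFFFF:08x}"


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def _prepare_obs(obs: SpectrumData, apply_singleton_mask: bool) -> SpectrumData:
    if not obs.folded:
        raise ValueError("fit expects a folded spectrum")
    if apply_singleton_mask:
        obs = mask_singletons(obs)
    return obs


def _optimize_replicate(
    obs: SpectrumData,
    model_family: str,
    ranges: dict[str, SearchRange],
    n_loops: int,
    n_sims: int,
    mu: float,
    rep_rng: np.random.Generator,
) -> dict[str, float]:
    """One replicate: random start, coordinate-wise bracketed search.

    Each coordinate step evaluates the incumbent together with a lower and
    an upper proposal (geometric bracket in log-parameter space) against
    shared coalescent draws; the move is accepted only if it improves the
    composite likelihood, otherwise the bracket shrinks by the golden
    ratio.  Estimates may exceed the search-range upper limits, but the
    lower limits bound the search (with an absolute floor of 2 diploids),
    mirroring the search-range semantics of fastsimcoal-style ECM runs.
    """
    free, _ = _family(model_family)
    floors = {p: max(ranges[p].lower, MIN_SIZE) for p in free}
    params = {p: max(ranges[p].draw(rep_rng), floors[p]) for p in free}
    width = {p: 1.0 for p in free}
    unmasked = ~obs.mask
    counts = obs.counts
    n2 = obs.n_chromosomes
    for _ in range(n_loops):
        for p in free:
            w = width[p]
            cands = [params]
            for f in (math.exp(-w), math.exp(w)):
                alt = dict(params)
                alt[p] = max(params[p] * f, floors[p])
                cands.append(alt)
            models = [build_family_model(model_family, c) for c in cands]
            probs = expected_sfs_multi(models, n2, mu, n_sims, _child_seed(rep_rng))
            lls = [_ll_from_probs(counts, unmasked, row) for row in probs]
            best = int(np.argmax(lls))
            if best == 0:
                width[p] = max(w * 0.618, 0.01)
            else:
                params = cands[best]
    return params


def fit_model(
    obs: SpectrumData,
    model_family: str,
    ranges: dict[str, SearchRange] | None = None,
    n_replicates: int = 100,
    n_loops: int = 100,
    n_sims: int = 100_000,
    rng=None,
    mu: float = DEFAULT_MU,
    apply_singleton_mask: bool = True,
    final_seed: int | None = None,
    final_n_sims: int | None = None,
) -> FitResult:
    """Fit one model family; the best of ``n_replicates`` runs is returned.

    Each replicate starts from values drawn from the search ranges and
    refines them over ``n_loops`` coordinate cycles, each likelihood
    evaluation using ``n_sims`` fresh coalescent simulations.  All
    replicates' final likelihoods are computed against one shared
    evaluation stream (``final_seed``), which also allows likelihoods of
    different families to be compared head-to-head when the same seed is
    passed (as :func:`fit_models` does).  Because replicate selection must
    resolve likelihood differences of order one nat on flat ridges, the
    final evaluation defaults to at least 10^5 simulations regardless of
    the per-comparison ``n_sims``.
    """
    rng = _as_rng(rng)
    master_seed = _child_seed(rng)
    master = np.random.default_rng(master_seed)
    obs = _prepare_obs(obs, apply_singleton_mask)
    free, _ = _family(model_family)
    if ranges is None:
        ranges = {r.parameter: r for r in default_search_ranges(model_family)}
    missing = [p for p in free if p not in ranges]
    if missing:
        raise ValueError(f"search ranges missing for parameters: {missing}")
    if final_seed is None:
        final_seed = _child_seed(master)
    if final_n_sims is None:
        final_n_sims = max(n_sims, 100_000)
    rep_seeds = [_child_seed(master) for _ in range(n_replicates)]
    all_params = []
    for rep_seed in rep_seeds:
        rep_rng = np.random.default_rng(rep_seed)
        all_params.append(
            _optimize_replicate(obs, model_family, ranges, n_loops, n_sims, mu, rep_rng)
        )
    # shared-stream final evaluation across replicates
    models = [build_family_model(model_family, p) for p in all_params]
    probs = expected_sfs_multi(models, obs.n_chromosomes, mu, final_n_sims, final_seed)
    lls = [_ll_from_probs(obs.counts, ~obs.mask, row) for row in probs]
    best = int(np.argmax(lls))
    log10_cl = lls[best]
    estimates = all_params[best]
    return FitResult(
        model_name=model_family,
        estimates=estimates,
        log10_cl=log10_cl,
        delta_lhood=max_observed_likelihood(obs) - log10_cl,
        aic=aic(log10_cl, len(free)),
        n_replicates=n_replicates,
        n_loops=n_loops,
        n_sims=n_sims,
        seed=master_seed,
        best_replicate_index=best,
        obs_fingerprint=_fingerprint(obs),
    )


def fit_models(
    obs: SpectrumData,
    families: tuple[str, ...] = ("bottleneck", "null"),
    ranges: dict[str, SearchRange] | None = None,
    n_replicates: int = 100,
    n_loops: int = 100,
    n_sims: int = 100_000,
    rng=None,
    mu: float = DEFAULT_MU,
    apply_singleton_mask: bool = True,
    final_n_sims: int | None = None,
) -> ModelComparison:
    """Fit several families to the same spectrum and rank them by AIC.

    The final likelihood of every family is evaluated against the same
    coalescent draw stream so that the AIC comparison reflects model fit
    rather than independent Monte Carlo noise.
    """
    rng = _as_rng(rng)
    shared_final_seed = _child_seed(rng)
    fits = []
    for fam in families:
        fam_ranges = None
        if ranges is not None:
            free, _ = _family(fam)
            fam_ranges = {p: ranges[p] for p in free if p in ranges}
        fits.append(
            fit_model(
                obs,
                fam,
                ranges=fam_ranges,
                n_replicates=n_replicates,
                n_loops=n_loops,
                n_sims=n_sims,
                rng=rng,
                mu=mu,
                apply_singleton_mask=apply_singleton_mask,
                final_seed=shared_final_seed,
                final_n_sims=final_n_sims,
            )
        )
    return compare_models(fits)
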
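"""Nonparametric bootstrap uncertainty for SFS demographic fits.

The observed spectrum is resampled site-wise with replacement (multinomial
over frequency classes, treating loci as unlinked — the same independence
assumption the composite likelihood makes), the model is refitted on every
resample, and percentile confidence intervals are taken from the resulting
distribution of best-replicate estimates.  For the bottleneck family the
distribution of the recovery ratio Ne_post / Ne_pre is also summarised,
including the fraction of resamples in which the population exceeded its
pre-decline size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from sfsdemog.demography import SearchRange
from sfsdemog.inference import FitResult, fit_model
from sfsdemog.sfs import SpectrumData, bootstrap_resample

__all__ = ["BootstrapSummary", "run_bootstrap", "percentile_ci", "ratio_distribution"]


def percentile_ci(samples, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval from an empirical distribution.

    Quantiles use linear interpolation between order statistics; e.g. the
    95% interval spans the empirical 2.5% and 97.5% quantiles.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least two samples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


@dataclass(frozen=True)
class BootstrapSummary:
    """Per-parameter bootstrap distributions and percentile CIs."""

    model_name: str
    n_boot: int
    estimates: dict[str, np.ndarray]
    ci95: dict[str, tuple[float, float]]
    seed: int
    fits: tuple[FitResult, ...] = ()

    def parameter(self, name: str) -> np.ndarray:
        return self.estimates[name]

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model_name,
                "n_boot": self.n_boot,
                "seed": self.seed,
                "ci95": {k: list(v) for k, v in self.ci95.items()},
                "means": {k: float(np.mean(v)) for k, v in self.estimates.items()},
            },
            indent=2,
        )

    def estimates_table(self) -> list[dict]:
        """One row per bootstrap replicate (for TSV export / plotting)."""
        names = list(self.estimates)
        return [
            {"replicate": b, **{n: float(self.estimates[n][b]) for n in names}}
            for b in range(self.n_boot)
        ]


def run_bootstrap(
    obs: SpectrumData,
    model_family: str = "bottleneck",
    ranges: dict[str, SearchRange] | None = None,
    n_boot: int = 600,
    per_boot_replicates: int = 100,
    n_loops: int = 100,
    n_sims: int = 100_000,
    rng=None,
    apply_singleton_mask: bool = True,
) -> BootstrapSummary:
    """Resample the SFS ``n_boot`` times and refit the model on each.

    Every bootstrap replicate runs a full (scaled-down if desired)
    replicate fit; the best run per resample enters the bootstrap
    distribution.  Deterministic for a fixed master ``rng`` seed.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    master_seed = int(rng.integers(1, 2**31 - 1))
    master = np.random.default_rng(master_seed)
    fits: list[FitResult] = []
    for b in range(n_boot):
        resampled = bootstrap_resample(obs, master)
        try:
            fit = fit_model(
                resampled,
                model_family,
                ranges=ranges,
                n_replicates=per_boot_replicates,
                n_loops=n_loops,
                n_sims=n_sims,
                rng=master,
                apply_singleton_mask=apply_singleton_mask,
            )
        except Exception as exc:  # noqa: BLE001 - annotate replicate and re-raise
            raise RuntimeError(f"bootstrap replicate {b} failed: {exc}") from exc
        fits.append(fit)
    names = list(fits[0].estimates)
    estimates = {n: np.array([f.estimates[n] for f in fits]) for n in names}
    ci95 = {n: percentile_ci(estimates[n]) for n in names}
    return BootstrapSummary(
        model_name=model_family,
        n_boot=n_boot,
        estimates=estimates,
        ci95=ci95,
        seed=master_seed,
        fits=tuple(fits),
    )


@dataclass(frozen=True)
class RatioSummary:
    """Distribution of the recovery ratio Ne_post / Ne_pre."""

    ratios: np.ndarray
    mean: float
    ci95: tuple[float, float]
    fraction_greater_than_one: float


def ratio_distribution(summary: BootstrapSummary) -> RatioSummary:
    """Per-replicate Ne_post / Ne_pre with mean, 95% CI and P(ratio > 1).

    Only defined for the bottleneck family (the null model has no
    pre-decline size).
    """
    if "Ne_pre" not in summary.estimates or "Ne_post" not in summary.estimates:
        raise ValueError("ratio requires a bottleneck-family bootstrap (Ne_pre and Ne_post)")
    ratios = summary.estimates["Ne_post"] / summary.estimates["Ne_pre"]
    return RatioSummary(
        ratios=ratios,
        mean=float(ratios.mean()),
        ci95=percentile_ci(ratios),
        fraction_greater_than_one=float(np.mean(ratios > 1.0)),
    )
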
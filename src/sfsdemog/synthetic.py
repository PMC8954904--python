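"""Synthetic data with the statistical structure the inference assumes.

Two fidelity levels:

- :func:`generate_sfs_dataset` draws a folded SFS directly from the
  expected spectrum of a demographic model (fast path used for fitting
  and bootstrap validation);
- :func:`generate_gl_dataset` emulates reduced-representation sequencing
  at the read level: genealogy-consistent genotypes for a diploid sample,
  Poisson read depths with dropout, symmetric per-read sequencing error,
  and binomial genotype likelihoods — the input the GL → SFS estimator
  consumes.

Defaults mirror a 70-individual pinniped RAD-seq study design: Ne
trajectory (12,506 → 534 → 29,319), mutation rate 2.5e-8, mean depth 10
within a 5–58x acceptance window, 0.5% sequencing error, and missingness
low enough to be consistent with a >=90% per-site presence filter.
Sites are simulated independently (no linkage), matching the composite
likelihood's independence assumption.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from sfsdemog.demography import DEFAULT_MU, DemographicModel, build_bottleneck_model, build_null_model
from sfsdemog.engine import draw_sfs, expected_sfs
from sfsdemog.gl import GLMatrix
from sfsdemog.sfs import SpectrumData

__all__ = ["ScenarioConfig", "generate_sfs_dataset", "generate_gl_dataset"]

#: Site count of the full-scale study design (positions with genotype
#: likelihoods); tests use the default 5e4.
PAPER_SCALE_N_SITES = 31_328_941


@dataclass(frozen=True)
class ScenarioConfig:
    """Generating conditions for one synthetic dataset."""

    ne_pre: float = 12_506.0
    ne_bot: float = 534.0
    ne_post: float = 29_319.0
    model_family: str = "bottleneck"
    n_individuals: int = 70
    n_sites: int = 50_000
    mu: float = DEFAULT_MU
    mean_depth: float = 10.0
    error_rate: float = 0.005
    missing_rate: float = 0.02
    master_seed: int = 1234
    #: coalescent simulations used to evaluate the generating expected SFS
    n_expected_sims: int = 100_000

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        for name in ("ne_pre", "ne_bot", "ne_post", "n_sites", "mu", "mean_depth"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.model_family not in ("bottleneck", "null"):
            raise ValueError(f"unknown model family {self.model_family!r}")

    def model(self) -> DemographicModel:
        if self.model_family == "null":
            return build_null_model(self.ne_post)
        return build_bottleneck_model(self.ne_pre, self.ne_bot, self.ne_post)

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_individuals


def _truth_record(config: ScenarioConfig, kind: str) -> dict:
    return {"kind": kind, **asdict(config)}


def generate_sfs_dataset(config: ScenarioConfig) -> tuple[SpectrumData, dict]:
    """Folded SFS of ``n_sites`` independent sites drawn from the model.

    Deterministic under ``config.master_seed``; the truth record carries
    the full generating configuration.
    """
    rng = np.random.default_rng(config.master_seed)
    exp = expected_sfs(
        config.model(),
        config.n_chromosomes,
        config.mu,
        config.n_expected_sims,
        rng,
        fold=True,
    )
    spectrum = draw_sfs(exp, config.n_sites, rng)
    return spectrum, _truth_record(config, "sfs")


def _genotype_likelihoods(
    genotypes: np.ndarray, depth: np.ndarray, b_minor: np.ndarray, error_rate: float
) -> np.ndarray:
    """Binomial read-support likelihoods for genotypes 0/1/2.

    A read drawn from a chromosome carrying the minor allele reports it
    with probability ``1 - error_rate`` (symmetric error), so the
    per-read minor-allele probability is ``error_rate``, 0.5 and
    ``1 - error_rate`` for genotypes 0, 1 and 2.  Binomial coefficients
    are omitted (common factor per site-individual).
    """
    p_minor = np.array([error_rate, 0.5, 1.0 - error_rate])
    d = depth[..., None].astype(float)
    b = b_minor[..., None].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        # 0 * log(0) -> 0 so that error_rate = 0 yields exact hard-call GLs
        term_minor = np.where(b > 0, b * np.log(p_minor), 0.0)
        term_major = np.where(d - b > 0, (d - b) * np.log1p(-p_minor), 0.0)
    log_gl = term_minor + term_major
    log_gl -= log_gl.max(axis=-1, keepdims=True)
    gl = np.exp(log_gl)
    gl[depth == 0] = 1.0  # no reads, no information
    return gl


def generate_gl_dataset(config: ScenarioConfig) -> tuple[GLMatrix, np.ndarray, dict]:
    """Read-level synthetic dataset: GL matrix, true genotypes, truth record.

    Per site, the minor-allele count is drawn from the model's expected
    folded SFS and alleles are scattered over chromosomes by random
    permutation; consecutive chromosome pairs form diploids, giving
    Hardy–Weinberg genotype proportions.  Depths are Poisson thinned by
    the missing rate; reads carry symmetric per-read error.
    """
    rng = np.random.default_rng(config.master_seed)
    n2 = config.n_chromosomes
    exp = expected_sfs(
        config.model(), n2, config.mu, config.n_expected_sims, rng, fold=True
    )
    probs = exp.probs / exp.probs.sum()
    minor_counts = rng.choice(len(probs), size=config.n_sites, p=probs)

    # scatter minor alleles over chromosomes via random ranks
    ranks = np.argsort(rng.random((config.n_sites, n2)), axis=1)
    chrom = ranks < minor_counts[:, None]
    genotypes = chrom[:, 0::2].astype(np.int8) + chrom[:, 1::2].astype(np.int8)

    depth = rng.poisson(config.mean_depth, size=genotypes.shape)
    if config.missing_rate > 0:
        depth = np.where(
            rng.random(genotypes.shape) < config.missing_rate, 0, depth
        )
    p_minor = np.array([config.error_rate, 0.5, 1.0 - config.error_rate])
    b_minor = rng.binomial(depth, p_minor[genotypes])
    gl = _genotype_likelihoods(genotypes, depth, b_minor, config.error_rate)
    glm = GLMatrix(gl=gl, depth=depth)
    truth = _truth_record(config, "gl")
    truth["true_folded_sfs"] = np.bincount(minor_counts, minlength=len(probs)).tolist()
    return glm, genotypes, truth


def write_truth(truth: dict, path) -> None:
    """Write the truth sidecar as JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
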
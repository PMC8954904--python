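"""Genotype-likelihood → SFS estimation (sample-allele-frequency + EM).

This reimplements the genotype-likelihood stage of SFS estimation as used
for low-coverage short-read data: per-site genotype likelihoods for each
diploid individual are combined, assuming Hardy–Weinberg proportions
within the sample, into per-site *sample allele frequency* (SAF)
likelihoods ``P(site data | X = x)`` for every possible sample minor-allele
count ``x = 0..2n``, and the SFS is then the maximum-likelihood mixture
over ``x`` fitted by EM across sites.

The estimator is agnostic to the GL model that produced the inputs; any
per-genotype likelihoods (on an arbitrary positive per-site-individual
scale) are accepted.  Missing data are flat likelihood vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from sfsdemog.sfs import SpectrumData

__all__ = [
    "GLMatrix",
    "SAFMatrix",
    "EMResult",
    "apply_site_filters",
    "saf_per_site",
    "saf_matrix",
    "em_sfs",
    "fold_saf_estimate",
    "estimate_sfs",
    "read_gl_tsv",
    "write_gl_tsv",
]

_GENOTYPE_MULTIPLICITY = np.array([1.0, 2.0, 1.0])  # C(2, g) for g = 0, 1, 2


@dataclass(frozen=True)
class GLMatrix:
    """Per-site × per-individual genotype likelihoods with read depths.

    ``gl[s, j, g]`` is P(reads of individual ``j`` at site ``s`` | genotype
    carries ``g`` copies of the minor allele), on any positive per-(s, j)
    scale.  ``depth[s, j] = 0`` means no reads; such entries must carry a
    flat (uninformative) likelihood vector.
    """

    gl: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        gl = np.asarray(self.gl, dtype=float)
        depth = np.asarray(self.depth)
        if gl.ndim != 3 or gl.shape[2] != 3:
            raise ValueError("gl must have shape (n_sites, n_individuals, 3)")
        if depth.shape != gl.shape[:2]:
            raise ValueError("depth shape must match gl's first two dimensions")
        if np.any(gl < 0):
            raise ValueError("genotype likelihoods must be non-negative")
        if np.any(gl.max(axis=2) <= 0):
            raise ValueError(
                "every site-individual needs a positive likelihood entry "
                "(use a flat vector for missing data)"
            )
        object.__setattr__(self, "gl", gl)
        object.__setattr__(self, "depth", depth)

    @property
    def n_sites(self) -> int:
        return self.gl.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.gl.shape[1]


@dataclass(frozen=True)
class SAFMatrix:
    """Per-site sample-allele-frequency likelihoods over x = 0..2n."""

    saf: np.ndarray
    n_chromosomes: int

    def __post_init__(self) -> None:
        saf = np.asarray(self.saf, dtype=float)
        if saf.ndim != 2 or saf.shape[1] != self.n_chromosomes + 1:
            raise ValueError("saf must have shape (n_sites, 2n + 1)")
        if np.any(saf < 0) or np.any(saf.max(axis=1) <= 0):
            raise ValueError("each site needs non-negative saf with a positive maximum")
        object.__setattr__(self, "saf", saf)

    @property
    def n_sites(self) -> int:
        return self.saf.shape[0]


def apply_site_filters(
    depth: np.ndarray,
    min_ind: int = 63,
    min_total_depth: int = 315,
    max_total_depth: int = 3600,
    min_ind_depth: int = 5,
) -> np.ndarray:
    """Boolean keep-mask over sites from depth-based quality filters.

    A site passes iff at least ``min_ind`` individuals have depth >=
    ``min_ind_depth`` and the pooled depth lies in ``[min_total_depth,
    max_total_depth]``.  The defaults implement a >=90%-presence rule with
    a 5–58x per-individual coverage window for 70 individuals.
    """
    depth = np.asarray(depth)
    if min_ind > depth.shape[1]:
        raise ValueError(
            f"min_ind={min_ind} exceeds the {depth.shape[1]} individuals present"
        )
    covered = (depth >= min_ind_depth).sum(axis=1)
    total = depth.sum(axis=1)
    return (covered >= min_ind) & (total >= min_total_depth) & (total <= max_total_depth)


def _saf_convolution(gl: np.ndarray) -> np.ndarray:
    """Sequential convolution over individuals, rescaled to avoid underflow.

    Input ``(n_sites, n_ind, 3)``; output ``(n_sites, 2n + 1)`` where
    column ``x`` is proportional to the sum over genotype configurations
    with total minor count ``x`` of the product of genotype likelihoods
    times ``C(2, g)`` multiplicities, i.e. the Hardy–Weinberg
    configuration-weighted likelihood before the hypergeometric
    normalisation.
    """
    n_sites, n_ind, _ = gl.shape
    h = np.ones((n_sites, 1))
    for j in range(n_ind):
        w = gl[:, j, :] * _GENOTYPE_MULTIPLICITY
        cur = h.shape[1]
        new = np.zeros((n_sites, cur + 2))
        new[:, 0:cur] += h * w[:, 0:1]
        new[:, 1 : cur + 1] += h * w[:, 1:2]
        new[:, 2 : cur + 2] += h * w[:, 2:3]
        peak = new.max(axis=1, keepdims=True)
        if np.any(peak <= 0):
            bad = int(np.argmax(peak.ravel() <= 0))
            raise ValueError(f"all-zero sample likelihood at site {bad} after individual {j}")
        h = new / peak
    return h


def _hypergeometric_weights(n_chrom: int) -> np.ndarray:
    x = np.arange(n_chrom + 1)
    log_c = gammaln(n_chrom + 1) - gammaln(x + 1) - gammaln(n_chrom - x + 1)
    return np.exp(-(log_c - log_c.max()))  # 1 / C(2n, x), rescaled


def saf_matrix(glm: GLMatrix, site_mask: np.ndarray | None = None) -> SAFMatrix:
    """SAF likelihood vectors for all (optionally filtered) sites."""
    gl = glm.gl if site_mask is None else glm.gl[site_mask]
    n_chrom = 2 * glm.n_individuals
    h = _saf_convolution(gl)
    saf = h * _hypergeometric_weights(n_chrom)
    saf /= saf.max(axis=1, keepdims=True)
    return SAFMatrix(saf=saf, n_chromosomes=n_chrom)


def saf_per_site(gl_site: np.ndarray) -> np.ndarray:
    """SAF vector P(D | X = x), x = 0..2n, for a single site.

    ``gl_site`` has shape ``(n_individuals, 3)``.  Computed by sequential
    convolution over individuals (never configuration enumeration) and
    returned on a per-site arbitrary positive scale.
    """
    gl_site = np.asarray(gl_site, dtype=float)
    if gl_site.ndim != 2 or gl_site.shape[1] != 3:
        raise ValueError("gl_site must have shape (n_individuals, 3)")
    h = _saf_convolution(gl_site[None, :, :])[0]
    saf = h * _hypergeometric_weights(2 * gl_site.shape[0])
    return saf / saf.max()


@dataclass(frozen=True)
class EMResult:
    """EM-estimated SFS mixture weights with the likelihood trace."""

    eta: np.ndarray
    log_likelihoods: np.ndarray
    n_iter: int
    converged: bool


def em_sfs(saf: SAFMatrix, max_iter: int = 1000, tol: float = 1e-8) -> EMResult:
    """Maximum-likelihood SFS proportions by EM over SAF mixture weights.

    E-step: per-site posterior over x proportional to ``eta_x * saf(x)``;
    M-step: ``eta`` = mean posterior.  The observed-data log-likelihood is
    non-decreasing every iteration; iteration stops when its relative
    change drops below ``tol`` or after ``max_iter`` iterations (hard cap).
    """
    L = saf.saf
    n_sites, n_classes = L.shape
    if n_sites < 1:
        raise ValueError("need at least one site")
    eta = np.full(n_classes, 1.0 / n_classes)
    lls = []
    converged = False
    prev = -np.inf
    for it in range(max_iter):
        denom = L @ eta
        if np.any(denom <= 0) or not np.all(np.isfinite(denom)):
            bad = int(np.argmax(~np.isfinite(denom) | (denom <= 0)))
            raise ValueError(f"non-finite mixture likelihood at site {bad}")
        ll = float(np.log(denom).sum())
        lls.append(ll)
        eta = eta * (L.T @ (1.0 / denom)) / n_sites
        eta = eta / eta.sum()
        if np.isfinite(prev) and ll - prev <= tol * abs(prev):
            converged = True
            break
        prev = ll
    return EMResult(
        eta=eta, log_likelihoods=np.array(lls), n_iter=len(lls), converged=converged
    )


def fold_saf_estimate(eta: np.ndarray, n_sites: float) -> SpectrumData:
    """Fold unfolded EM proportions and scale to fractional site counts."""
    eta = np.asarray(eta, dtype=float)
    n_chrom = len(eta) - 1
    unfolded = SpectrumData(
        counts=eta * n_sites, folded=False, n_chromosomes=n_chrom
    )
    from sfsdemog.sfs import fold as _fold

    return _fold(unfolded)


def estimate_sfs(
    glm: GLMatrix,
    min_ind: int | None = None,
    min_total_depth: int = 315,
    max_total_depth: int = 3600,
    min_ind_depth: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[SpectrumData, dict]:
    """Full pipeline: depth filters → SAF → EM → folded fractional SFS.

    Returns the folded spectrum of the retained sites plus a report dict
    with per-filter site counts and the EM trace summary.  ``min_ind``
    defaults to 90% of the individuals present.
    """
    if min_ind is None:
        min_ind = int(np.ceil(0.9 * glm.n_individuals))
    keep = apply_site_filters(
        glm.depth, min_ind, min_total_depth, max_total_depth, min_ind_depth
    )
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise ValueError("no sites pass the depth filters")
    saf = saf_matrix(glm, site_mask=keep)
    em = em_sfs(saf, max_iter=max_iter, tol=tol)
    spectrum = fold_saf_estimate(em.eta, n_kept)
    report = {
        "n_sites_input": glm.n_sites,
        "n_sites_retained": n_kept,
        "n_sites_removed": glm.n_sites - n_kept,
        "min_ind": min_ind,
        "min_total_depth": min_total_depth,
        "max_total_depth": max_total_depth,
        "min_ind_depth": min_ind_depth,
        "em_iterations": em.n_iter,
        "em_converged": em.converged,
        "em_final_log_likelihood": float(em.log_likelihoods[-1]),
    }
    return spectrum, report


# ---------------------------------------------------------------------------
# GLMatrix TSV dialect: two header lines then one row per site-individual
#   # n_sites=<S> n_individuals=<N>
#   site_id individual_id depth gl0 gl1 gl2
# ---------------------------------------------------------------------------


def write_gl_tsv(glm: GLMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_sites={glm.n_sites} n_individuals={glm.n_individuals}\n")
        fh.write("site_id\tindividual_id\tdepth\tgl0\tgl1\tgl2\n")
        for s in range(glm.n_sites):
            for j in range(glm.n_individuals):
                g = glm.gl[s, j]
                fh.write(
                    f"{s}\t{j}\t{int(glm.depth[s, j])}\t{float(g[0])!r}\t{float(g[1])!r}\t{float(g[2])!r}\n"
                )


def read_gl_tsv(path) -> GLMatrix:
    """Read the TSV dialect; validates that every (site, individual) is present."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: line 1: missing '# n_sites=... n_individuals=...'")
        meta = dict(item.split("=") for item in header[1:].split())
        n_sites, n_ind = int(meta["n_sites"]), int(meta["n_individuals"])
        fh.readline()  # column names
        gl = np.zeros((n_sites, n_ind, 3))
        depth = np.zeros((n_sites, n_ind), dtype=np.int64)
        seen = np.zeros((n_sites, n_ind), dtype=bool)
        for lineno, line in enumerate(fh, start=3):
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 columns")
            s, j = int(parts[0]), int(parts[1])
            depth[s, j] = int(parts[2])
            gl[s, j] = [float(parts[3]), float(parts[4]), float(parts[5])]
            seen[s, j] = True
    if not seen.all():
        s, j = np.argwhere(~seen)[0]
        raise ValueError(f"{path}: missing row for site {s}, individual {j}")
    return GLMatrix(gl=gl, depth=depth)
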
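"""SFS containers, folding, masking, bootstrap resampling and file I/O.

The container keeps the monomorphic class (index 0).  Because the analysis
fixes the mutation rate, the proportion of monomorphic sites is informative
about absolute Ne and takes part in the composite likelihood; dropping it
would leave absolute sizes unidentifiable from a folded spectrum alone.

Counts are stored as floats: EM-estimated spectra are fractional by
nature.  Folded class index = minor-allele count (0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpectrumData",
    "fold",
    "mask_singletons",
    "bootstrap_resample",
    "read_obs",
    "write_obs",
    "read_tsv",
    "write_tsv",
]


@dataclass(frozen=True)
class SpectrumData:
    """A (possibly folded) site frequency spectrum with a class mask.

    Parameters
    ----------
    counts
        Per-class site counts, length ``n + 1`` folded or ``2n + 1``
        unfolded for ``2n = n_chromosomes``.  Fractional values allowed.
    folded
        Whether classes are indexed by minor-allele count.
    n_chromosomes
        Number of sampled chromosomes (2n).
    mask
        True = class excluded from likelihood computations.  Masked counts
        are kept in the container; conservation properties always refer to
        all classes.
    """

    counts: np.ndarray
    folded: bool
    n_chromosomes: int
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if self.n_chromosomes < 2 or self.n_chromosomes % 2:
            raise ValueError("n_chromosomes must be an even number >= 2")
        expected = self.n_chromosomes // 2 + 1 if self.folded else self.n_chromosomes + 1
        if len(counts) != expected:
            raise ValueError(
                f"counts length {len(counts)} does not match "
                f"{'folded' if self.folded else 'unfolded'} 2n={self.n_chromosomes}"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        mask = self.mask
        if mask is None:
            mask = np.zeros(len(counts), dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if len(mask) != len(counts):
                raise ValueError("mask length must match counts length")
        object.__setattr__(self, "mask", mask)

    @property
    def total_sites(self) -> float:
        return float(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return len(self.counts)


def fold(spectrum: SpectrumData) -> SpectrumData:
    """Fold an unfolded spectrum onto minor-allele-count classes.

    ``folded[i] = unfolded[i] + unfolded[2n-i]`` for ``0 < i < n``;
    ``folded[n] = unfolded[n]``; the fixed-derived class joins the
    monomorphic class.  Total site count is conserved.
    """
    if spectrum.folded:
        raise ValueError("spectrum is already folded")
    n2 = spectrum.n_chromosomes
    n = n2 // 2
    u = spectrum.counts
    c = np.empty(n + 1)
    c[0] = u[0] + u[n2]
    for i in range(1, n):
        c[i] = u[i] + u[n2 - i]
    c[n] = u[n]
    m = spectrum.mask
    fm = np.empty(n + 1, dtype=bool)
    fm[0] = m[0] | m[n2]
    for i in range(1, n):
        fm[i] = m[i] | m[n2 - i]
    fm[n] = m[n]
    return SpectrumData(counts=c, folded=True, n_chromosomes=n2, mask=fm)


def mask_singletons(spectrum: SpectrumData) -> SpectrumData:
    """Exclude the singleton class (minor-allele count 1) from likelihoods.

    Singletons are disproportionately affected by sequencing error at low
    coverage, so fits mask them by default.  Counts are left untouched;
    idempotent.
    """
    if not spectrum.folded:
        raise ValueError("mask_singletons expects a folded spectrum")
    mask = spectrum.mask.copy()
    mask[1] = True
    return replace(spectrum, mask=mask)


def bootstrap_resample(spectrum: SpectrumData, rng) -> SpectrumData:
    """Multinomial resample of the sites underlying the spectrum.

    Sites are drawn with replacement with class probabilities
    ``counts / total_sites``; the total, mask and foldedness are preserved.
    This matches site-level SFS bootstrapping of unlinked loci.
    """
    total = spectrum.total_sites
    if total <= 0:
        raise ValueError("cannot bootstrap an empty spectrum")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    p = spectrum.counts / total
    counts = rng.multinomial(int(round(total)), p).astype(float)
    return replace(spectrum, counts=counts)


# ---------------------------------------------------------------------------
# File I/O
#
# .obs dialect (fastsimcoal-style minor-allele-frequency spectrum):
#   line 1: "1 observations"
#   line 2: whitespace-separated class labels d0_0 .. d0_n
#   line 3: whitespace-separated counts (real-valued accepted)
# The dialect does not record the mask; use the TSV format for lossless
# round trips including masks.
# ---------------------------------------------------------------------------


def write_obs(spectrum: SpectrumData, path) -> None:
    """Write a spectrum in the minimal .obs dialect."""
    labels = " ".join(f"d0_{i}" for i in range(spectrum.n_classes))
    values = " ".join(repr(float(c)) for c in spectrum.counts)
    with open(path, "w") as fh:
        fh.write("1 observations\n")
        fh.write(labels + "\n")
        fh.write(values + "\n")


def read_obs(path, folded: bool = True) -> SpectrumData:
    """Read a .obs file; ``folded`` declares how to interpret the classes.

    A folded file with ``n + 1`` columns describes ``2n`` chromosomes; an
    unfolded file with ``2n + 1`` columns describes ``2n``.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or "observation" not in lines[0]:
        raise ValueError(f"{path}: line 1: expected '1 observations' header")
    if len(lines) < 3:
        raise ValueError(f"{path}: expected 3 lines (header, labels, counts)")
    labels = lines[1].split()
    values = lines[2].split()
    if len(values) != len(labels):
        raise ValueError(
            f"{path}: line 3: {len(values)} counts but {len(labels)} labels"
        )
    for j, lab in enumerate(labels):
        if lab != f"d0_{j}":
            raise ValueError(f"{path}: line 2: unexpected label {lab!r} at column {j}")
    try:
        counts = np.array([float(v) for v in values])
    except ValueError as exc:
        raise ValueError(f"{path}: line 3: non-numeric count ({exc})") from None
    if np.any(counts < 0):
        raise ValueError(f"{path}: line 3: negative count")
    n_classes = len(counts)
    n_chrom = 2 * (n_classes - 1) if folded else n_classes - 1
    return SpectrumData(counts=counts, folded=folded, n_chromosomes=n_chrom)


def write_tsv(spectrum: SpectrumData, path) -> None:
    """Self-describing TSV: columns (class, count, masked) plus a header."""
    with open(path, "w") as fh:
        fh.write(f"# folded={spectrum.folded} n_chromosomes={spectrum.n_chromosomes}\n")
        fh.write("class\tcount\tmasked\n")
        for i, (c, m) in enumerate(zip(spectrum.counts, spectrum.mask)):
            fh.write(f"{i}\t{float(c)!r}\t{int(m)}\n")


def read_tsv(path) -> SpectrumData:
    """Read the TSV format written by :func:`write_tsv` (lossless)."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: line 1: missing metadata header")
        meta = dict(item.split("=") for item in header[1:].split())
        folded = meta["folded"] == "True"
        n_chrom = int(meta["n_chromosomes"])
        fh.readline()  # column names
        counts, mask = [], []
        for line in fh:
            _, c, m = line.split("\t")
            counts.append(float(c))
            mask.append(bool(int(m)))
    return SpectrumData(
        counts=np.array(counts), folded=folded, n_chromosomes=n_chrom, mask=np.array(mask)
    )
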
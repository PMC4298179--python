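"""Infer paternal haplotypes from F1-cross sequencing against a reference strain.

A male of unknown genotype is crossed to a homozygous reference-strain female;
sequencing one F1 daughter yields, at every site, a mixture of the known
maternal (reference) allele and the unknown paternal allele.  At a site where
the paternal allele differs from the reference, the F1 is heterozygous and the
alternate allele should appear in about half the reads.  The caller therefore
accepts an alternate paternal allele when its count lies inside the central
binomial acceptance region for p = 0.5 (default level 90%), subject to
coverage filters: depth above a floor (default > 9) and below the library's
upper coverage quantile (default 98th percentile, a guard against duplicated
regions), and the site being monomorphic in a resequenced pool of the
reference strain (residual heterozygosity guard).

Counts above the acceptance region are called missing rather than alternate:
an F1 from a homozygous reference mother cannot be homozygous non-reference,
so an excess of alternate reads signals a problem, not a genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import NUCLEOTIDES, HaplotypeMatrix, PoolCounts

__all__ = [
    "CallingConfig",
    "binomial_acceptance_region",
    "call_paternal_allele",
    "call_haplotypes",
    "empirical_fdr",
]

_ACGT = np.array(NUCLEOTIDES)  # A C G T column order for count arrays


@dataclass(frozen=True)
class CallingConfig:
    """Filters and thresholds for paternal-allele calling."""

    ci_level: float = 0.90
    expectation: float = 0.5
    min_coverage: int = 10          # i.e. coverage > 9
    max_coverage_quantile: float = 0.98

    def __post_init__(self):
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


@lru_cache(maxsize=4096)
def binomial_acceptance_region(n: int, level: float = 0.90) -> tuple[int, int]:
    """Central acceptance region of Binomial(n, 1/2) at the given level.

    ``lo`` is the smallest count k with CDF(k) >= (1-level)/2 and
    ``hi = n - lo``; both bounds are inclusive.  Exact (no normal
    approximation), which matters at the ~10x depths being filtered for.
    """
    if n < 1:
        raise ValueError("coverage must be >= 1")
    alpha = (1 - level) / 2
    lo = int(stats.binom.ppf(alpha, n, 0.5))
    # ppf returns smallest k with CDF(k) >= alpha
    return lo, n - lo


def call_paternal_allele(ref_count: int, alt_count: int,
                         config: CallingConfig = CallingConfig(),
                         library_max_coverage: int | None = None) -> str:
    """Call one site: ``"ref"``, ``"alt"`` or ``"N"``.

    Coverage outside ``[min_coverage, library_max_coverage)`` gives ``N``;
    an alternate count above the acceptance region also gives ``N`` (it is
    inconsistent with a heterozygous F1)."""
    n = ref_count + alt_count
    if n < config.min_coverage:
        return "N"
    if library_max_coverage is not None and n > library_max_coverage:
        return "N"
    lo, hi = binomial_acceptance_region(n, config.ci_level)
    if alt_count > hi:
        return "N"
    if alt_count >= lo and alt_count > 0:
        return "alt"
    return "ref"


def _reference_consensus(ref_pool_counts: np.ndarray,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Consensus allele of the reference pool and a monomorphism mask."""
    counts = np.asarray(ref_pool_counts)
    consensus_idx = counts.argmax(axis=1)
    consensus = _ACGT[consensus_idx]
    total = counts.sum(axis=1)
    monomorphic = (counts.max(axis=1) == total) & (total > 0)
    return consensus, monomorphic


def _call_individual(counts: np.ndarray, maternal: np.ndarray,
                     usable: np.ndarray, config: CallingConfig) -> np.ndarray:
    """Call all sites of one F1 library.

    ``counts``: n_sites x 4 (A,C,G,T) read counts.  ``maternal``: reference
    consensus allele per site.  ``usable``: sites monomorphic in the
    reference pool.  Returns per-site calls as nucleotides or ``N``.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n_sites = counts.shape[0]
    cov = counts.sum(axis=1)
    covered = cov[cov > 0]
    cap = np.quantile(covered, config.max_coverage_quantile) if covered.size \
        else np.inf
    calls = np.full(n_sites, "N", dtype="<U1")
    mat_col = np.searchsorted(_ACGT, maternal)  # ACGT sorted == alphabetical
    mat_count = counts[np.arange(n_sites), mat_col]
    non_mat = counts.copy()
    non_mat[np.arange(n_sites), mat_col] = -1
    alt_col = non_mat.argmax(axis=1)
    alt_count = counts[np.arange(n_sites), alt_col]
    n_alleles = (counts > 0).sum(axis=1)
    # sites strictly above the library's upper coverage quantile are excluded
    eligible = (usable & (cov >= config.min_coverage) & (cov <= cap)
                & (n_alleles <= 2))
    for i in np.flatnonzero(eligible):
        c = call_paternal_allele(int(mat_count[i]), int(alt_count[i]), config)
        if c == "ref":
            calls[i] = maternal[i]
        elif c == "alt":
            calls[i] = _ACGT[alt_col[i]]
    return calls


def call_haplotypes(f1_counts: Sequence[np.ndarray],
                    ref_pool_counts: np.ndarray | PoolCounts,
                    sites: pd.DataFrame,
                    ids: Sequence[str] | None = None,
                    config: CallingConfig = CallingConfig(),
                    snp_only: bool = True) -> HaplotypeMatrix:
    """Call one haplotype per F1 individual; keep SNP sites.

    Parameters
    ----------
    f1_counts
        One ``n_sites x 4`` (A,C,G,T) count array per F1 individual.
    ref_pool_counts
        Counts of the resequenced reference-strain pool over the same sites
        (array or single-sample :class:`PoolCounts`); sites segregating in
        the pool are masked for all individuals.
    sites
        Site table (chrom, pos, ref) shared by all count arrays.
    snp_only
        If True (default) the returned matrix is restricted to sites
        polymorphic among the called haplotypes.
    """
    if isinstance(ref_pool_counts, PoolCounts):
        ref_arr = np.stack([ref_pool_counts.allele_counts(a)[:, 0]
                            for a in "ACGT"], axis=1)
    else:
        ref_arr = np.asarray(ref_pool_counts)
    maternal, monomorphic = _reference_consensus(ref_arr)
    rows = [
        _call_individual(c, maternal, monomorphic, config) for c in f1_counts
    ]
    calls = np.stack(rows, axis=0)
    if ids is None:
        ids = [f"h{i + 1}" for i in range(len(f1_counts))]
    matrix = HaplotypeMatrix(ids, calls, sites)
    if not snp_only:
        return matrix
    poly = np.zeros(matrix.n_sites, dtype=bool)
    for j in range(matrix.n_sites):
        col = matrix.calls[:, j]
        alleles = np.unique(col[col != "N"])
        poly[j] = alleles.size >= 2
    return matrix.subset(site_mask=poly)


def _downsample_counts(counts: np.ndarray, target_depth: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Downsample each site's reads to the target depth without replacement."""
    out = counts.copy()
    cov = counts.sum(axis=1)
    for i in np.flatnonzero(cov > target_depth):
        out[i] = rng.multivariate_hypergeometric(counts[i], target_depth)
    return out


def empirical_fdr(libraries: Sequence[np.ndarray],
                  ref_pool_counts: np.ndarray | PoolCounts,
                  sites: pd.DataFrame,
                  target_depth: int = 10,
                  min_mean_coverage: float = 60.0,
                  config: CallingConfig = CallingConfig(),
                  rng: np.random.Generator | None = None,
                  ) -> tuple[float, float]:
    """Empirical false-positive / false-negative rates by downsampling.

    High-coverage libraries (mean depth above ``min_mean_coverage``) are
    downsampled to ``target_depth`` and re-called; full-depth calls are
    treated as truth.  Over sites where both call sets are non-missing:
    FP = downsampled alternate calls that are reference at full depth,
    FN = full-depth alternate calls missed (called reference) after
    downsampling; both divided by the number of compared sites.
    """
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(ref_pool_counts, PoolCounts):
        ref_arr = np.stack([ref_pool_counts.allele_counts(a)[:, 0]
                            for a in "ACGT"], axis=1)
    else:
        ref_arr = np.asarray(ref_pool_counts)
    maternal, monomorphic = _reference_consensus(ref_arr)
    qualifying = [lib for lib in libraries
                  if lib.sum(axis=1).mean() > min_mean_coverage]
    if not qualifying:
        raise ValueError(
            f"no library with mean coverage > {min_mean_coverage}")
    fp = fn = compared = 0
    for lib in qualifying:
        full = _call_individual(lib, maternal, monomorphic, config)
        down_counts = _downsample_counts(np.asarray(lib, dtype=np.int64),
                                         target_depth, rng)
        down = _call_individual(down_counts, maternal, monomorphic, config)
        both = (full != "N") & (down != "N")
        compared += int(both.sum())
        full_alt = both & (full != maternal)
        down_alt = both & (down != maternal)
        fp += int((down_alt & ~full_alt).sum())
        fn += int((full_alt & (down == maternal)).sum())
    if compared == 0:
        return 0.0, 0.0
    return fp / compared, fn / compared
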
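"""Cochran-Mantel-Haenszel scan of Pool-Seq time series.

For every biallelic SNP, allele counts at the base generation and a later
generation form one 2x2 table per replicate; replicates are the strata of a
CMH test (chi-squared, 1 df):

    T = (sum_k (a_k - E[a_k]))^2 / sum_k Var[a_k]

with hypergeometric expectation and variance under fixed margins.  No
continuity correction is applied by default (at K = 1 the statistic then
reduces exactly to the fixed-margins randomization chi-square,
(n-1)/n times the Pearson chi-square).

SNPs are ranked by ascending p-value; the per-timepoint detection threshold
for the haplotype-block scan is the minimum, over the ``top_n`` (default
2,000) ranked SNPs, of the mean across replicates of the rising-allele
frequency change.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import PoolCounts

__all__ = [
    "cmh_test",
    "cmh_test_batch",
    "rank_candidates",
    "derive_thresholds",
]


def cmh_test(tables: np.ndarray,
             continuity_correction: bool = False) -> tuple[float, float]:
    """CMH statistic and p-value for K stratified 2x2 tables.

    ``tables`` has shape (K, 2, 2): rows = allele, columns = timepoint.
    Strata with a zero row or column margin are skipped; if every stratum is
    degenerate the result is (nan, nan).
    """
    t = np.asarray(tables, dtype=float)
    if t.ndim == 2:
        t = t[None]
    a = t[:, 0, 0]
    r1 = t[:, 0, :].sum(axis=1)
    r2 = t[:, 1, :].sum(axis=1)
    c1 = t[:, :, 0].sum(axis=1)
    c2 = t[:, :, 1].sum(axis=1)
    n = r1 + r2
    valid = (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0) & (n > 1)
    if not valid.any():
        return float("nan"), float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        e = r1 * c1 / n
        v = r1 * r2 * c1 * c2 / (n * n * (n - 1))
    num = np.abs((a[valid] - e[valid]).sum())
    if continuity_correction:
        num = max(num - 0.5, 0.0)
    stat = num ** 2 / v[valid].sum()
    return float(stat), float(stats.chi2.sf(stat, df=1))


def cmh_test_batch(a: np.ndarray, b: np.ndarray,
                   c: np.ndarray, d: np.ndarray,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised CMH over many SNPs.

    ``a``/``b`` are counts of allele 1/2 at the base timepoint, ``c``/``d``
    at the target timepoint; each has shape (n_snps, K).  Degenerate strata
    are dropped per SNP; SNPs with no valid stratum get NaN.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    r1 = a + c   # allele-1 margin (rows = allele, columns = timepoint)
    r2 = b + d
    c1 = a + b   # base-timepoint margin
    c2 = c + d
    n = r1 + r2
    valid = (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0) & (n > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = r1 * c1 / n
        v = r1 * r2 * c1 * c2 / (n * n * (n - 1))
    diff = np.where(valid, a - e, 0.0)
    var = np.where(valid, v, 0.0).sum(axis=1)
    any_valid = valid.any(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = diff.sum(axis=1) ** 2 / var
    stat = np.where(any_valid & (var > 0), stat, np.nan)
    p = np.where(np.isnan(stat), np.nan, stats.chi2.sf(stat, df=1))
    return stat, p


def _top2_alleles(counts_sum: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices (into A,T,C,G) of the two most common alleles per site."""
    order = np.argsort(-counts_sum, axis=1, kind="stable")
    return order[:, 0], order[:, 1]


def rank_candidates(pool: PoolCounts, base_timepoint: str = "F0",
                    target_timepoint: str = "F15",
                    polarization: str = "rising") -> pd.DataFrame:
    """CMH test and rank for every biallelic SNP between two timepoints.

    Per replicate, allele counts are summed over the samples of that
    replicate at each timepoint (normally one sample each); a replicate
    missing either timepoint contributes no stratum.  ``mean_rise`` is the
    mean across replicates of the frequency change of the rising allele
    (``polarization="rising"``) or of the absolute frequency change
    (``polarization="absolute"``).

    Returns a DataFrame sorted by rank with columns chrom, pos, statistic,
    p_value, rank, mean_rise, rising_allele.
    """
    if polarization not in ("rising", "absolute"):
        raise ValueError("polarization must be 'rising' or 'absolute'")
    reps = list(pd.unique(pool.design["replicate"]))
    acgt = np.stack([pool.allele_counts(x) for x in ("A", "T", "C", "G")],
                    axis=2)  # sites x samples x 4 (sync ATCG order)
    base_cols = {r: pool.samples_for(base_timepoint, r) for r in reps}
    targ_cols = {r: pool.samples_for(target_timepoint, r) for r in reps}
    reps = [r for r in reps if base_cols[r].size and targ_cols[r].size]
    if not reps:
        raise ValueError("no replicate has both timepoints")
    total = acgt.sum(axis=1)  # sites x 4, pooled over all samples
    a1, a2 = _top2_alleles(total)
    n_sites = pool.n_sites
    rows = np.arange(n_sites)
    K = len(reps)
    A = np.zeros((n_sites, K))
    B = np.zeros((n_sites, K))
    C = np.zeros((n_sites, K))
    D = np.zeros((n_sites, K))
    for k, r in enumerate(reps):
        bc = acgt[:, base_cols[r], :].sum(axis=1)
        tc = acgt[:, targ_cols[r], :].sum(axis=1)
        A[:, k] = bc[rows, a1]
        B[:, k] = bc[rows, a2]
        C[:, k] = tc[rows, a1]
        D[:, k] = tc[rows, a2]
    biallelic = (total[rows, a2] > 0) & \
        ((total.sum(axis=1) - total[rows, a1] - total[rows, a2]) == 0)
    stat, p = cmh_test_batch(A, B, C, D)
    stat = np.where(biallelic, stat, np.nan)
    p = np.where(biallelic, p, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_base = A / (A + B)
        f_targ = C / (C + D)
    change = f_targ - f_base  # change of allele 1, per replicate
    valid = ~(np.isnan(f_base) | np.isnan(f_targ))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_change = np.where(valid, change, 0.0).sum(axis=1) \
            / np.maximum(valid.sum(axis=1), 1)
    sync_letters = np.array(("A", "T", "C", "G"))
    if polarization == "rising":
        rising_first = mean_change >= 0
        mean_rise = np.abs(mean_change)
        rising_allele = np.where(rising_first, sync_letters[a1],
                                 sync_letters[a2])
    else:
        mean_rise = np.where(valid, np.abs(change), 0.0).sum(axis=1) \
            / np.maximum(valid.sum(axis=1), 1)
        rising_allele = np.where(mean_change >= 0, sync_letters[a1],
                                 sync_letters[a2])
    df = pd.DataFrame({
        "chrom": pool.sites["chrom"],
        "pos": pool.sites["pos"],
        "statistic": stat,
        "p_value": p,
        "mean_rise": mean_rise,
        "rising_allele": rising_allele,
    })
    df = df[~df["p_value"].isna()].copy()
    df = df.sort_values(["p_value", "statistic", "chrom", "pos"],
                        ascending=[True, False, True, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def derive_thresholds(pool: PoolCounts,
                      target_timepoints: Sequence[str] = ("F15", "F37", "F59"),
                      base_timepoint: str = "F0",
                      top_n: int = 2000,
                      polarization: str = "rising",
                      ) -> dict[str, float]:
    """Per-timepoint block-detection thresholds from the CMH top candidates.

    threshold_t = min over the ``top_n`` highest-ranked SNPs of the mean
    across replicates of the rising-allele frequency change base -> t.  If
    fewer SNPs were tested, all of them are used (with a warning).
    """
    import warnings

    thresholds: dict[str, float] = {}
    for tp in target_timepoints:
        res = rank_candidates(pool, base_timepoint, tp, polarization)
        if len(res) < top_n:
            warnings.warn(
                f"only {len(res)} tested SNPs for {tp}; using all of them")
        top = res.head(top_n)
        thresholds[tp] = float(top["mean_rise"].min())
    return thresholds
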
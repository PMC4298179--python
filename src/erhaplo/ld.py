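"""Linkage disequilibrium from phased haplotype matrices.

r² between two biallelic sites is D²/(p_A(1-p_A) p_B(1-p_B)) computed on the
haplotypes called at *both* sites; a pair is eligible only if at least
``min_haplotypes`` (default 24) haplotypes are jointly called and both sites
remain polymorphic after the missing-data intersection.  Ineligible or
monomorphic pairs are excluded, never scored 0.

The module summarises LD three ways: decay profiles (mean r² in distance
bins), background LD (random cross-chromosome pairs — the floor set by sample
size, E[r²] ≈ 1/n for unlinked loci), and change in LD between a base and an
evolved population, optionally stratified by initial-LD bin or by genomic
region category (inversion / low recombination / high recombination).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import HaplotypeMatrix

__all__ = [
    "LdPair",
    "r_squared",
    "pair_r2",
    "ld_decay_profile",
    "background_ld",
    "ld_change_by_initial",
    "stratified_ld_change",
]

DEFAULT_MIN_HAPLOTYPES = 24


@dataclass(frozen=True)
class LdPair:
    r2: float
    n_haplotypes: int
    p_a: float
    p_b: float
    D: float


def r_squared(calls_a: np.ndarray, calls_b: np.ndarray,
              min_haplotypes: int = DEFAULT_MIN_HAPLOTYPES) -> LdPair | None:
    """r² between two sites given per-haplotype calls (N = missing).

    Returns ``None`` when fewer than ``min_haplotypes`` haplotypes are called
    at both sites, either site is not biallelic among them, or a site is
    monomorphic after intersection.
    """
    a = np.asarray(calls_a, dtype="<U1")
    b = np.asarray(calls_b, dtype="<U1")
    mask = (a != "N") & (b != "N")
    n = int(mask.sum())
    if n < min_haplotypes:
        return None
    av, bv = a[mask], b[mask]
    ua, ub = np.unique(av), np.unique(bv)
    if ua.size != 2 or ub.size != 2:
        return None
    x = (av == ua[0]).astype(float)
    y = (bv == ub[0]).astype(float)
    p_a, p_b = x.mean(), y.mean()
    D = (x * y).mean() - p_a * p_b
    r2 = D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LdPair(float(r2), n, float(p_a), float(p_b), float(D))


def pair_r2(codes: np.ndarray, ia: np.ndarray, ja: np.ndarray,
            min_haplotypes: int = DEFAULT_MIN_HAPLOTYPES,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised r² for many site pairs.

    ``codes`` is the int8 haplotypes x sites indicator matrix from
    :meth:`HaplotypeMatrix.indicator_matrix` (0/1 alleles, -1 missing);
    ``ia``/``ja`` are site-index arrays of equal length.  Returns
    ``(r2, eligible)``; ``r2`` is NaN where ineligible.
    """
    A = codes[:, ia].T.astype(np.int16)   # pairs x haplotypes
    B = codes[:, ja].T.astype(np.int16)
    M = (A >= 0) & (B >= 0)
    n = M.sum(axis=1)
    Am = np.where(M, A, 0).astype(float)
    Bm = np.where(M, B, 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = Am.sum(axis=1) / n
        pb = Bm.sum(axis=1) / n
        pab = (Am * Bm).sum(axis=1) / n
        D = pab - pa * pb
        denom = pa * (1 - pa) * pb * (1 - pb)
        r2 = D * D / denom
    eligible = (n >= min_haplotypes) & (denom > 0)
    r2 = np.where(eligible, r2, np.nan)
    return r2, eligible


def _prepare(matrix: HaplotypeMatrix):
    codes, biallelic = matrix.indicator_matrix()
    sites = matrix.sites
    return codes, biallelic, sites


def _sample_pairs_in_bin(pos: np.ndarray, lo: int, hi: int,
                         max_pairs: int | None,
                         rng: np.random.Generator | None,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Site-index pairs (i < j) with distance in [lo, hi].

    Exhaustive when the bin is small or no cap given; otherwise a seeded
    random sample of anchor/partner pairs (with replacement).
    """
    n = pos.size
    left = np.searchsorted(pos, pos + lo, side="left")
    left = np.maximum(left, np.arange(n) + 1)  # j > i: never pair a site with itself
    right = np.searchsorted(pos, pos + hi, side="right")
    per_anchor = np.maximum(right - left, 0)
    total = int(per_anchor.sum())
    if total == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    if max_pairs is None or total <= max_pairs:
        ii = np.repeat(np.arange(n), per_anchor)
        jj = np.concatenate([np.arange(left[i], right[i])
                             for i in np.flatnonzero(per_anchor)])
        return ii, jj
    if rng is None:
        rng = np.random.default_rng()
    anchors = np.flatnonzero(per_anchor)
    weights = per_anchor[anchors] / total
    ii = rng.choice(anchors, size=max_pairs, p=weights)
    offs = rng.integers(0, per_anchor[ii])
    jj = left[ii] + offs
    return ii, jj


def ld_decay_profile(matrix: HaplotypeMatrix,
                     distance_bins: Sequence[tuple[int, int]],
                     min_haplotypes: int = DEFAULT_MIN_HAPLOTYPES,
                     max_pairs_per_bin: int | None = 20_000,
                     rng: np.random.Generator | None = None,
                     site_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Mean r² per distance bin per chromosome.

    ``distance_bins`` are inclusive (lo, hi) bp ranges, e.g. 1-kb windows at
    anchor distances 2 kb ... 15 Mb.  Bins with no eligible pair are reported
    with NaN mean (missing, never zero).  Long-range bins are sampled up to
    ``max_pairs_per_bin`` pairs (seeded via ``rng``); pass ``None`` for
    exhaustive enumeration.
    """
    codes, biallelic, sites = _prepare(matrix)
    keep = biallelic.copy()
    if site_mask is not None:
        keep &= np.asarray(site_mask)
    rows = []
    for chrom in sites["chrom"].unique():
        on_chrom = np.flatnonzero((sites["chrom"] == chrom).to_numpy() & keep)
        pos = sites["pos"].to_numpy()[on_chrom]
        for lo, hi in distance_bins:
            ii, jj = _sample_pairs_in_bin(pos, lo, hi, max_pairs_per_bin, rng)
            if ii.size == 0:
                rows.append({"chrom": chrom, "bin_lo": lo, "bin_hi": hi,
                             "mean_r2": np.nan, "n_pairs": 0})
                continue
            r2, elig = pair_r2(codes, on_chrom[ii], on_chrom[jj],
                               min_haplotypes)
            n_ok = int(elig.sum())
            mean = float(np.nanmean(r2)) if n_ok else np.nan
            rows.append({"chrom": chrom, "bin_lo": lo, "bin_hi": hi,
                         "mean_r2": mean, "n_pairs": n_ok})
    return pd.DataFrame(rows)


def background_ld(matrix: HaplotypeMatrix, n_per_chrom: int = 2000,
                  max_pairs: int = 100_000,
                  min_haplotypes: int = DEFAULT_MIN_HAPLOTYPES,
                  rng: np.random.Generator | None = None) -> float:
    """Mean r² of random cross-chromosome SNP pairs (background LD).

    ``n_per_chrom`` SNPs are drawn per chromosome (all of them, with a
    warning, if fewer exist); mean r² is taken over up to ``max_pairs``
    random pairs of sampled SNPs on different chromosomes.
    """
    if rng is None:
        rng = np.random.default_rng()
    codes, biallelic, sites = _prepare(matrix)
    chroms = sites["chrom"].unique()
    if chroms.size < 2:
        raise ValueError("background LD needs at least 2 chromosomes")
    sampled: list[np.ndarray] = []
    chrom_of: list[np.ndarray] = []
    for k, chrom in enumerate(chroms):
        on_chrom = np.flatnonzero((sites["chrom"] == chrom).to_numpy()
                                  & biallelic)
        if on_chrom.size < n_per_chrom:
            warnings.warn(
                f"only {on_chrom.size} eligible SNPs on {chrom}; using all")
            pick = on_chrom
        else:
            pick = rng.choice(on_chrom, size=n_per_chrom, replace=False)
        sampled.append(pick)
        chrom_of.append(np.full(pick.size, k))
    all_sites = np.concatenate(sampled)
    all_chrom = np.concatenate(chrom_of)
    m = all_sites.size
    ii = rng.integers(0, m, size=max_pairs)
    jj = rng.integers(0, m, size=max_pairs)
    bad = all_chrom[ii] == all_chrom[jj]
    while bad.any():
        jj[bad] = rng.integers(0, m, size=int(bad.sum()))
        bad = all_chrom[ii] == all_chrom[jj]
    r2, elig = pair_r2(codes, all_sites[ii], all_sites[jj], min_haplotypes)
    if not elig.any():
        return float("nan")
    return float(np.nanmean(r2))


def _polymorphic_mask(matrix: HaplotypeMatrix) -> np.ndarray:
    _, biallelic = matrix.indicator_matrix()
    return biallelic


def _match_sites(base: HaplotypeMatrix, evolved: HaplotypeMatrix,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Indices of sites shared by both matrices, in matched order."""
    bi = base.site_index()
    ei = evolved.site_index()
    common = bi.intersection(ei)
    return (bi.get_indexer(common), ei.get_indexer(common))


def ld_change_by_initial(base: HaplotypeMatrix, evolved: HaplotypeMatrix,
                         distance_classes: Sequence[tuple[int, int]],
                         initial_bins: Sequence[float] = (
                             0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0001),
                         min_haplotypes: int = DEFAULT_MIN_HAPLOTYPES,
                         max_pairs_per_class: int | None = 20_000,
                         rng: np.random.Generator | None = None,
                         ) -> pd.DataFrame:
    """Δr² distributions by distance class and initial-r² bin.

    Only matched pairs eligible (polymorphic, enough haplotypes) in *both*
    populations enter; pairs that became monomorphic in the evolved
    population are excluded and counted in ``n_excluded``.  Δr² respects
    -r²_base <= Δ <= 1 - r²_base by construction.
    """
    b_idx, e_idx = _match_sites(base, evolved)
    codes_b, bi_b = base.indicator_matrix()
    codes_e, bi_e = evolved.indicator_matrix()
    ok = bi_b[b_idx] & bi_e[e_idx]
    b_sites = b_idx[ok]
    e_sites = e_idx[ok]
    sites = base.sites.iloc[b_sites]
    pos_all = sites["pos"].to_numpy()
    chrom_all = sites["chrom"].to_numpy()
    rows = []
    edges = np.asarray(initial_bins)
    for chrom in np.unique(chrom_all):
        sel = np.flatnonzero(chrom_all == chrom)
        pos = pos_all[sel]
        order = np.argsort(pos)
        sel, pos = sel[order], pos[order]
        for lo, hi in distance_classes:
            ii, jj = _sample_pairs_in_bin(pos, lo, hi, max_pairs_per_class,
                                          rng)
            if ii.size == 0:
                continue
            r2b, eb = pair_r2(codes_b, b_sites[sel[ii]], b_sites[sel[jj]],
                              min_haplotypes)
            r2e, ee = pair_r2(codes_e, e_sites[sel[ii]], e_sites[sel[jj]],
                              min_haplotypes)
            both = eb & ee
            n_excluded = int((eb & ~ee).sum())
            delta = r2e[both] - r2b[both]
            r2b_ok = r2b[both]
            which = np.clip(np.searchsorted(edges, r2b_ok, side="right") - 1,
                            0, edges.size - 2)
            for k in range(edges.size - 1):
                d = delta[which == k]
                rows.append({
                    "chrom": chrom, "dist_lo": lo, "dist_hi": hi,
                    "initial_lo": float(edges[k]),
                    "initial_hi": float(edges[k + 1]),
                    "n_pairs": int(d.size),
                    "n_excluded": n_excluded,
                    "median": float(np.median(d)) if d.size else np.nan,
                    "q1": float(np.quantile(d, 0.25)) if d.size else np.nan,
                    "q3": float(np.quantile(d, 0.75)) if d.size else np.nan,
                    "mean": float(d.mean()) if d.size else np.nan,
                })
    return pd.DataFrame(rows)


def _category_of_sites(sites: pd.DataFrame,
                       categories: pd.DataFrame) -> np.ndarray:
    """Category label per site (object array, None when uncovered).

    ``categories`` has columns label, chrom, start, end (1-based inclusive).
    """
    out = np.full(len(sites), None, dtype=object)
    for chrom, grp in categories.groupby("chrom"):
        on_chrom = (sites["chrom"] == chrom).to_numpy()
        pos = sites["pos"].to_numpy()
        for _, iv in grp.iterrows():
            hit = on_chrom & (pos >= iv["start"]) & (pos <= iv["end"])
            out[hit] = iv["label"]
    return out


def stratified_ld_change(base: HaplotypeMatrix, evolved: HaplotypeMatrix,
                         categories: pd.DataFrame,
                         distance_bins: Sequence[tuple[int, int]],
                         min_haplotypes: int = DEFAULT_MIN_HAPLOTYPES,
                         max_pairs_per_bin: int | None = 20_000,
                         rng: np.random.Generator | None = None,
                         ) -> pd.DataFrame:
    """Per-category binned mean r² for base and evolved, plus Δ.

    A pair belongs to a category only when both sites fall into intervals of
    that same category; pairs spanning categories are counted separately
    (``n_cross_category``) and excluded from the per-category means.
    """
    b_idx, e_idx = _match_sites(base, evolved)
    codes_b, bi_b = base.indicator_matrix()
    codes_e, bi_e = evolved.indicator_matrix()
    ok = bi_b[b_idx] & bi_e[e_idx]
    b_sites, e_sites = b_idx[ok], e_idx[ok]
    sites = base.sites.iloc[b_sites].reset_index(drop=True)
    cat = _category_of_sites(sites, categories)
    labels = [l for l in pd.unique(categories["label"])]
    rows = []
    chrom_all = sites["chrom"].to_numpy()
    pos_all = sites["pos"].to_numpy()
    for chrom in np.unique(chrom_all):
        sel = np.flatnonzero(chrom_all == chrom)
        pos = pos_all[sel]
        order = np.argsort(pos)
        sel, pos = sel[order], pos[order]
        for lo, hi in distance_bins:
            ii, jj = _sample_pairs_in_bin(pos, lo, hi, max_pairs_per_bin, rng)
            if ii.size == 0:
                continue
            ca = cat[sel[ii]]
            cb = cat[sel[jj]]
            same = (ca == cb) & (ca != None)  # noqa: E711
            n_cross = int(((ca != cb) & (ca != None) & (cb != None)).sum())  # noqa: E711
            r2b, eb = pair_r2(codes_b, b_sites[sel[ii]], b_sites[sel[jj]],
                              min_haplotypes)
            r2e, ee = pair_r2(codes_e, e_sites[sel[ii]], e_sites[sel[jj]],
                              min_haplotypes)
            both = eb & ee
            for label in labels:
                use = same & (ca == label) & both
                n = int(use.sum())
                rows.append({
                    "category": label, "chrom": chrom,
                    "dist_lo": lo, "dist_hi": hi, "n_pairs": n,
                    "n_cross_category": n_cross,
                    "mean_r2_base": float(np.mean(r2b[use])) if n else np.nan,
                    "mean_r2_evolved": float(np.mean(r2e[use])) if n else np.nan,
                    "mean_delta": float(np.mean(r2e[use] - r2b[use]))
                    if n else np.nan,
                })
    return pd.DataFrame(rows)
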
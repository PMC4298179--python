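"""Detection of selected haplotype-blocks from singleton-marker windows.

The idea: a SNP allele carried by exactly one sequenced founder haplotype (a
singleton) is a private marker of that haplotype, so the Pool-Seq frequency
trajectory of a haplotype's singletons tracks the haplotype itself.  The scan

1. assigns every singleton site of the founder matrix to its haplotype,
2. slides a window of 20 consecutive singletons (step 5, i.e. overlap 15)
   along each haplotype and chromosome,
3. for each window fits a two-factor fixed-effects ANOVA of the 20 marker
   frequencies on timepoint x replicate and takes the Tukey-HSD family-wise
   95% lower confidence bound of the mean frequency increase from the base
   to each later timepoint,
4. flags windows whose lower bound exceeds the per-timepoint empirical
   threshold (from the CMH top candidates, :func:`erhaplo.cmh.derive_thresholds`),
5. merges flagged windows of the same haplotype transitively when they
   overlap or lie less than 2 cM apart on the genetic map.

Merged runs of windows are the reported haplotype-blocks, spanning the
outermost member singleton positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import HaplotypeMatrix, PoolCounts, RecombMap

__all__ = [
    "SingletonWindow",
    "find_singletons",
    "build_windows",
    "window_frequencies",
    "tukey_increase_bounds",
    "window_increase",
    "scan_windows",
    "call_blocks",
    "scan_blocks",
    "pipeline_run",
    "neutral_block_rate",
]


def find_singletons(matrix: HaplotypeMatrix,
                    min_called: int = 24) -> dict[str, pd.DataFrame]:
    """Singleton sites per haplotype.

    A site is a singleton of haplotype ``h`` when, among called haplotypes,
    exactly two alleles segregate and the minor allele is carried by ``h``
    alone, with at least ``min_called`` haplotypes called at the site.
    Each singleton site belongs to exactly one haplotype (a partition).
    """
    calls = matrix.calls
    sites = matrix.sites
    n_hap, n_sites = calls.shape
    alphabet = np.array(["A", "C", "G", "N", "T"])  # sorted
    codes = np.searchsorted(alphabet, calls)        # hap x sites, 0..4
    counts = np.zeros((5, n_sites), dtype=np.int32)
    for a in range(5):
        counts[a] = (codes == a).sum(axis=0)
    nuc_counts = counts[[0, 1, 2, 4]]               # drop N
    n_called = n_hap - counts[3]
    n_alleles = (nuc_counts > 0).sum(axis=0)
    # singleton: exactly two alleles, minor count 1, major count > 1
    sorted_counts = np.sort(nuc_counts, axis=0)
    eligible = ((n_called >= min_called) & (n_alleles == 2)
                & (sorted_counts[-2] == 1) & (sorted_counts[-1] > 1))
    nuc_idx = np.array([0, 1, 2, 4])
    masked = np.where(nuc_counts > 0, nuc_counts, np.iinfo(np.int32).max)
    minor_code = nuc_idx[masked.argmin(axis=0)]
    out: dict[str, list] = {h: [] for h in matrix.ids}
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for j in np.flatnonzero(eligible):
        carrier = int((codes[:, j] == minor_code[j]).argmax())
        out[matrix.ids[carrier]].append(
            (int(j), chrom_arr[j], int(pos_arr[j]),
             str(alphabet[minor_code[j]])))
    return {
        h: pd.DataFrame(rows, columns=["site", "chrom", "pos", "allele"])
        for h, rows in out.items()
    }


@dataclass
class SingletonWindow:
    """A run of consecutive singletons of one haplotype on one chromosome."""

    haplotype: str
    chrom: str
    index: int                     # running window number per haplotype/chrom
    positions: np.ndarray          # bp of member singletons, sorted
    alleles: np.ndarray            # singleton allele per member site
    site_rows: np.ndarray          # row numbers in the haplotype's singleton table

    @property
    def start(self) -> int:
        return int(self.positions[0])

    @property
    def end(self) -> int:
        return int(self.positions[-1])


def build_windows(singletons: Mapping[str, pd.DataFrame],
                  size: int = 20, step: int = 5) -> list[SingletonWindow]:
    """Sliding windows of ``size`` singletons advancing by ``step``.

    Windows start at singleton indices 0, step, 2*step, ... per haplotype and
    chromosome; a trailing run shorter than ``size`` is dropped.
    """
    windows: list[SingletonWindow] = []
    for hap, df in singletons.items():
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("pos").reset_index()
            n = len(grp)
            w = 0
            for start in range(0, n - size + 1, step):
                sl = grp.iloc[start:start + size]
                windows.append(SingletonWindow(
                    haplotype=hap, chrom=chrom, index=w,
                    positions=sl["pos"].to_numpy(),
                    alleles=sl["allele"].to_numpy(dtype="<U1"),
                    site_rows=sl["index"].to_numpy()))
                w += 1
    return windows


def window_frequencies(window: SingletonWindow, pool: PoolCounts,
                       site_lookup: Mapping[tuple, int] | None = None,
                       ) -> pd.DataFrame:
    """Pool-Seq frequency of each singleton allele in every sample.

    Returns a tidy frame (marker, replicate, generation, timepoint, freq);
    markers absent from the sync data are skipped, zero-coverage samples
    yield NaN.
    """
    if site_lookup is None:
        site_lookup = pool.site_lookup()
    rows = []
    idx = [site_lookup.get((window.chrom, int(p))) for p in window.positions]
    design = pool.design
    cov = pool.coverage()
    for m, (i, allele) in enumerate(zip(idx, window.alleles)):
        if i is None:
            continue
        counts = pool.allele_counts(allele)[i]
        for s in range(pool.n_samples):
            c = cov[i, s]
            freq = counts[s] / c if c > 0 else np.nan
            rows.append({
                "marker": m,
                "replicate": design["replicate"].iloc[s],
                "generation": design["generation"].iloc[s],
                "timepoint": design["timepoint"].iloc[s],
                "freq": freq,
            })
    return pd.DataFrame(rows)


from functools import lru_cache


@lru_cache(maxsize=1024)
def _studentized_range_crit(level: float, k: int, df: int) -> float:
    # expensive in scipy (numerical integration); identical across windows
    return float(stats.studentized_range.ppf(level, k, df))


def tukey_increase_bounds(obs: pd.DataFrame, base_timepoint: str = "F0",
                          level: float = 0.95) -> dict[str, float]:
    """Tukey-HSD lower confidence bounds of mean increases over the base.

    ``obs`` needs columns ``freq``, ``timepoint``, ``replicate``.  A
    two-factor fixed-effects ANOVA (timepoint, replicate, interaction) gives
    the residual mean square on N - (#timepoints x #replicates) degrees of
    freedom; the family-wise ``level`` interval on each timepoint-mean
    difference uses the studentized range with the number of timepoint
    levels.  With zero residual variance (or zero residual df) the interval
    collapses to the point estimate.  Returns
    ``{timepoint: lower bound of (mean_t - mean_base)}``.
    """
    obs = obs.dropna(subset=["freq"])
    tps = list(pd.unique(obs["timepoint"]))
    if base_timepoint not in tps:
        raise ValueError(f"base timepoint {base_timepoint!r} not in data")
    cells = obs.groupby(["timepoint", "replicate"], sort=False)["freq"]
    cell_mean = cells.transform("mean")
    resid = obs["freq"] - cell_mean
    n_cells = cells.ngroups
    n_obs = len(obs)
    df_err = n_obs - n_cells
    mse = float((resid ** 2).sum() / df_err) if df_err > 0 else 0.0
    group = obs.groupby("timepoint", sort=False)["freq"]
    means = group.mean()
    sizes = group.size()
    k = len(tps)
    if mse > 0 and df_err > 0:
        q = _studentized_range_crit(level, k, df_err)
    else:
        q = 0.0
    out = {}
    for tp in tps:
        if tp == base_timepoint:
            continue
        diff = means[tp] - means[base_timepoint]
        se = np.sqrt(mse / 2 * (1 / sizes[tp] + 1 / sizes[base_timepoint]))
        out[tp] = float(diff - q * se)
    return out


def window_increase(window: SingletonWindow, pool: PoolCounts,
                    base_timepoint: str = "F0",
                    target_timepoints: Sequence[str] = ("F15", "F37", "F59"),
                    level: float = 0.95,
                    site_lookup: Mapping[tuple, int] | None = None,
                    freqs: pd.DataFrame | None = None,
                    ) -> dict[str, float]:
    """Lower-bound frequency-increase estimate of one window per timepoint.

    A timepoint is skipped (absent from the result) when any
    timepoint x replicate cell involved in its contrast is entirely missing.
    ``freqs`` may supply a precomputed :func:`window_frequencies` table.
    """
    if freqs is None:
        freqs = window_frequencies(window, pool, site_lookup)
    freqs = freqs[freqs["timepoint"].isin([base_timepoint,
                                           *target_timepoints])]
    freqs = freqs.dropna(subset=["freq"])
    if freqs.empty or base_timepoint not in set(freqs["timepoint"]):
        return {}
    reps = set(freqs["replicate"])
    have = freqs.groupby("timepoint")["replicate"].agg(set)
    usable = [tp for tp in (base_timepoint, *target_timepoints)
              if tp in have.index and have[tp] == reps]
    if base_timepoint not in usable or len(usable) < 2:
        return {}
    sub = freqs[freqs["timepoint"].isin(usable)]
    bounds = tukey_increase_bounds(sub, base_timepoint, level)
    return {tp: bounds[tp] for tp in usable if tp != base_timepoint}


def _tukey_lower_fast(X: np.ndarray, tp_of_col: np.ndarray,
                      rep_of_col: np.ndarray, tp_labels: Sequence[str],
                      base_timepoint: str, level: float,
                      ) -> tuple[dict[str, float], dict[str, float]]:
    """Numpy implementation of the per-window Tukey lower bounds.

    Same model as :func:`tukey_increase_bounds` (two-factor cell means,
    residual MSE, studentized-range interval) without DataFrame overhead;
    the two paths are asserted equal in the test suite.  ``X`` is the
    markers x samples frequency matrix (NaN = no coverage).  Returns
    ``(lower_bounds, point_rises)`` keyed by timepoint label.
    """
    valid = ~np.isnan(X)
    tp_idx = {tp: i for i, tp in enumerate(pd.unique(tp_of_col))}
    rep_idx = {r: i for i, r in enumerate(pd.unique(rep_of_col))}
    T, R = len(tp_idx), len(rep_idx)
    col_tp = np.array([tp_idx[t] for t in tp_of_col])
    col_rep = np.array([rep_idx[r] for r in rep_of_col])
    col_cell = col_tp * R + col_rep
    col_cnt = valid.sum(axis=0)
    col_sum = np.where(valid, X, 0.0).sum(axis=0)
    col_sum2 = np.where(valid, X * X, 0.0).sum(axis=0)
    cell_cnt = np.bincount(col_cell, weights=col_cnt, minlength=T * R)
    # point rises use every timepoint with any data
    tp_cnt_all = np.bincount(col_tp, weights=col_cnt, minlength=T)
    tp_sum_all = np.bincount(col_tp, weights=col_sum, minlength=T)
    with np.errstate(invalid="ignore", divide="ignore"):
        tp_mean_all = np.where(tp_cnt_all > 0, tp_sum_all / tp_cnt_all,
                               np.nan)
    base_i = tp_idx.get(base_timepoint)
    rises: dict[str, float] = {}
    if base_i is not None and tp_cnt_all[base_i] > 0:
        for tp, i in tp_idx.items():
            if i != base_i and tp_cnt_all[i] > 0:
                rises[tp] = float(tp_mean_all[i] - tp_mean_all[base_i])
    # usable timepoints: data in every replicate observed anywhere
    cells = cell_cnt.reshape(T, R) > 0
    reps_any = cells.any(axis=0)
    usable = [tp for tp, i in tp_idx.items()
              if np.array_equal(cells[i] & reps_any, reps_any)
              and cells[i].any()]
    if base_timepoint not in usable or len(usable) < 2:
        return {}, rises
    use_tp = np.array([tp_idx[tp] for tp in usable])
    col_use = np.isin(col_tp, use_tp)
    cnt = np.where(col_use, col_cnt, 0)
    s1 = np.where(col_use, col_sum, 0.0)
    s2 = np.where(col_use, col_sum2, 0.0)
    cell_n = np.bincount(col_cell, weights=cnt, minlength=T * R)
    cell_s = np.bincount(col_cell, weights=s1, minlength=T * R)
    n_obs = cnt.sum()
    n_cells = int((cell_n > 0).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        ss_within = s2.sum() - np.where(cell_n > 0,
                                        cell_s ** 2 / np.maximum(cell_n, 1),
                                        0.0).sum()
    df_err = int(n_obs) - n_cells
    mse = max(float(ss_within) / df_err, 0.0) if df_err > 0 else 0.0
    tp_n = np.bincount(col_tp, weights=cnt, minlength=T)
    tp_s = np.bincount(col_tp, weights=s1, minlength=T)
    with np.errstate(invalid="ignore", divide="ignore"):
        tp_mean = np.where(tp_n > 0, tp_s / tp_n, np.nan)
    k = len(usable)
    q = _studentized_range_crit(level, k, df_err) \
        if (mse > 0 and df_err > 0) else 0.0
    bounds: dict[str, float] = {}
    bi = tp_idx[base_timepoint]
    for tp in usable:
        if tp == base_timepoint:
            continue
        i = tp_idx[tp]
        diff = tp_mean[i] - tp_mean[bi]
        se = np.sqrt(mse / 2 * (1 / tp_n[i] + 1 / tp_n[bi]))
        bounds[tp] = float(diff - q * se)
    return bounds, rises


def scan_windows(matrix: HaplotypeMatrix, pool: PoolCounts,
                 base_timepoint: str = "F0",
                 target_timepoints: Sequence[str] = ("F15", "F37", "F59"),
                 size: int = 20, step: int = 5, min_called: int = 24,
                 level: float = 0.95) -> pd.DataFrame:
    """All singleton windows with their Tukey lower bounds and point changes.

    One row per window; columns ``lb_<tp>`` hold the lower bounds and
    ``rise_<tp>`` the plain mean frequency changes (useful diagnostics such
    as the 99% quantile or maximum window change under neutrality).
    """
    singles = find_singletons(matrix, min_called)
    lookup = pool.site_lookup()
    cov = pool.coverage().astype(float)
    wanted = {base_timepoint, *target_timepoints}
    keep_cols = np.flatnonzero(
        pool.design["timepoint"].isin(wanted).to_numpy())
    tp_of_col = pool.design["timepoint"].to_numpy()[keep_cols]
    rep_of_col = pool.design["replicate"].to_numpy()[keep_cols]
    tp_labels = list(pd.unique(tp_of_col))
    rows = []
    for hap, df in singles.items():
        if df.empty:
            continue
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("pos").reset_index(drop=True)
            pos = grp["pos"].to_numpy()
            idx = np.array([lookup.get((chrom, int(p)), -1) for p in pos])
            F = np.full((len(grp), keep_cols.size), np.nan)
            for letter in ("A", "T", "C", "G"):
                mask = (grp["allele"].to_numpy() == letter) & (idx >= 0)
                if mask.any():
                    c = pool.allele_counts(letter)[np.ix_(idx[mask],
                                                          keep_cols)]
                    cv = cov[np.ix_(idx[mask], keep_cols)]
                    with np.errstate(invalid="ignore", divide="ignore"):
                        F[mask] = np.where(cv > 0, c / cv, np.nan)
            present = idx >= 0
            w = 0
            for start in range(0, len(grp) - size + 1, step):
                sel = slice(start, start + size)
                X = F[sel][present[sel]]
                row = {"haplotype": hap, "chrom": chrom, "window": w,
                       "start": int(pos[start]),
                       "end": int(pos[start + size - 1]),
                       "n_markers": int(present[sel].sum())}
                if X.shape[0]:
                    bounds, rises = _tukey_lower_fast(
                        X, tp_of_col, rep_of_col, tp_labels, base_timepoint,
                        level)
                else:
                    bounds, rises = {}, {}
                for tp in target_timepoints:
                    row[f"lb_{tp}"] = bounds.get(tp, np.nan)
                    row[f"rise_{tp}"] = rises.get(tp, np.nan)
                rows.append(row)
                w += 1
    cols = ["haplotype", "chrom", "window", "start", "end", "n_markers"]
    for tp in target_timepoints:
        cols += [f"lb_{tp}", f"rise_{tp}"]
    return pd.DataFrame(rows, columns=cols)


def call_blocks(window_table: pd.DataFrame,
                thresholds: Mapping[str, float],
                recomb_map: RecombMap,
                merge_cm: float = 2.0) -> pd.DataFrame:
    """Merge passing windows into haplotype-blocks.

    A window passes when its lower-bound estimate exceeds the threshold for
    any timepoint.  Passing windows of the same haplotype and chromosome are
    merged transitively when they overlap or the genetic distance between
    their nearest edges is below ``merge_cm`` (strictly).  Blocks report the
    outermost singleton positions, physical and genetic length, the mean
    local recombination rate and the union of supporting timepoints.
    """
    tps = list(thresholds)
    wt = window_table.copy()
    for tp in tps:
        wt[f"pass_{tp}"] = wt[f"lb_{tp}"] > thresholds[tp]
    wt["passing"] = np.logical_or.reduce([wt[f"pass_{tp}"] for tp in tps])
    passing = wt[wt["passing"]]
    blocks = []
    for (hap, chrom), grp in passing.groupby(["haplotype", "chrom"],
                                             sort=False):
        grp = grp.sort_values(["start", "end"])
        current: dict | None = None
        for _, w in grp.iterrows():
            w_tps = {tp for tp in tps if w[f"pass_{tp}"]}
            if current is not None:
                gap_ok = (w["start"] <= current["end"] or
                          recomb_map.genetic_distance(
                              chrom, current["end"], w["start"]) < merge_cm)
            if current is not None and gap_ok:
                current["end"] = max(current["end"], int(w["end"]))
                current["timepoints"] |= w_tps
                current["n_windows"] += 1
            else:
                if current is not None:
                    blocks.append(current)
                current = {"haplotype": hap, "chrom": chrom,
                           "start": int(w["start"]), "end": int(w["end"]),
                           "timepoints": set(w_tps), "n_windows": 1}
        if current is not None:
            blocks.append(current)
    rows = []
    for i, b in enumerate(blocks, start=1):
        length = b["end"] - b["start"] + 1
        rows.append({
            "block": i, "haplotype": b["haplotype"], "chrom": b["chrom"],
            "start": b["start"], "end": b["end"], "length": length,
            "mean_rate": recomb_map.mean_rate(b["chrom"], b["start"], b["end"]),
            "genetic_length_cm": recomb_map.genetic_distance(
                b["chrom"], b["start"], b["end"]),
            "timepoints": ",".join(sorted(b["timepoints"])),
            "n_windows": b["n_windows"],
        })
    return pd.DataFrame(rows, columns=[
        "block", "haplotype", "chrom", "start", "end", "length", "mean_rate",
        "genetic_length_cm", "timepoints", "n_windows"])


def scan_blocks(matrix: HaplotypeMatrix, pool: PoolCounts,
                recomb_map: RecombMap,
                thresholds: Mapping[str, float],
                base_timepoint: str = "F0",
                size: int = 20, step: int = 5, min_called: int = 24,
                merge_cm: float = 2.0,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full scan: windows -> estimates -> thresholded, merged blocks.

    Returns ``(blocks, window_table)``.
    """
    window_table = scan_windows(matrix, pool, base_timepoint,
                                tuple(thresholds), size, step, min_called)
    blocks = call_blocks(window_table, thresholds, recomb_map, merge_cm)
    return blocks, window_table


def pipeline_run(config, rng: np.random.Generator, depth_model=80,
                 n_known: int = 29, top_n: int = 2000,
                 target_timepoints: Sequence[str] = ("F15", "F37", "F59"),
                 min_called: int = 24, size: int = 20, step: int = 5,
                 merge_cm: float = 2.0,
                 thresholds: Mapping[str, float] | None = None,
                 known: Sequence[str] | None = None,
                 ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """One full scan pipeline on one simulated experiment.

    Simulates the replicated experiment from ``config``
    (:func:`erhaplo.sim.simulate_experiment`), derives the per-timepoint
    thresholds from that run's own CMH top candidates (unless fixed
    ``thresholds`` are supplied, e.g. as a positive-control setting), takes
    ``n_known`` randomly chosen founders as the sequenced base haplotypes
    (or the given ``known`` ids) and scans for blocks.  Returns
    ``(blocks, window_table, context)`` where ``context`` carries the panel,
    pool, snapshots, thresholds and known-haplotype ids for downstream
    checks.
    """
    from . import cmh as cmh_mod
    from . import sim as sim_mod

    panel, snapshots, pool = sim_mod.simulate_experiment(config, rng,
                                                         depth_model)
    if thresholds is None:
        thresholds = cmh_mod.derive_thresholds(pool, target_timepoints,
                                               top_n=top_n)
    if known is None:
        known = list(rng.choice(panel.matrix.ids, size=n_known,
                                replace=False))
    known = list(known)
    sub = panel.matrix.subset(haplotypes=known)
    blocks, window_table = scan_blocks(sub, pool, config.recomb_map,
                                       thresholds, size=size, step=step,
                                       min_called=min_called,
                                       merge_cm=merge_cm)
    context = {"panel": panel, "snapshots": snapshots, "pool": pool,
               "thresholds": thresholds, "known": known}
    return blocks, window_table, context


def neutral_block_rate(configs: Sequence, seed: int = 0, depth_model=80,
                       n_known: int = 29, top_n: int = 2000,
                       **scan_kwargs) -> list[int]:
    """Detected block counts across independent neutral pipeline runs.

    One run per config (e.g. five runs, three at Ne = 250 and two at
    Ne = 150); each run re-derives its thresholds from its own CMH top
    candidates.  The returned per-run block counts are the neutrality
    control: under pure drift (almost) no run should call a block.
    """
    ss = np.random.SeedSequence(seed)
    counts = []
    for config, child in zip(configs, ss.spawn(len(configs))):
        rng = np.random.default_rng(child)
        blk, _, _ = pipeline_run(config, rng, depth_model, n_known, top_n,
                                 **scan_kwargs)
        counts.append(len(blk))
    return counts
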
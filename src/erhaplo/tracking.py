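"""Tracking haplotype(-block) frequencies from Pool-Seq and auditing blocks.

Frequency tracking uses the median-of-markers estimator: a haplotype's
frequency in a pooled sample is estimated by the median Pool-Seq frequency of
its singleton markers in non-overlapping windows of 20 markers (a trailing
run shorter than 20 is folded into the last window so short blocks remain
trackable).  The median is robust to individual markers that are not truly
private — e.g. shared with an unsequenced founder — which is the dominant
error source when only a fraction of the founder haplotypes is known.

Block integrity compares the base-population block haplotype with evolved
haplotypes via the allele-sharing distance (1 - shared / jointly-called over
block SNPs), clusters with average linkage, and classifies each evolved
haplotype as intact, end-recombined, recombined or absent.

Candidate-SNP enrichment asks whether a block's singletons rank higher in
the CMH scan than the remaining singletons of the same chromosome
(Mann-Whitney U, BH-FDR), and whether their ranks trend over timepoints.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .io import HaplotypeMatrix, PoolCounts

__all__ = [
    "marker_window_medians",
    "estimate_block_frequency",
    "track_haplotypes",
    "evaluate_tracking_accuracy",
    "allele_sharing_distance",
    "block_integrity",
    "linkage_newick",
    "enrichment",
    "candidate_genes",
]


# ---------------------------------------------------------------------------
# Median-of-markers frequency estimation
# ---------------------------------------------------------------------------


def marker_window_medians(marker_freqs: np.ndarray,
                          window: int = 20) -> np.ndarray:
    """Median marker frequency in non-overlapping windows of ``window``.

    ``marker_freqs`` is (n_markers, n_samples), markers in chromosomal
    order.  Windows tile the markers with step = size; a trailing remainder
    is folded into the last window.  Even-count medians are the mean of the
    two central values.  Returns (n_windows, n_samples).
    """
    f = np.asarray(marker_freqs, dtype=float)
    if f.ndim == 1:
        f = f[:, None]
    n = f.shape[0]
    if n == 0:
        raise ValueError("no markers")
    n_win = max(n // window, 1)
    bounds = [(i * window, (i + 1) * window) for i in range(n_win)]
    lo, _ = bounds[-1]
    bounds[-1] = (lo, n)  # fold the trailing remainder into the last window
    return np.vstack([np.nanmedian(f[a:b], axis=0) for a, b in bounds])


def estimate_block_frequency(marker_freqs: np.ndarray, window: int = 20,
                             method: str = "mean_of_medians") -> np.ndarray:
    """Block frequency per sample from its singleton-marker frequencies.

    ``method="mean_of_medians"`` (default) averages the per-window medians;
    ``method="blockwide_median"`` takes a single median over all markers.
    """
    if method == "blockwide_median":
        f = np.asarray(marker_freqs, dtype=float)
        return np.nanmedian(f if f.ndim == 2 else f[:, None], axis=0)
    if method != "mean_of_medians":
        raise ValueError("unknown method")
    med = marker_window_medians(marker_freqs, window)
    return np.nanmean(med, axis=0)


def _marker_freq_matrix(singles: pd.DataFrame, pool: PoolCounts,
                        site_lookup: Mapping[tuple, int]) -> np.ndarray:
    """Frequencies (n_markers x n_samples) of one haplotype's singletons."""
    cov = pool.coverage().astype(float)
    rows = []
    for _, m in singles.iterrows():
        i = site_lookup.get((m["chrom"], int(m["pos"])))
        if i is None:
            continue
        counts = pool.allele_counts(m["allele"])[i].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rows.append(np.where(cov[i] > 0, counts / cov[i], np.nan))
    if not rows:
        return np.empty((0, pool.n_samples))
    return np.vstack(rows)


def track_haplotypes(singletons: Mapping[str, pd.DataFrame],
                     pool: PoolCounts, window: int = 20,
                     method: str = "mean_of_medians") -> pd.DataFrame:
    """Estimated frequency of every haplotype in every Pool-Seq sample.

    ``singletons`` is the per-haplotype marker table from
    :func:`erhaplo.blocks.find_singletons`.  Returns a tidy frame
    (haplotype, sample, replicate, generation, timepoint, estimate).
    """
    lookup = pool.site_lookup()
    rows = []
    for hap, singles in singletons.items():
        if singles.empty:
            continue
        singles = singles.sort_values(["chrom", "pos"])
        freqs = _marker_freq_matrix(singles, pool, lookup)
        if freqs.shape[0] == 0:
            continue
        est = estimate_block_frequency(freqs, window, method)
        for s in range(pool.n_samples):
            d = pool.design.iloc[s]
            rows.append({
                "haplotype": hap, "sample": d["sample"],
                "replicate": d["replicate"], "generation": d["generation"],
                "timepoint": d["timepoint"], "estimate": float(est[s]),
            })
    return pd.DataFrame(rows)


def evaluate_tracking_accuracy(panel, snapshots, pool: PoolCounts,
                               known_haplotypes: Sequence[str],
                               window: int = 20,
                               min_called: int | None = None,
                               ) -> dict:
    """Mean absolute deviation of tracked vs true haplotype frequencies.

    ``snapshots`` maps each Pool-Seq sample (by design generation) to the
    :class:`erhaplo.sim.Population` it was sampled from, providing exact
    founder-haplotype frequencies as truth.  Markers are re-derived from the
    ``known_haplotypes`` subset only, emulating partially known founders.
    Deviations are collected per window, haplotype and sample; the headline
    number is their mean.
    """
    from .blocks import find_singletons

    known = list(known_haplotypes)
    sub = panel.matrix.subset(haplotypes=known)
    if min_called is None:
        min_called = len(known)
    singles = find_singletons(sub, min_called=min_called)
    lookup = pool.site_lookup()
    founder_row = {h: i for i, h in enumerate(panel.matrix.ids)}
    truth_by_gen = {gen: p.founder_frequencies()
                    for gen, p in snapshots.items()}
    devs = []
    per_hap: dict[str, list] = {h: [] for h in known}
    for hap in known:
        singles_h = singles[hap].sort_values(["chrom", "pos"])
        if singles_h.empty:
            continue
        freqs = _marker_freq_matrix(singles_h, pool, lookup)
        if freqs.shape[0] == 0:
            continue
        med = marker_window_medians(freqs, window)
        for s in range(pool.n_samples):
            gen = pool.design["generation"].iloc[s]
            truth = truth_by_gen[gen][founder_row[hap]]
            d = np.abs(med[:, s] - truth)
            d = d[~np.isnan(d)]
            devs.extend(d.tolist())
            per_hap[hap].extend(d.tolist())
    if not devs:
        raise ValueError("known subset yielded no usable markers")
    return {
        "mad": float(np.mean(devs)),
        "n_deviations": len(devs),
        "per_haplotype": {h: float(np.mean(v)) for h, v in per_hap.items()
                          if v},
    }


# ---------------------------------------------------------------------------
# Block integrity
# ---------------------------------------------------------------------------


def allele_sharing_distance(calls_a: np.ndarray, calls_b: np.ndarray,
                            min_called_fraction: float = 0.2,
                            ) -> float:
    """1 - (shared calls / jointly called sites); NaN below call threshold."""
    a = np.asarray(calls_a, dtype="<U1")
    b = np.asarray(calls_b, dtype="<U1")
    joint = (a != "N") & (b != "N")
    if joint.sum() < min_called_fraction * a.size:
        return float("nan")
    return float(1.0 - (a[joint] == b[joint]).mean())


def _scipy_tree_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _scipy_tree_to_newick(node.get_left(), labels)
    right = _scipy_tree_to_newick(node.get_right(), labels)
    return f"({left},{right}):{node.dist:.6g}"


def linkage_newick(dist_matrix: np.ndarray, labels: Sequence[str]) -> str:
    """Average-linkage (UPGMA-style) tree of a distance matrix as Newick."""
    condensed = dist_matrix[np.triu_indices(len(labels), k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    tree = hierarchy.to_tree(Z)
    return _scipy_tree_to_newick(tree, list(labels)) + ";"


def block_integrity(base_calls: np.ndarray,
                    evolved: HaplotypeMatrix,
                    positions: np.ndarray,
                    epsilon: float = 0.005,
                    end_fraction: float = 0.1,
                    min_called_fraction: float = 0.2,
                    absent_distance: float = 0.5) -> dict:
    """Classify how well a block survived in the evolved haplotypes.

    ``base_calls`` are the block haplotype's calls over the block SNPs (in
    chromosomal order, positions given); ``evolved`` holds the evolved
    haplotypes restricted to the same sites.  Per evolved haplotype:

    * ``intact`` — allele-sharing distance <= epsilon;
    * ``end_recombined`` — mismatches confined to the terminal
      ``end_fraction`` of the block span at either end;
    * ``recombined`` — interior mismatches but overall distance below
      ``absent_distance``;
    * ``absent`` — no meaningful sharing (distance >= absent_distance);
    * ``excluded`` — fewer than ``min_called_fraction`` of block SNPs called.

    Returns the per-haplotype table, the block-level status (``persistent``
    if any evolved copy is intact or end-recombined, else ``absent``) and an
    average-linkage Newick tree over base + non-excluded evolved haplotypes.
    """
    base_calls = np.asarray(base_calls, dtype="<U1")
    positions = np.asarray(positions)
    span_lo = positions[0] + end_fraction * (positions[-1] - positions[0])
    span_hi = positions[-1] - end_fraction * (positions[-1] - positions[0])
    interior = (positions >= span_lo) & (positions <= span_hi)
    rows = []
    kept_calls = [base_calls]
    kept_labels = ["base"]
    for i, hap in enumerate(evolved.ids):
        calls = evolved.calls[i]
        dist = allele_sharing_distance(base_calls, calls, min_called_fraction)
        if np.isnan(dist):
            rows.append({"haplotype": hap, "distance": np.nan,
                         "class": "excluded"})
            continue
        joint = (base_calls != "N") & (calls != "N")
        mism = joint & (base_calls != calls)
        interior_mismatch = (mism & interior).sum()
        interior_joint = (joint & interior).sum()
        interior_dist = (interior_mismatch / interior_joint
                         if interior_joint else 0.0)
        if dist <= epsilon:
            cls = "intact"
        elif interior_dist <= epsilon:
            cls = "end_recombined"
        elif dist < absent_distance:
            cls = "recombined"
        else:
            cls = "absent"
        rows.append({"haplotype": hap, "distance": dist, "class": cls})
        kept_calls.append(calls)
        kept_labels.append(hap)
    table = pd.DataFrame(rows)
    ok = table["class"].isin(["intact", "end_recombined"])
    status = "persistent" if ok.any() else "absent"
    newick = None
    if len(kept_labels) >= 3:
        m = len(kept_labels)
        D = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                d = allele_sharing_distance(kept_calls[i], kept_calls[j],
                                            min_called_fraction=0.0)
                D[i, j] = D[j, i] = 0.0 if np.isnan(d) else d
        newick = linkage_newick(D, kept_labels)
    return {"haplotypes": table, "status": status, "newick": newick}


# ---------------------------------------------------------------------------
# Candidate-SNP enrichment
# ---------------------------------------------------------------------------


def enrichment(blocks: pd.DataFrame,
               singletons: Mapping[str, pd.DataFrame],
               cmh_results: Mapping[str, pd.DataFrame],
               top_n: int = 2000) -> dict:
    """Enrichment of block singletons among top CMH candidates.

    For each block and each base-vs-timepoint comparison, the CMH ranks of
    the block haplotype's singletons inside the block span are compared with
    the ranks of all non-block singletons on the same chromosome (two-sided
    Mann-Whitney U with normal approximation and tie correction); p-values
    are BH-adjusted across blocks x comparisons.  A per-block linear trend
    of rank on timepoint index is fitted the same way.  ``top_capture``
    reports, per comparison, the fraction of the ``top_n`` ranked SNPs that
    fall inside any block span.
    """
    tps = list(cmh_results)
    rank_maps = {
        tp: res.set_index(["chrom", "pos"])["rank"] for tp, res in
        cmh_results.items()
    }
    # singleton membership: which block (if any) covers each singleton
    all_singles = []
    for hap, df in singletons.items():
        d = df.copy()
        d["haplotype"] = hap
        all_singles.append(d)
    singles = pd.concat(all_singles, ignore_index=True)
    singles["block"] = 0
    for _, b in blocks.iterrows():
        inside = ((singles["haplotype"] == b["haplotype"])
                  & (singles["chrom"] == b["chrom"])
                  & (singles["pos"] >= b["start"])
                  & (singles["pos"] <= b["end"]))
        singles.loc[inside, "block"] = b["block"]
    in_any_block_span = np.zeros(len(singles), dtype=bool)
    for _, b in blocks.iterrows():
        in_any_block_span |= ((singles["chrom"] == b["chrom"])
                              & (singles["pos"] >= b["start"])
                              & (singles["pos"] <= b["end"])).to_numpy()
    rows = []
    trend_rows = []
    for _, b in blocks.iterrows():
        block_mask = (singles["block"] == b["block"]).to_numpy()
        bg_mask = ((singles["chrom"] == b["chrom"]).to_numpy()
                   & ~in_any_block_span)
        trend_x, trend_y = [], []
        for t_i, tp in enumerate(tps):
            rmap = rank_maps[tp]
            def _ranks(mask):
                idx = pd.MultiIndex.from_frame(
                    singles.loc[mask, ["chrom", "pos"]])
                r = rmap.reindex(idx)
                return r.dropna().to_numpy()
            br = _ranks(block_mask)
            gr = _ranks(bg_mask)
            if br.size < 2 or gr.size < 2:
                continue
            u = stats.mannwhitneyu(br, gr, alternative="two-sided",
                                   method="asymptotic")
            rows.append({"block": b["block"], "timepoint": tp,
                         "n_block": br.size, "n_background": gr.size,
                         "median_rank": float(np.median(br)),
                         "median_background_rank": float(np.median(gr)),
                         "U": float(u.statistic), "p_value": float(u.pvalue)})
            trend_x.extend([t_i] * br.size)
            trend_y.extend(br.tolist())
        if len(set(trend_x)) >= 2:
            slope, _, _, p, _ = stats.linregress(trend_x, trend_y)
            trend_rows.append({"block": b["block"], "slope": float(slope),
                               "p_value": float(p)})
    utable = pd.DataFrame(rows)
    if not utable.empty:
        utable["q_value"] = multipletests(utable["p_value"], method="fdr_bh")[1]
    ttable = pd.DataFrame(trend_rows)
    if not ttable.empty:
        ttable["q_value"] = multipletests(ttable["p_value"], method="fdr_bh")[1]
    capture = {}
    for tp, res in cmh_results.items():
        top = res[res["rank"] <= top_n]
        inside = np.zeros(len(top), dtype=bool)
        for _, b in blocks.iterrows():
            inside |= ((top["chrom"] == b["chrom"])
                       & (top["pos"] >= b["start"])
                       & (top["pos"] <= b["end"])).to_numpy()
        capture[tp] = float(inside.mean()) if len(top) else float("nan")
    return {"u_tests": utable, "trends": ttable, "top_capture": capture}


def candidate_genes(block: Mapping, block_sites: pd.DataFrame,
                    genes: pd.DataFrame, padding: int = 0,
                    max_base_frequency: float = 0.1) -> list[str]:
    """Genes containing a low-frequency block allele.

    ``block_sites`` lists the block haplotype's SNPs with columns chrom,
    pos, base_freq (frequency of the block allele in the base population);
    ``genes`` has chrom, start, end, name.  A gene qualifies when its
    (optionally padded) interval contains at least one block SNP whose base
    frequency is below ``max_base_frequency``.
    """
    sel = block_sites[
        (block_sites["chrom"] == block["chrom"])
        & (block_sites["pos"] >= block["start"])
        & (block_sites["pos"] <= block["end"])
        & (block_sites["base_freq"] < max_base_frequency)]
    if sel.empty:
        return []
    out = []
    for _, g in genes[genes["chrom"] == block["chrom"]].iterrows():
        lo, hi = g["start"] - padding, g["end"] + padding
        if ((sel["pos"] >= lo) & (sel["pos"] <= hi)).any():
            out.append(g["name"])
    return out
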
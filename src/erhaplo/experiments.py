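"""Desk-scale reference experiments: the package's standard study conditions.

Each function runs one self-contained simulation experiment whose conditions
mirror the emulated E&R study at a scale that finishes in seconds to minutes:

* :func:`background_ld_experiment` — sample-size floor of r² between
  unlinked loci in a sample of ~26 haplotypes.
* :func:`tracking_accuracy_experiment` — accuracy of median-of-markers
  haplotype frequency tracking with partially known founders.
* :func:`neutral_control_experiment` — the full block-detection pipeline on
  neutral whole-genome simulations (the false-positive control).
* :func:`planted_sweep_experiment` — positive control: recovery of a
  selected low-frequency founder haplotype.

Scaled-down choices (documented in the methods note): genomes of 1-2
chromosome arms with 10-50k SNPs each instead of ~1.45M genome-wide; the
threshold-defining CMH candidate list is scaled to preserve the candidate
*fraction* (2,000 / 1.45M ~ 0.14%), since the threshold's meaning depends on
how deep into the tail the candidate list reaches, not on its absolute size.
"""

from __future__ import annotations

import numpy as np

from . import blocks as blocks_mod
from . import sim as sim_mod
from . import tracking as tracking_mod
from .io import RecombMap
from .ld import background_ld

__all__ = [
    "FULL_SCALE_SNPS",
    "FULL_SCALE_TOP_N",
    "PAPER_THRESHOLDS",
    "scaled_top_n",
    "background_ld_experiment",
    "tracking_accuracy_experiment",
    "neutral_control_experiment",
    "planted_sweep_experiment",
]

#: SNP count and candidate-list size of the emulated full-scale analysis
FULL_SCALE_SNPS = 1_450_000
FULL_SCALE_TOP_N = 2_000

#: per-timepoint detection thresholds of the full-scale study (fixed inputs
#: for positive-control runs)
PAPER_THRESHOLDS = {"F15": 0.1489, "F37": 0.1851, "F59": 0.2771}


def scaled_top_n(n_snps: int) -> int:
    """Candidate-list size preserving the full-scale candidate fraction."""
    return max(1, round(n_snps * FULL_SCALE_TOP_N / FULL_SCALE_SNPS))


def background_ld_experiment(seed: int = 0, n_haplotypes: int = 26,
                             n_chromosomes: int = 5, snps_per_chrom: int = 2000,
                             max_pairs: int = 100_000) -> dict:
    """Mean inter-chromosomal r² between unlinked loci.

    Simulates ``n_haplotypes`` haplotypes at independent biallelic SNPs with
    a neutral folded SFS (conditioned on polymorphism) on several chromosome
    labels, then averages r² over random cross-chromosome pairs.  For
    unlinked loci the expectation is ~1/n, the sampling floor of r².
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lengths = {f"chr{i + 1}": 20_000_000 for i in range(n_chromosomes)}
    cfg = sim_mod.SimulationConfig(
        chrom_lengths=lengths,
        sites_per_chrom={c: snps_per_chrom for c in lengths},
        n_founders=n_haplotypes, effective_size=n_haplotypes,
        generations=(0,))
    panel = sim_mod.make_founder_panel(cfg, rng)
    mean_r2 = background_ld(panel.matrix, n_per_chrom=snps_per_chrom,
                            max_pairs=max_pairs, rng=rng)
    return {"mean_r2": mean_r2, "n_pairs": max_pairs,
            "n_haplotypes": n_haplotypes}


def tracking_accuracy_experiment(seed: int = 0, n_founders: int = 158,
                                 n_sites: int = 16_000, ne: int = 200,
                                 depth: int = 80,
                                 generations=(0, 20, 40, 60),
                                 n_known: int = 29,
                                 known_fractions=(0.2, 0.5, 0.75)) -> dict:
    """Median-of-markers tracking accuracy with partially known founders.

    One chromosome arm, neutral evolution at ``ne`` without recombination
    over ~60 generations, Pool-Seq at ``depth``; singleton markers are
    re-derived from a random known subset and the estimator is scored
    against the simulator's exact haplotype frequencies.  Returns the mean
    absolute deviation for ``n_known`` known founders and for each fraction
    in ``known_fractions`` (nested subsets of one random founder ordering).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cfg = sim_mod.SimulationConfig(
        chrom_lengths={"2L": 20_000_000},
        sites_per_chrom={"2L": n_sites},
        n_founders=n_founders, effective_size=ne,
        generations=tuple(generations), recomb_map=None)
    panel = sim_mod.make_founder_panel(cfg, rng)
    pop = sim_mod.initialize_population(panel, cfg, rng)
    snaps = sim_mod.evolve(pop, cfg, rng)
    pool = sim_mod.sample_poolseq(
        [("R1", g, snaps[g]) for g in generations], depth, rng)
    order = list(rng.permutation(panel.matrix.ids))
    main = tracking_mod.evaluate_tracking_accuracy(panel, snaps, pool,
                                                   order[:n_known])
    by_fraction = {}
    for f in known_fractions:
        m = int(round(f * n_founders))
        res = tracking_mod.evaluate_tracking_accuracy(panel, snaps, pool,
                                                      order[:m])
        by_fraction[f] = res["mad"]
    return {"mad": main["mad"], "n_deviations": main["n_deviations"],
            "by_fraction": by_fraction}


def _neutral_config(ne: int, snps_per_chrom: int = 50_000,
                    chrom_length: int = 12_000_000) -> sim_mod.SimulationConfig:
    lengths = {"2L": chrom_length, "2R": chrom_length}
    return sim_mod.SimulationConfig(
        chrom_lengths=lengths,
        sites_per_chrom={c: snps_per_chrom for c in lengths},
        n_founders=158, effective_size=ne,
        generations=(0, 15, 37, 59),
        recomb_map=RecombMap.uniform(lengths, 2.0))


def neutral_control_experiment(seed: int = 0, depth: int = 80,
                               snps_per_chrom: int = 50_000) -> list[int]:
    """Block counts of five neutral whole-pipeline runs (Sim1-3 at Ne=250,
    Sim4-5 at Ne=150), thresholds re-derived per run from that run's own
    CMH candidates at the full-scale candidate fraction."""
    configs = [_neutral_config(250, snps_per_chrom)] * 3 \
        + [_neutral_config(150, snps_per_chrom)] * 2
    top_n = scaled_top_n(2 * snps_per_chrom)
    return blocks_mod.neutral_block_rate(configs, seed=seed,
                                         depth_model=depth, n_known=29,
                                         top_n=top_n)


def planted_sweep_experiment(seed: int = 0, n_runs: int = 5,
                             n_sites: int = 20_000, s: float = 0.3,
                             n_diploids: int = 500,
                             depth: int = 80) -> list[dict]:
    """Positive control: a selected haplotype starting at 1/113.

    One chromosome without recombination; the favoured allele is a singleton
    of one founder, giving that haplotype viability advantage ``1 + s`` when
    homozygous (h = 0.5).  The population is census-sized (default 500
    diploids, so the carrier starts from ~9 copies at frequency 1/113);
    at drift-sized N the handful of starting copies would be lost to
    stochastic extinction in a large fraction of replicates, which is an
    establishment question, not a detection one.  The scan runs with the
    full-scale study's fixed thresholds.  Each run reports whether a block
    of the carrier haplotype was detected and how much of the carrier's
    passing-window span the detected block covers.
    """
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_runs):
        rng = np.random.default_rng(child)
        L = 12_000_000
        rmap0 = RecombMap.uniform({"2L": L}, 0.0)
        cfg = sim_mod.SimulationConfig(
            chrom_lengths={"2L": L}, sites_per_chrom={"2L": n_sites},
            n_founders=113, effective_size=n_diploids,
            generations=(0, 15, 37, 59), recomb_map=rmap0)
        panel = sim_mod.make_founder_panel(cfg, rng)
        singleton_sites = np.flatnonzero(panel.alt.sum(axis=0) == 1)
        site = int(rng.choice(singleton_sites))
        carrier_idx = int(panel.alt[:, site].argmax())
        carrier = panel.matrix.ids[carrier_idx]
        cfg.selection_targets = (sim_mod.SelectionTarget(
            "2L", int(panel.sites["pos"].iloc[site]), s=s, h=0.5,
            allele=str(panel.alt_alleles[site])),)
        samples = []
        for rep in cfg.replicates:
            pop = sim_mod.initialize_population(panel, cfg, rng)
            gens = [cfg.sampled_generation(rep, g) for g in cfg.generations]
            snaps = sim_mod.evolve(pop, cfg, rng, sampling_generations=gens)
            for dg, ag in zip(cfg.generations, gens):
                samples.append((rep, dg, snaps[ag]))
        pool = sim_mod.sample_poolseq(samples, depth, rng)
        others = [h for h in panel.matrix.ids if h != carrier]
        known = [carrier] + list(rng.choice(others, 28, replace=False))
        sub = panel.matrix.subset(haplotypes=known)
        blk, wt = blocks_mod.scan_blocks(sub, pool, rmap0, PAPER_THRESHOLDS,
                                         min_called=24)
        cw = wt[wt.haplotype == carrier]
        passing = cw[np.logical_or.reduce(
            [cw[f"lb_{tp}"] > thr for tp, thr in PAPER_THRESHOLDS.items()])]
        carrier_blocks = blk[blk.haplotype == carrier]
        if len(passing) == 0 or len(carrier_blocks) == 0:
            out.append({"detected": False, "span_coverage": 0.0,
                        "n_blocks": len(blk)})
            continue
        span_lo = int(passing["start"].min())
        span_hi = int(passing["end"].max())
        b = carrier_blocks.iloc[0]
        overlap = max(0, min(b["end"], span_hi) - max(b["start"], span_lo) + 1)
        out.append({
            "detected": True,
            "span_coverage": overlap / (span_hi - span_lo + 1),
            "n_blocks": len(blk),
        })
    return out
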
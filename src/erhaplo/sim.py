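"""Forward Wright-Fisher simulation of E&R experiments from founder haplotypes.

The experimental design being emulated: a laboratory population founded from
order-100 wild-derived haplotypes, kept at a census of ~1,000 flies (effective
size 150-250), evolved for tens of discrete generations in replicate, and
sequenced as pools at a handful of timepoints.  Because the experiment relies
on standing variation only, no new mutation is simulated; every chromosome in
every generation is a mosaic of founder segments.  That mosaic is the internal
representation — each chromosome is a list of (segment start, founder index)
pairs — which makes whole-genome simulation cheap and gives exact truth for
haplotype(-block) frequencies.

Selection, when requested, acts through relative viabilities 1 : 1+hs : 1+s,
multiplicative across loci.  Crossovers per gamete are Poisson with mean equal
to the genetic map length in Morgans, placed proportionally to the local rate
(no interference).  Pool-Seq sampling draws binomial read counts at each site
from the population allele frequency, matching how real coverage was imposed
on simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import NUCLEOTIDES, HaplotypeMatrix, PoolCounts, RecombMap

__all__ = [
    "SelectionTarget",
    "SimulationConfig",
    "FounderPanel",
    "Population",
    "make_founder_panel",
    "initialize_population",
    "evolve",
    "sample_poolseq",
    "simulate_experiment",
    "make_f1_cross",
    "draw_depths",
]


@dataclass(frozen=True)
class SelectionTarget:
    """A selected site: the ``allele`` at ``(chrom, pos)`` has advantage ``s``
    with dominance ``h`` (fitnesses 1, 1+hs, 1+s)."""

    chrom: str
    pos: int
    s: float
    h: float = 0.5
    allele: str | None = None  # default: the minor allele in the founder panel

    def __post_init__(self):
        if self.s <= -1:
            raise ValueError("selection coefficient must be > -1")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated E&R experiment.

    Defaults mirror the emulated experiment: 158 founder haplotypes filling a
    breeding population of Ne = 200 diploids (census ~1,000 flies; drift is
    governed by the effective size, which is what is simulated), three
    replicates sampled at generations 0/15/37/59, with replicate R2's first
    evolved sample taken at generation 23 instead of 15.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"2L": 10_000_000})
    sites_per_chrom: Mapping[str, int] = field(
        default_factory=lambda: {"2L": 5_000})
    n_founders: int = 158
    effective_size: int = 200          # breeding diploids (Ne)
    census_diploids: int = 1_000       # nominal census, reported only
    replicates: Sequence[str] = ("R1", "R2", "R3")
    generations: Sequence[int] = (0, 15, 37, 59)
    #: replicate -> {design generation -> actually sampled generation}
    generation_aliases: Mapping[str, Mapping[int, int]] = field(
        default_factory=lambda: {"R2": {15: 23}})
    selection_targets: Sequence[SelectionTarget] = ()
    recomb_map: RecombMap | None = None

    def __post_init__(self):
        if 2 * self.effective_size < self.n_founders:
            raise ValueError("need 2*Ne >= number of founder haplotypes")
        if list(self.generations) != sorted(self.generations):
            raise ValueError("sampling generations must be sorted")
        for chrom in self.sites_per_chrom:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"sites requested on unknown chromosome {chrom}")
            if self.sites_per_chrom[chrom] > self.chrom_lengths[chrom]:
                raise ValueError(
                    f"more SNPs than positions on chromosome {chrom}")

    def sampled_generation(self, replicate: str, design_gen: int) -> int:
        return self.generation_aliases.get(replicate, {}).get(
            design_gen, design_gen)


class FounderPanel:
    """Founder haplotypes plus a biallelic encoding used by the simulator."""

    def __init__(self, matrix: HaplotypeMatrix, alt: np.ndarray,
                 ref_alleles: np.ndarray, alt_alleles: np.ndarray):
        self.matrix = matrix
        self.alt = np.asarray(alt, dtype=np.int8)        # founders x sites
        self.ref_alleles = np.asarray(ref_alleles, dtype="<U1")
        self.alt_alleles = np.asarray(alt_alleles, dtype="<U1")
        self._site_slices: dict[str, slice] = {}
        sites = matrix.sites
        for chrom in sites["chrom"].unique():
            idx = np.flatnonzero((sites["chrom"] == chrom).to_numpy())
            self._site_slices[chrom] = slice(int(idx[0]), int(idx[-1]) + 1)

    @property
    def sites(self) -> pd.DataFrame:
        return self.matrix.sites

    @property
    def n_founders(self) -> int:
        return self.matrix.n_haplotypes

    def chrom_slice(self, chrom: str) -> slice:
        return self._site_slices[chrom]

    def site_positions(self, chrom: str) -> np.ndarray:
        sl = self.chrom_slice(chrom)
        return self.sites["pos"].to_numpy()[sl]

    def singleton_fraction(self) -> float:
        counts = self.alt.sum(axis=0)
        folded = np.minimum(counts, self.n_founders - counts)
        return float((folded == 1).mean())


def make_founder_panel(config: SimulationConfig,
                       rng: np.random.Generator) -> FounderPanel:
    """Draw a neutral founder panel: every site polymorphic, SFS ~ 1/i.

    Derived-allele counts are drawn from the standard neutral site frequency
    spectrum P(i) proportional to 1/i (i = 1 .. n-1), conditioned on
    polymorphism, and carriers are assigned uniformly at random — the
    coalescent expectation for unlinked sites.
    """
    n = config.n_founders
    if n < 2:
        raise ValueError("need at least 2 founder haplotypes")
    sfs = 1.0 / np.arange(1, n)
    sfs /= sfs.sum()
    ids = [f"f{i + 1}" for i in range(n)]
    all_calls = []
    all_alt = []
    frames = []
    for chrom, n_sites in config.sites_per_chrom.items():
        length = config.chrom_lengths[chrom]
        pos = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1
        counts = rng.choice(np.arange(1, n), size=n_sites, p=sfs)
        # uniform random carrier subset of size counts[j] per site, vectorised:
        # rank the founders by iid uniforms and take the first counts[j]
        ranks = rng.random((n_sites, n)).argsort(axis=1).argsort(axis=1)
        alt = (ranks < counts[:, None]).T.astype(np.int8)
        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
        ref = np.array(NUCLEOTIDES)[ref_idx]
        altn = np.array(NUCLEOTIDES)[alt_idx]
        calls = np.where(alt == 1, altn[None, :], ref[None, :])
        all_calls.append(calls)
        all_alt.append(alt)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref}))
    sites = pd.concat(frames, ignore_index=True)
    calls = np.concatenate(all_calls, axis=1)
    alt = np.concatenate(all_alt, axis=1)
    matrix = HaplotypeMatrix(ids, calls, sites)
    ref_all = sites["ref"].to_numpy(dtype="<U1")
    # alt letter per site = the call of any alt carrier
    alt_all = calls[alt.argmax(axis=0), np.arange(alt.shape[1])].astype("<U1")
    return FounderPanel(matrix, alt, ref_all, alt_all)


# ---------------------------------------------------------------------------
# Population: chromosomes as founder-segment mosaics
# ---------------------------------------------------------------------------

Chromosome = tuple[np.ndarray, np.ndarray]  # (segment starts, founder indices)


class Population:
    """2N chromosome copies per chromosome label; copies 2i, 2i+1 form
    diploid i consistently across labels."""

    def __init__(self, panel: FounderPanel,
                 chroms: dict[str, list[Chromosome]], generation: int = 0):
        self.panel = panel
        self.chroms = chroms
        self.generation = generation
        self.n_diploids = len(next(iter(chroms.values()))) // 2

    def copy(self) -> "Population":
        return Population(self.panel,
                          {k: list(v) for k, v in self.chroms.items()},
                          self.generation)

    # -- truth accessors ----------------------------------------------------

    def founder_per_site(self, chrom: str) -> np.ndarray:
        """Founder index of every chromosome copy at every site
        (shape 2N x n_sites_on_chrom)."""
        pos = self.panel.site_positions(chrom)
        out = np.empty((len(self.chroms[chrom]), pos.size), dtype=np.int32)
        for i, (starts, founders) in enumerate(self.chroms[chrom]):
            idx = np.searchsorted(starts, pos, side="right") - 1
            out[i] = founders[idx]
        return out

    def allele_frequencies(self) -> np.ndarray:
        """Population frequency of the alt allele at every panel site.

        Computed from per-founder segment coverage rather than materialising
        every chromosome, so cost scales with segment count, not 2N x sites.
        """
        freqs = np.empty(self.panel.sites.shape[0], dtype=float)
        for chrom in self.chroms:
            sl = self.panel.chrom_slice(chrom)
            pos = self.panel.site_positions(chrom)
            copies = self.chroms[chrom]
            weight = np.zeros((self.panel.n_founders, pos.size),
                              dtype=np.int32)
            for starts, founders in copies:
                bounds = np.searchsorted(pos, starts, side="left")
                bounds = np.append(bounds, pos.size)
                for k in range(founders.size):
                    if bounds[k] < bounds[k + 1]:
                        weight[founders[k], bounds[k]:bounds[k + 1]] += 1
            alt = self.panel.alt[:, sl]
            freqs[sl] = (weight * alt).sum(axis=0) / len(copies)
        return freqs

    def founder_frequencies(self) -> np.ndarray:
        """Fraction of chromosome copies descending *entirely* from each
        founder (exact haplotype frequencies when recombination is off)."""
        n_f = self.panel.n_founders
        counts = np.zeros(n_f, dtype=float)
        total = 0
        for copies in self.chroms.values():
            for starts, founders in copies:
                total += 1
                if len(founders) == 1:
                    counts[founders[0]] += 1
        return counts / max(total, 1)

    def to_haplotype_matrix(self, copies: Sequence[int] | None = None,
                            prefix: str = "s") -> HaplotypeMatrix:
        """Materialise chromosome copies as full allele calls."""
        n_copies = len(next(iter(self.chroms.values())))
        if copies is None:
            copies = range(n_copies)
        copies = list(copies)
        sites = self.panel.sites
        calls = np.empty((len(copies), len(sites)), dtype="<U1")
        for chrom in self.chroms:
            sl = self.panel.chrom_slice(chrom)
            pos = self.panel.site_positions(chrom)
            site_idx = np.arange(sl.stop - sl.start)
            panel_calls = self.panel.matrix.calls[:, sl]
            for row, c in enumerate(copies):
                starts, founders = self.chroms[chrom][c]
                f = founders[np.searchsorted(starts, pos, side="right") - 1]
                calls[row, sl] = panel_calls[f, site_idx]
        ids = [f"{prefix}{c}" for c in copies]
        return HaplotypeMatrix(ids, calls, sites)


def initialize_population(panel: FounderPanel,
                          config: SimulationConfig,
                          rng: np.random.Generator) -> Population:
    """Fill 2N chromosome sets with founder haplotypes as evenly as possible.

    With k founders and 2N slots each founder appears floor(2N/k) or
    floor(2N/k)+1 times; which founders get the extra copy is random, as is
    the pairing into diploids.  This mimics expanding a modest number of
    isofemale-line chromosomes into the experimental base population.
    """
    n2 = 2 * config.effective_size
    k = panel.n_founders
    base, rem = divmod(n2, k)
    copies = np.full(k, base, dtype=int)
    if rem:
        copies[rng.choice(k, size=rem, replace=False)] += 1
    assignment = np.repeat(np.arange(k), copies)
    rng.shuffle(assignment)
    chroms = {
        chrom: [(np.array([1], dtype=np.int64),
                 np.array([f], dtype=np.int32)) for f in assignment]
        for chrom in config.sites_per_chrom
    }
    return Population(panel, chroms, generation=0)


def _recombine(a: Chromosome, b: Chromosome,
               breaks: np.ndarray) -> Chromosome:
    """Splice two homologs at sorted breakpoints (copy from ``a`` first)."""
    homologs = (a, b)
    out_starts: list[int] = []
    out_founders: list[int] = []
    bounds = [1] + list(breaks)
    for i, lo in enumerate(bounds):
        hi = bounds[i + 1] if i + 1 < len(bounds) else None
        starts, founders = homologs[i % 2]
        j = np.searchsorted(starts, lo, side="right") - 1
        while j < len(starts) and (hi is None or starts[j] < hi):
            seg_start = max(int(starts[j]), lo)
            f = int(founders[j])
            if out_founders and out_founders[-1] == f:
                pass  # merge with previous identical segment
            else:
                out_starts.append(seg_start)
                out_founders.append(f)
            j += 1
    return (np.array(out_starts, dtype=np.int64),
            np.array(out_founders, dtype=np.int32))


def _gamete(pop_chroms: dict[str, list[Chromosome]], parent: int,
            recomb_map: RecombMap | None,
            rng: np.random.Generator) -> dict[str, Chromosome]:
    """One meiotic product: per chromosome, Poisson crossovers placed by the
    genetic map, independent assortment across chromosomes."""
    gamete = {}
    for chrom, copies in pop_chroms.items():
        h1 = copies[2 * parent]
        h2 = copies[2 * parent + 1]
        if rng.random() < 0.5:
            h1, h2 = h2, h1
        n_x = 0
        if recomb_map is not None and chrom in recomb_map.chromosomes:
            morgans = recomb_map.total_cm(chrom) / 100.0
            n_x = rng.poisson(morgans)
        if n_x == 0:
            gamete[chrom] = h1
            continue
        cm = np.sort(rng.uniform(0.0, recomb_map.total_cm(chrom), size=n_x))
        breaks = np.array(sorted({recomb_map.physical_position(chrom, c)
                                  for c in cm}), dtype=np.int64)
        gamete[chrom] = _recombine(h1, h2, breaks)
    return gamete


def _fitness(pop: Population, targets: Sequence[SelectionTarget]) -> np.ndarray:
    panel = pop.panel
    n = pop.n_diploids
    w = np.ones(n, dtype=float)
    lookup = {(c, p): i for i, (c, p) in
              enumerate(zip(panel.sites["chrom"], panel.sites["pos"]))}
    for t in targets:
        site = lookup.get((t.chrom, t.pos))
        if site is None:
            raise ValueError(f"selection target {t.chrom}:{t.pos} not a panel site")
        sl = panel.chrom_slice(t.chrom)
        local = site - sl.start
        if t.allele is None:
            favored = panel.alt[:, site] == 1
            counts = panel.alt[:, site].sum()
            if counts > panel.n_founders / 2:
                favored = ~favored
        else:
            favored = panel.matrix.calls[:, site] == t.allele
        pos = panel.site_positions(t.chrom)[local]
        dosage = np.zeros(n, dtype=int)
        for i, (starts, founders) in enumerate(pop.chroms[t.chrom]):
            f = founders[np.searchsorted(starts, pos, side="right") - 1]
            dosage[i // 2] += int(favored[f])
        w *= np.where(dosage == 2, 1 + t.s,
                      np.where(dosage == 1, 1 + t.h * t.s, 1.0))
    return w


def evolve(population: Population, config: SimulationConfig,
           rng: np.random.Generator,
           sampling_generations: Sequence[int] | None = None,
           ) -> dict[int, Population]:
    """Run discrete Wright-Fisher generations; return snapshots.

    Each generation: viability-weighted multinomial choice of two parents per
    offspring (selfing permitted, as in a standard WF model), one recombinant
    gamete from each parent.  Snapshots are taken at ``sampling_generations``
    (defaults to ``config.generations``); generation 0 is the input state.
    """
    gens = sorted(sampling_generations if sampling_generations is not None
                  else config.generations)
    if not gens:
        raise ValueError("no sampling generations requested")
    pop = population
    snapshots: dict[int, Population] = {}
    if gens[0] == 0:
        snapshots[0] = pop.copy()
    n = config.effective_size
    for gen in range(1, max(gens) + 1):
        if config.selection_targets:
            w = _fitness(pop, config.selection_targets)
            p = w / w.sum()
            mothers = rng.choice(n, size=n, p=p)
            fathers = rng.choice(n, size=n, p=p)
        else:
            mothers = rng.integers(0, n, size=n)
            fathers = rng.integers(0, n, size=n)
        new_chroms: dict[str, list[Chromosome]] = {
            chrom: [None] * (2 * n) for chrom in pop.chroms}
        for i in range(n):
            g_m = _gamete(pop.chroms, int(mothers[i]), config.recomb_map, rng)
            g_f = _gamete(pop.chroms, int(fathers[i]), config.recomb_map, rng)
            for chrom in pop.chroms:
                new_chroms[chrom][2 * i] = g_m[chrom]
                new_chroms[chrom][2 * i + 1] = g_f[chrom]
        pop = Population(pop.panel, new_chroms, generation=gen)
        if gen in gens:
            snapshots[gen] = pop.copy()
    return snapshots


# ---------------------------------------------------------------------------
# Sequencing models
# ---------------------------------------------------------------------------


def draw_depths(depth_model, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    """Resolve a coverage model to per-site integer depths.

    Accepted models: a fixed integer depth; a per-site depth vector (copied
    from real data, for coverage matching); or ``("nbinom", mean, k)`` for
    negative-binomially overdispersed coverage with dispersion ``k``.
    """
    if isinstance(depth_model, (int, np.integer)):
        return np.full(n_sites, int(depth_model), dtype=np.int64)
    if isinstance(depth_model, tuple) and depth_model[0] == "nbinom":
        _, mean, k = depth_model
        p = k / (k + mean)
        return rng.negative_binomial(k, p, size=n_sites).astype(np.int64)
    depths = np.asarray(depth_model, dtype=np.int64)
    if depths.shape != (n_sites,):
        raise ValueError("depth vector length does not match number of sites")
    return depths


def sample_poolseq(snapshots: Mapping[tuple[str, str], Population] |
                   Sequence[tuple[str, int, Population]],
                   depth_model, rng: np.random.Generator,
                   design_generations: Mapping[tuple[str, str], int] | None = None,
                   ) -> PoolCounts:
    """Binomial Pool-Seq read sampling from population allele frequencies.

    ``snapshots`` is a sequence of ``(replicate, design_generation,
    Population)``; one sync sample column is emitted per entry, with read
    count of the alt allele ~ Binomial(depth, population alt frequency).
    Sites with zero depth are emitted with coverage 0.
    """
    if isinstance(snapshots, Mapping):
        snapshots = [(rep, gen, p) for (rep, gen), p in snapshots.items()]
    first_pop = snapshots[0][2]
    panel = first_pop.panel
    sites = panel.sites
    n_sites = len(sites)
    counts = np.zeros((n_sites, len(snapshots), 6), dtype=np.int64)
    design = []
    for s, (rep, gen, pop) in enumerate(snapshots):
        freqs = pop.allele_frequencies()
        depths = draw_depths(depth_model, n_sites, rng)
        alt_reads = rng.binomial(depths, freqs)
        ref_reads = depths - alt_reads
        for letter, reads in ((panel.ref_alleles, ref_reads),
                              (panel.alt_alleles, alt_reads)):
            for b, nuc in enumerate(("A", "T", "C", "G")):
                mask = letter == nuc
                counts[mask, s, b] += reads[mask]
        design.append((rep, gen, f"F{gen}"))
    return PoolCounts(sites.copy(), counts, design)


def simulate_experiment(config: SimulationConfig, rng: np.random.Generator,
                        depth_model=80, panel: FounderPanel | None = None,
                        ) -> tuple[FounderPanel, dict, PoolCounts]:
    """One complete replicated E&R experiment: panel, evolution, Pool-Seq.

    Each replicate starts from an independent random expansion of the same
    founder panel and evolves independently; samples are taken at the design
    generations (respecting per-replicate aliases such as F23 filling the
    F15 slot).  A pre-built ``panel`` may be supplied (e.g. when selection
    targets refer to its sites).  Returns ``(panel, snapshots, pool)`` where
    ``snapshots`` maps ``(replicate, design_generation)`` to the sampled
    :class:`Population`.
    """
    if panel is None:
        panel = make_founder_panel(config, rng)
    snapshots: dict[tuple[str, int], Population] = {}
    samples = []
    for rep in config.replicates:
        pop = initialize_population(panel, config, rng)
        gens = [config.sampled_generation(rep, g) for g in config.generations]
        snaps = evolve(pop, config, rng, sampling_generations=gens)
        for design_gen, actual in zip(config.generations, gens):
            snapshots[(rep, design_gen)] = snaps[actual]
            samples.append((rep, design_gen, snaps[actual]))
    pool = sample_poolseq(samples, depth_model, rng)
    return panel, snapshots, pool


def make_f1_cross(founder_calls: np.ndarray, reference_calls: np.ndarray,
                  sites: pd.DataFrame, depth_model, error_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Simulate sequencing an F1 of founder x reference-strain cross.

    Returns per-site A/C/G/T read counts (shape n_sites x 4, column order
    A, C, G, T).  At sites where the two parental alleles differ the F1 is
    heterozygous, so paternal-allele reads ~ Binomial(depth, 0.5); sequencing
    error flips a read to the other parental allele with probability
    ``error_rate`` (symmetric biallelic error model).
    """
    founder_calls = np.asarray(founder_calls, dtype="<U1")
    reference_calls = np.asarray(reference_calls, dtype="<U1")
    if founder_calls.shape != reference_calls.shape:
        raise ValueError("parental haplotypes must cover the same sites")
    n_sites = founder_calls.size
    depths = draw_depths(depth_model, n_sites, rng)
    het = founder_calls != reference_calls
    p_true = np.where(het, 0.5, 0.0)  # prob. a read shows the founder allele
    p_read = p_true * (1 - error_rate) + (1 - p_true) * error_rate
    founder_reads = rng.binomial(depths, p_read)
    ref_reads = depths - founder_reads
    counts = np.zeros((n_sites, 4), dtype=np.int64)
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    for letters, reads in ((reference_calls, ref_reads),
                           (founder_calls, founder_reads)):
        for nuc, col in order.items():
            mask = letters == nuc
            counts[mask, col] += reads[mask]
    return counts
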
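# Methods

This note documents the models, estimators, numerical conventions and design
choices behind `erhaplo`, and what the simulation-based tests do and do not
demonstrate about real data.

## Coordinates and formats

All coordinates are 1-based inclusive. BED input (0-based half-open) is
converted on read; GFF3 is taken as is. Pool-Seq counts use the PoPoolation2
"sync" layout (`A:T:C:G:N:del` per sample); allele frequencies are computed
over A/C/G/T only — the N and del columns are preserved through I/O but never
enter frequency arithmetic. The sample design maps each sync column to a
replicate, a generation and a *timepoint label*; the label lets a sample
taken at a deviating generation fill a design slot (the emulated experiment
sampled replicate R2 at generation 23 for its "F15" slot).

The recombination map is piecewise-constant cM/Mb on windows (typically
100 kb) that must tile each chromosome. Genetic distance is the exact
integral of the rate over the physical span; queries are permitted up to one
bp past the last window (the right edge of the tiled interval). A block's
"local rate" is reported as the unweighted mean of the rates of all windows
the block touches, the convention used in the emulated study's block table.

## Haplotype calling from F1 crosses

At a site where a homozygous-reference mother and an unknown father differ,
the F1 daughter is heterozygous, so the paternal (alternate) allele should
appear in half the reads. The caller accepts an alternate allele when its
count lies in the central acceptance region of Binomial(n, ½):
`lo = min{k : CDF(k) ≥ (1−level)/2}`, `hi = n − lo`, level 0.90 by default,
computed exactly rather than by normal approximation because the relevant
depths are ~10×. Counts above `hi` are called missing, not alternate — an F1
of a homozygous reference mother cannot be homozygous non-reference, so an
alternate excess indicates a mapping or duplication artefact. Sites are
called only when monomorphic in the resequenced reference pool (residual
heterozygosity guard), with depth ≥ 10 and not above the library's 98th
coverage percentile (duplicated-region guard), and with at most two observed
alleles in the individual.

Two properties of the exact region are worth knowing:

* its width alternates by ±1 with the parity of n, so "width is
  non-decreasing in n" holds within each parity class only;
* its realised coverage oscillates (97.9% at n = 10, 90.1% at n = 30), so
  the empirical false-*negative* rate of downsampled calls is **not**
  monotone in target depth; the error-driven false-positive rate is (a
  spurious alternate call needs ≥ lo(n) error reads of one allele).

The empirical FP/FN estimator downsamples high-coverage libraries (mean
depth > 60) to a target depth without replacement and scores discordance
against the full-depth calls over sites called in both.

## LD

r² is the squared correlation of 0/1 allele indicators across haplotypes,
computed per pair on the haplotypes called at *both* sites; a pair is
eligible only with ≥ 24 jointly called haplotypes (the sequenced-panel
convention) and both sites still polymorphic after intersection. Ineligible
pairs are excluded, never scored 0, and empty bins are reported missing.
For unlinked loci E[r̂²] ≈ 1/n — with 26 haplotypes a floor of ~0.04 — which
is what the background (inter-chromosomal) estimate measures. Long-range
bins are sampled (seeded) up to a pair cap rather than enumerated, since
exhaustive enumeration at 15 Mb anchors is quadratic and adds nothing; short
range (≤ 1 kb) defaults to exhaustive. Changes in LD use matched pairs
polymorphic and eligible in both populations; pairs monomorphic in the
evolved sample are excluded and counted, rather than assigned Δr² = −r²,
which would create an artificial mass at the lower bound.

## Inversion typing

A haplotype is an inversion carrier when ≥ 80% of its non-missing
inversion-specific markers bear the inverted-state allele, with at least 10
markers called (untyped haplotypes leave the denominator). Empirically
carriers separate cleanly, so the threshold only guards degenerate inputs.
Frequencies are reported at two decimals and frequency changes are computed
from the rounded values, matching how such tables are conventionally printed.

## CMH scan and thresholds

Each biallelic SNP contributes one 2×2 allele × timepoint table per
replicate; the CMH statistic sums hypergeometric deviations and variances
across strata (no continuity correction by default — at K = 1 the statistic
is then exactly the fixed-margins randomization χ², (n−1)/n × Pearson).
Strata with a zero margin are dropped. SNPs are ranked by p (ties: statistic
desc, then position). The block-detection threshold for a timepoint is the
minimum, over the top-ranked candidates, of the mean across replicates of
the **rising-allele** frequency change (the allele with positive mean
change; an absolute-change variant is available by flag).

## Haplotype-block detection

Singletons — sites where exactly one called haplotype carries the minor
allele, among ≥ 24 called — partition cleanly among haplotypes and act as
private markers. Per haplotype and chromosome, windows of 20 consecutive
singletons advance by 5 (overlap 15); trailing incomplete windows are
dropped. Each window's 20 marker frequencies per (timepoint × replicate)
cell enter a two-factor fixed-effects ANOVA; the residual mean square on
N − (#timepoints × #replicates) df feeds Tukey-HSD family-wise 95% intervals
on the timepoint means (studentized range with the number of timepoint
levels), and the lower bound of (mean_t − mean_F0) is the window's estimate
for timepoint t. The 20 marker frequencies are the observational unit within
each cell — the only reading that gives the two-factor model its degrees of
freedom. With zero residual variance the interval collapses to the point
estimate. A timepoint whose replicate set is incomplete for a window is
skipped for that window. A fast numpy path computes the same algebra as the
pandas reference implementation; the suite asserts their equality at 1e-10.

Windows passing any per-timepoint threshold are merged transitively when
they overlap or their nearest edges are < 2 cM apart (strict); block span is
the outermost member singleton positions. Raising a threshold monotonically
shrinks the passing-window set and the covered genome, but **not**
necessarily the block count — removing a middle window can split a merged
block in two.

## Block tracking, integrity, enrichment

Haplotype frequency per pooled sample is the median marker frequency in
non-overlapping windows of 20 markers; a trailing remainder folds into the
last window so short blocks stay trackable; even-count medians are the mean
of the central pair; a block trajectory averages its window medians (a
block-wide median is available by flag). The median is what buys robustness
against markers that are not truly private (shared with unsequenced
founders) — the dominant error when only ~18–20% of founders are known.

Integrity: allele-sharing distance = 1 − shared/jointly-called over block
SNPs (haplotypes with < 20% of block SNPs called are excluded). Evolved
haplotypes are classified intact (distance ≤ ε, default 0.005),
end-recombined (mismatches confined to the terminal 10% of the span),
recombined (interior mismatches, distance < 0.5) or absent; average-linkage
trees are emitted as Newick. The ε default is a floor of order twice the
empirical calling FP rate.

Enrichment compares CMH ranks of a block's singletons against all non-block
singletons of the same chromosome (two-sided Mann–Whitney U, asymptotic with
tie correction), BH-adjusted across blocks × comparisons, plus a linear
rank ~ timepoint trend per block, and the fraction of top candidates falling
in block spans. Candidate genes are those whose (optionally padded) interval
contains ≥ 1 block-allele SNP at base frequency < 0.1.

## The simulator

Because the experiment uses standing variation only, no mutation is
simulated; every chromosome is a mosaic of founder segments, which is also
the internal representation (segment lists), making whole-genome simulation
cheap and giving exact haplotype-frequency truth. Founder panels draw
derived-allele counts from the neutral SFS (P(i) ∝ 1/i conditioned on
polymorphism) with uniformly random carriers; the suite checks the singleton
fraction against msprime as an independent coalescent oracle. Populations
are initialised by replicating founders as evenly as possible into 2N
chromosome sets (which founders get an extra copy is random), mimicking the
expansion of isofemale-line chromosomes. Generations are discrete
Wright–Fisher: two parents per offspring drawn ∝ viability (1, 1+hs, 1+s
per selected genotype, multiplicative across loci; selfing permitted), one
gamete per parent with Poisson(map length in Morgans) crossovers placed by
inverting the cumulative genetic map (no interference), independent
assortment across chromosomes. Drift is governed by the simulated N; the
census size of the emulated experiment (~1,000) is carried in the config for
reporting only, and simulations default to the drift-effective sizes
(150–250) except where noted. Pool-Seq sampling is binomial per site
(with replacement) at fixed, per-site, or negative-binomial depths; F1
libraries are binomial at p = ½ for heterozygous sites with a symmetric
biallelic error model.

## Standard desk-scale experiments

The reference experiments in `erhaplo.experiments` fix the package's study
conditions at sizes that run in seconds to minutes (the full-scale analysis
had ~1.45M SNPs genome-wide):

* **Background LD**: 26 haplotypes, 5 chromosomes × 2,000 unlinked SNPs,
  100,000 random cross-chromosome pairs. Expected mean r² ≈ 1/26 ≈ 0.04.
* **Tracking accuracy**: 158 founders on one 20-Mb arm with 16,000 SNPs,
  neutral evolution at Ne = 200 without recombination over 60 generations,
  one replicate sampled at generations 0/20/40/60, Pool-Seq at 80×; markers
  re-derived from a random known subset (29, and fractions 0.2/0.5/0.75 as
  nested subsets). With 29 known founders the mean absolute deviation is
  ~0.006–0.008. **Known limitation**: at 80× the deviation reaches the
  read-count quantisation floor (~0.002) by 50% known founders, so the
  50% → 75% step is a statistical tie (paired-seed mean difference
  ~10⁻⁵ ± 2·10⁻⁴); reported full-scale gains below that floor imply an
  evaluation at effectively higher coverage. Accuracy does improve clearly
  from 18–20% to 50% known.
* **Neutral control**: five whole-pipeline runs (2 chromosomes × 50,000
  SNPs; Ne = 250, 250, 250, 150, 150; three replicates; thresholds
  re-derived per run from that run's own CMH candidates). The candidate
  list is scaled to preserve the full-scale *fraction* (2,000/1.45M ≈
  0.14%, i.e. top 138 of 100,000): the threshold is a tail quantile of the
  drift distribution, so its meaning lives in the fraction, not the
  absolute count — a literal top-2,000 of 100,000 SNPs (top 2%) sits below
  the neutral singleton-window maxima and would call spurious blocks in
  every run. At the preserved fraction, at most one of five neutral runs
  calls a block.
* **Planted sweep**: 113 founders, one 12-Mb chromosome with 20,000 SNPs,
  recombination off, one founder's singleton allele given s = 0.3 (h = 0.5),
  census-like N = 500 diploids so the carrier starts from ~9 copies
  (frequency 1/113); at drift-sized N the sweep would simply go extinct in
  a large fraction of replicates, which tests establishment, not detection.
  The scan uses the full-scale study's fixed thresholds
  (0.1489/0.1851/0.2771) as inputs: with recombination off, every minority
  allele of the sweeping haplotype rises with it, so a threshold re-derived
  from the same run's candidates would equal the sweep's own rise and no
  window could exceed it. Detected blocks cover the carrier's entire
  passing-window span.

What these tests show — and what they do not: the generator reproduces the
designed conditions (founder counts, Ne, sampling schedule, coverage) with
idealised reads (no mapping error, no repeat masking, no indel artefacts,
uniform coverage models) and unstructured neutral founders (no inversions,
no population structure, no LD among founders beyond shared descent).
Passing therefore validates the estimators and the pipeline's logic against
exact truth under those conditions; it does not certify performance on real
libraries with alignment artefacts or on founder panels with strong internal
structure.

## Numerical conventions and edge cases

* Seeds: every stochastic routine takes a `numpy.random.Generator` or an
  integer seed expanded through `SeedSequence`; seeded runs are
  bit-reproducible.
* Sites with both alleles at count 1 (possible only in tiny panels) have no
  defined minor allele and are not singletons of anyone.
* Frequencies at zero-coverage samples are NaN and propagate as missing;
  windows never treat missing as zero.
* The studentized-range quantile is cached on (level, k, df): it is the
  scan's only expensive scalar and identical across windows.
* `physical_position` (inverse map lookup) places a genetic position inside
  a zero-rate window at the window start; crossover breakpoints therefore
  never land strictly inside zero-rate windows, as they should.
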
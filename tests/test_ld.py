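import numpy as np
import pandas as pd
import pytest

from erhaplo.io import RecombMap
from erhaplo.ld import (background_ld, ld_change_by_initial,
                        ld_decay_profile, pair_r2, r_squared,
                        stratified_ld_change)
from erhaplo.sim import SimulationConfig, evolve, initialize_population, \
    make_founder_panel

from conftest import make_matrix


def _col(matrix, j):
    return matrix.calls[:, j]


class TestRSquared:
    def test_perfect_coupling(self):
        m = make_matrix(["AC"] * 4 + ["GT"] * 4)
        pair = r_squared(_col(m, 0), _col(m, 1), min_haplotypes=8)
        assert pair.r2 == pytest.approx(1.0)

    def test_equilibrium(self):
        m = make_matrix(["AC", "AT", "GC", "GT"] * 2)
        pair = r_squared(_col(m, 0), _col(m, 1), min_haplotypes=8)
        assert pair.r2 == pytest.approx(0.0)

    def test_intermediate_value(self):
        rows = ["AC"] * 3 + ["AT"] + ["GC"] + ["GT"] * 3
        m = make_matrix(rows)
        pair = r_squared(_col(m, 0), _col(m, 1), min_haplotypes=8)
        assert abs(pair.D) == pytest.approx(0.125)
        assert pair.r2 == pytest.approx(0.25)

    def test_too_few_joint_haplotypes_excluded(self):
        m = make_matrix(["AC"] * 4 + ["GT"] * 4)
        assert r_squared(_col(m, 0), _col(m, 1), min_haplotypes=24) is None

    def test_monomorphic_after_intersection_excluded(self):
        rows = ["AC", "AT", "NC", "NT"] * 2  # site0: only A among joint
        m = make_matrix(rows)
        assert r_squared(_col(m, 0), _col(m, 1), min_haplotypes=4) is None

    def test_label_swap_invariance(self, rng):
        for _ in range(20):
            a = rng.choice(["A", "G"], size=30)
            b = rng.choice(["C", "T"], size=30)
            p1 = r_squared(a, b, min_haplotypes=10)
            swap = np.where(a == "A", "G", "A")
            p2 = r_squared(swap, b, min_haplotypes=10)
            if p1 is not None:
                assert p1.r2 == pytest.approx(p2.r2, abs=1e-12)

    def test_equals_squared_indicator_correlation(self, rng):
        """Oracle: r2 == squared Pearson correlation of 0/1 indicators."""
        checked = 0
        for _ in range(200):
            n = rng.integers(8, 40)
            a = rng.choice(["A", "G", "N"], size=n, p=[0.45, 0.45, 0.1])
            b = rng.choice(["C", "T", "N"], size=n, p=[0.45, 0.45, 0.1])
            pair = r_squared(a, b, min_haplotypes=5)
            if pair is None:
                continue
            mask = (a != "N") & (b != "N")
            x = (a[mask] == "A").astype(float)
            y = (b[mask] == "C").astype(float)
            rho = np.corrcoef(x, y)[0, 1]
            assert pair.r2 == pytest.approx(rho ** 2, abs=1e-10)
            checked += 1
        assert checked > 50

    def test_vectorised_kernel_matches_scalar(self, rng):
        m = make_matrix([
            "".join(rng.choice(["A", "G", "N"], size=40, p=[.4, .4, .2]))
            for _ in range(30)])
        codes, biallelic = m.indicator_matrix()
        ia = np.flatnonzero(biallelic)[:10]
        ja = np.flatnonzero(biallelic)[10:20]
        r2, elig = pair_r2(codes, ia, ja, min_haplotypes=5)
        for k, (i, j) in enumerate(zip(ia, ja)):
            scalar = r_squared(m.calls[:, i], m.calls[:, j], min_haplotypes=5)
            if scalar is None:
                assert not elig[k]
            else:
                assert r2[k] == pytest.approx(scalar.r2, abs=1e-12)


def _independent_panel(rng, n_hap=26, n_chrom=2, snps=400):
    cfg = SimulationConfig(
        chrom_lengths={f"c{i}": 10_000_000 for i in range(n_chrom)},
        sites_per_chrom={f"c{i}": snps for i in range(n_chrom)},
        n_founders=n_hap, effective_size=n_hap, generations=(0,))
    return make_founder_panel(cfg, rng).matrix


class TestProfiles:
    def test_duplicated_sites_give_r2_one_everywhere(self):
        pattern = "AATAA" + "T" * 21
        m = make_matrix([c * 30 for c in pattern],
                        positions=np.arange(1, 31) * 1000)
        prof = ld_decay_profile(m, [(1, 2000), (5000, 20_000)],
                                min_haplotypes=24)
        means = prof["mean_r2"].dropna().to_numpy()
        assert means.size and np.allclose(means, 1.0)

    def test_empty_bin_reported_missing_not_zero(self):
        m = make_matrix(["AT" * 5, "TA" * 5], positions=np.arange(1, 11) * 10)
        prof = ld_decay_profile(m, [(10_000, 20_000)], min_haplotypes=2)
        assert prof["n_pairs"].iloc[0] == 0
        assert np.isnan(prof["mean_r2"].iloc[0])

    def test_independent_sites_mean_near_one_over_n(self, rng):
        m = _independent_panel(rng, n_hap=26, n_chrom=1, snps=1500)
        prof = ld_decay_profile(m, [(1, 10_000_000)], min_haplotypes=24,
                                max_pairs_per_bin=30_000, rng=rng)
        assert prof["mean_r2"].iloc[0] == pytest.approx(1 / 26, abs=0.012)

    def test_sampled_cap_matches_full_enumeration(self, rng):
        m = _independent_panel(rng, n_hap=30, n_chrom=1, snps=300)
        full = ld_decay_profile(m, [(1, 10_000_000)], min_haplotypes=24,
                                max_pairs_per_bin=None)
        sub = ld_decay_profile(m, [(1, 10_000_000)], min_haplotypes=24,
                               max_pairs_per_bin=5_000, rng=rng)
        # SE of the subsample mean, bounded by r2 in [0,1]
        se = 0.5 / np.sqrt(5_000)
        assert sub["mean_r2"].iloc[0] == pytest.approx(
            full["mean_r2"].iloc[0], abs=2 * se + 0.01)


class TestBackgroundLd:
    def test_matches_sample_size_floor(self, rng):
        m = _independent_panel(rng, n_hap=26, n_chrom=3, snps=700)
        bg = background_ld(m, n_per_chrom=500, max_pairs=30_000, rng=rng)
        assert bg == pytest.approx(1 / 26, abs=0.01)

    def test_shrinks_with_many_haplotypes(self, rng):
        m = _independent_panel(rng, n_hap=200, n_chrom=2, snps=400)
        bg = background_ld(m, n_per_chrom=300, max_pairs=20_000, rng=rng)
        assert bg < 0.012

    def test_seeded_reproducibility(self, rng):
        m = _independent_panel(rng, n_hap=26, n_chrom=2, snps=300)
        b1 = background_ld(m, n_per_chrom=200, max_pairs=5_000,
                           rng=np.random.default_rng(3))
        b2 = background_ld(m, n_per_chrom=200, max_pairs=5_000,
                           rng=np.random.default_rng(3))
        assert b1 == b2

    def test_single_chromosome_rejected(self, rng):
        m = _independent_panel(rng, n_chrom=1)
        with pytest.raises(ValueError):
            background_ld(m, rng=rng)


class TestLdChange:
    def test_identical_matrices_give_zero_delta(self, rng):
        m = _independent_panel(rng, n_hap=26, n_chrom=1, snps=200)
        out = ld_change_by_initial(m, m, [(1, 1_000_000)],
                                   min_haplotypes=24, rng=rng)
        got = out.dropna(subset=["median"])
        assert (got["median"].abs() < 1e-12).all()

    def test_delta_respects_bounds(self, rng):
        base = _independent_panel(rng, n_hap=26, n_chrom=1, snps=200)
        cfg = SimulationConfig(chrom_lengths={"c0": 10_000_000},
                               sites_per_chrom={"c0": 200},
                               n_founders=26, effective_size=50,
                               generations=(0, 30))
        panel = make_founder_panel(cfg, np.random.default_rng(5))
        pop = initialize_population(panel, cfg, np.random.default_rng(6))
        snaps = evolve(pop, cfg, np.random.default_rng(7))
        evolved = snaps[30].to_haplotype_matrix(copies=range(26))
        evolved.ids = panel.matrix.ids  # matched site tables
        base_m = panel.matrix
        codes_b, bi_b = base_m.indicator_matrix()
        codes_e, bi_e = evolved.indicator_matrix()
        ok = np.flatnonzero(bi_b & bi_e)
        ia, ja = ok[:-1], ok[1:]
        r2b, eb = pair_r2(codes_b, ia, ja, 24)
        r2e, ee = pair_r2(codes_e, ia, ja, 24)
        both = eb & ee
        delta = r2e[both] - r2b[both]
        assert (delta >= -r2b[both] - 1e-12).all()
        assert (delta <= 1 - r2b[both] + 1e-12).all()

    def test_drift_increases_short_range_ld_with_initial_ld(self):
        """Bottleneck reproduces the qualitative pattern: tightly linked
        pairs with substantial initial LD show a positive median change,
        while far-separated pairs with high initial LD decay."""
        seed = np.random.default_rng(42)
        L = 16_000_000
        cfg = SimulationConfig(chrom_lengths={"3R": L},
                               sites_per_chrom={"3R": 9000},
                               n_founders=58, effective_size=200,
                               generations=(0, 67),
                               recomb_map=RecombMap.uniform({"3R": L}, 2.0))
        panel = make_founder_panel(cfg, seed)
        pop = initialize_population(panel, cfg, seed)
        snaps = evolve(pop, cfg, seed)
        base = snaps[0].to_haplotype_matrix(copies=range(29), prefix="b")
        evolved = snaps[67].to_haplotype_matrix(copies=range(29), prefix="e")
        out = ld_change_by_initial(
            base, evolved,
            distance_classes=[(1, 1000), (14_000_000, 15_000_000)],
            initial_bins=(0, 0.3, 0.7, 1.0001),
            min_haplotypes=24, max_pairs_per_class=30_000, rng=seed)
        short = out[(out.dist_lo == 1) & (out.initial_lo == 0.3)]
        far = out[(out.dist_lo == 14_000_000) & (out.initial_lo == 0.7)]
        assert short["median"].iloc[0] > 0
        if far["n_pairs"].iloc[0] >= 20:
            assert far["median"].iloc[0] <= 0


class TestStratified:
    def test_single_category_equals_unstratified(self, rng):
        m = _independent_panel(rng, n_hap=26, n_chrom=1, snps=150)
        cats = pd.DataFrame({"label": ["high_recombination"],
                             "chrom": ["c0"], "start": [1],
                             "end": [10_000_000]})
        strat = stratified_ld_change(m, m, cats, [(1, 1_000_000)],
                                     min_haplotypes=24,
                                     max_pairs_per_bin=None)
        plain = ld_decay_profile(m, [(1, 1_000_000)], min_haplotypes=24,
                                 max_pairs_per_bin=None)
        assert strat["mean_r2_base"].iloc[0] == pytest.approx(
            plain["mean_r2"].iloc[0], abs=1e-12)

    def test_category_without_pairs_missing_not_zero(self, rng):
        m = _independent_panel(rng, n_hap=26, n_chrom=1, snps=150)
        cats = pd.DataFrame({
            "label": ["inversion", "high_recombination"],
            "chrom": ["c0", "c0"], "start": [1, 2],
            "end": [1, 10_000_000]})  # inversion interval covers no site
        strat = stratified_ld_change(m, m, cats, [(1, 1_000_000)],
                                     min_haplotypes=24,
                                     max_pairs_per_bin=None)
        inv = strat[strat.category == "inversion"]
        assert (inv["n_pairs"] == 0).all()
        assert inv["mean_r2_base"].isna().all()
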
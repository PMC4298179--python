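import numpy as np
import pandas as pd
import pytest
from scipy import stats

from erhaplo.blocks import find_singletons
from erhaplo.io import PoolCounts
from erhaplo.sim import SimulationConfig, evolve, initialize_population, \
    make_founder_panel, sample_poolseq
from erhaplo.tracking import (allele_sharing_distance, block_integrity,
                              candidate_genes, enrichment,
                              estimate_block_frequency,
                              evaluate_tracking_accuracy, linkage_newick,
                              marker_window_medians, track_haplotypes)

from conftest import make_pool


class TestMedianEstimator:
    def test_constant_markers(self):
        f = np.full((20, 1), 0.3)
        assert estimate_block_frequency(f)[0] == pytest.approx(0.3)

    def test_robust_to_one_contaminated_marker(self):
        f = np.array([0.2] * 19 + [0.95])[:, None]
        assert estimate_block_frequency(f)[0] == pytest.approx(0.2)

    def test_even_count_median_is_mean_of_central_pair(self):
        f = np.array([0.1] * 10 + [0.9] * 10)[:, None]
        assert estimate_block_frequency(f)[0] == pytest.approx(0.5)

    def test_trailing_markers_fold_into_last_window(self):
        f = np.arange(45, dtype=float)[:, None] / 100
        med = marker_window_medians(f, window=20)
        assert med.shape[0] == 2  # windows of 20 and 25
        assert med[1, 0] == pytest.approx(np.median(f[20:, 0]))

    def test_permutation_invariance_within_window(self, rng):
        f = rng.uniform(0, 1, size=(20, 3))
        shuffled = f[rng.permutation(20)]
        np.testing.assert_allclose(estimate_block_frequency(f),
                                   estimate_block_frequency(shuffled))

    def test_monotone_in_marker_frequencies(self, rng):
        f = rng.uniform(0, 0.5, size=(40, 2))
        base = estimate_block_frequency(f)
        raised = estimate_block_frequency(f + 0.1)
        assert (raised >= base).all()

    def test_blockwide_median_flag(self):
        f = np.array([0.1] * 30 + [0.9] * 10)[:, None]
        est = estimate_block_frequency(f, method="blockwide_median")
        assert est[0] == pytest.approx(0.1)


class TestTrackingAccuracy:
    def _sim(self, seed, sites=6000, gens=(0, 20, 40, 60)):
        rng = np.random.default_rng(seed)
        cfg = SimulationConfig(chrom_lengths={"2L": 10_000_000},
                               sites_per_chrom={"2L": sites},
                               n_founders=158, effective_size=200,
                               generations=gens, recomb_map=None)
        panel = make_founder_panel(cfg, rng)
        pop = initialize_population(panel, cfg, rng)
        snaps = evolve(pop, cfg, rng)
        return rng, panel, snaps

    def test_exact_counts_and_full_panel_give_zero_deviation(self):
        rng, panel, snaps = self._sim(3, sites=3000, gens=(0,))
        # exact counts: depth 400 = 2N, so counts = freq * depth exactly
        freqs = snaps[0].allele_frequencies()
        counts = np.zeros((len(freqs), 1, 6), dtype=np.int64)
        order = {"A": 0, "T": 1, "C": 2, "G": 3}
        for i, (f, a, r) in enumerate(zip(freqs, panel.alt_alleles,
                                          panel.ref_alleles)):
            counts[i, 0, order[a]] = round(f * 400)
            counts[i, 0, order[r]] = 400 - round(f * 400)
        pool = PoolCounts(panel.sites.copy(), counts, [("R1", 0)])
        res = evaluate_tracking_accuracy(panel, {0: snaps[0]}, pool,
                                         panel.matrix.ids)
        assert res["mad"] == pytest.approx(0.0, abs=1e-12)

    def test_deviation_decreases_from_20_to_50_percent_known(self):
        mads = {0.2: [], 0.5: []}
        for seed in (11, 12):
            rng, panel, snaps = self._sim(seed)
            pool = sample_poolseq(
                [("R1", g, snaps[g]) for g in (0, 20, 40, 60)], 80, rng)
            order = list(rng.permutation(panel.matrix.ids))
            for f in (0.2, 0.5):
                res = evaluate_tracking_accuracy(
                    panel, snaps, pool, order[:int(f * 158)])
                mads[f].append(res["mad"])
        assert np.mean(mads[0.5]) < np.mean(mads[0.2])


class TestAlleleSharing:
    def test_identical_zero(self):
        a = np.array(list("ACGT" * 25))
        assert allele_sharing_distance(a, a) == 0.0

    def test_quarter_differing(self):
        a = np.array(["A"] * 100)
        b = a.copy()
        b[:25] = "G"
        assert allele_sharing_distance(a, b) == pytest.approx(0.25)

    def test_all_differing_one(self):
        a = np.array(["A"] * 50)
        b = np.array(["T"] * 50)
        assert allele_sharing_distance(a, b) == 1.0

    def test_sparse_calls_excluded(self):
        a = np.array(["A"] * 100)
        b = np.array(["N"] * 90 + ["A"] * 10)
        assert np.isnan(allele_sharing_distance(a, b,
                                                min_called_fraction=0.2))

    def test_triangle_inequality_on_complete_data(self, rng):
        for _ in range(50):
            x, y, z = (rng.choice(["A", "T"], size=60) for _ in range(3))
            dxy = allele_sharing_distance(x, y, 0)
            dyz = allele_sharing_distance(y, z, 0)
            dxz = allele_sharing_distance(x, z, 0)
            assert dxz <= dxy + dyz + 1e-12


class TestIntegrity:
    def _evolved(self, rows, positions):
        from conftest import make_matrix
        return make_matrix(rows, ids=[f"e{i + 1}" for i in range(len(rows))],
                           positions=positions)

    def test_classification(self):
        n = 100
        positions = np.arange(1, n + 1) * 1000
        base = np.array(["A"] * n)
        intact = "A" * n
        end_rec = "T" * 8 + "A" * 92            # mismatches in first 8%
        interior = "A" * 40 + "T" * 10 + "A" * 50
        absent = "T" * n
        ev = self._evolved([intact, end_rec, interior, absent], positions)
        out = block_integrity(base, ev, positions)
        got = dict(zip(out["haplotypes"]["haplotype"],
                       out["haplotypes"]["class"]))
        assert got == {"e1": "intact", "e2": "end_recombined",
                       "e3": "recombined", "e4": "absent"}
        assert out["status"] == "persistent"
        assert out["newick"].count("e1") == 1

    def test_sparsely_called_copy_excluded(self):
        n = 50
        positions = np.arange(1, n + 1) * 1000
        base = np.array(["A"] * n)
        sparse = "N" * 45 + "A" * 5
        ev = self._evolved([sparse, "A" * n], positions)
        out = block_integrity(base, ev, positions)
        assert out["haplotypes"]["class"].tolist() == ["excluded", "intact"]

    def test_absent_block_status(self):
        n = 50
        positions = np.arange(1, n + 1) * 1000
        base = np.array(["A"] * n)
        ev = self._evolved(["T" * n, "T" * n], positions)
        out = block_integrity(base, ev, positions)
        assert out["status"] == "absent"

    def test_zero_recombination_descendants_intact(self, rng):
        cfg = SimulationConfig(chrom_lengths={"2L": 1_000_000},
                               sites_per_chrom={"2L": 400},
                               n_founders=20, effective_size=40,
                               generations=(0, 25), recomb_map=None)
        panel = make_founder_panel(cfg, rng)
        pop = initialize_population(panel, cfg, rng)
        snaps = evolve(pop, cfg, rng)
        final = snaps[25]
        # find a founder with surviving whole copies
        ff = final.founder_frequencies()
        founder = int(np.argmax(ff))
        carriers = [i for i, (s, f) in enumerate(final.chroms["2L"])
                    if len(f) == 1 and f[0] == founder]
        ev = final.to_haplotype_matrix(copies=carriers[:5])
        base_calls = panel.matrix.calls[founder]
        out = block_integrity(base_calls, ev,
                              panel.sites["pos"].to_numpy())
        assert (out["haplotypes"]["class"] == "intact").all()

    def test_linkage_newick_labels(self):
        D = np.array([[0, .1, .5], [.1, 0, .5], [.5, .5, 0]])
        nwk = linkage_newick(D, ["base", "e1", "e2"])
        assert nwk.endswith(";")
        for lab in ("base", "e1", "e2"):
            assert lab in nwk


def _rank_frame(chrom, pos, ranks):
    return pd.DataFrame({"chrom": chrom, "pos": pos, "rank": ranks})


class TestEnrichment:
    def _blocks(self):
        return pd.DataFrame([{"block": 1, "haplotype": "b1", "chrom": "2L",
                              "start": 1000, "end": 5000}])

    def _singles(self, n_in=20, n_out=200):
        pos_in = np.linspace(1000, 5000, n_in).astype(int)
        pos_out = np.linspace(10_000, 200_000, n_out).astype(int)
        return {
            "b1": pd.DataFrame({"site": range(n_in), "chrom": "2L",
                                "pos": pos_in, "allele": "T"}),
            "b2": pd.DataFrame({"site": range(n_out), "chrom": "2L",
                                "pos": pos_out, "allele": "T"}),
        }

    def test_extreme_separation_minimal_p(self):
        singles = self._singles()
        all_pos = np.concatenate([singles["b1"]["pos"],
                                  singles["b2"]["pos"]])
        ranks = np.concatenate([np.arange(1, 21),       # block: top ranks
                                np.arange(1000, 1200)])
        res = {"F15": _rank_frame("2L", all_pos, ranks)}
        out = enrichment(self._blocks(), singles, res)
        assert out["u_tests"].iloc[0]["p_value"] < 1e-8
        assert out["u_tests"].iloc[0]["median_rank"] == pytest.approx(10.5)

    def test_null_p_values_roughly_uniform(self, rng):
        pvals = []
        singles = self._singles(n_in=30, n_out=120)
        all_pos = np.concatenate([singles["b1"]["pos"],
                                  singles["b2"]["pos"]])
        for _ in range(150):
            ranks = rng.permutation(len(all_pos)) + 1
            res = {"F15": _rank_frame("2L", all_pos, ranks)}
            out = enrichment(self._blocks(), singles, res)
            pvals.append(out["u_tests"].iloc[0]["p_value"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_top_capture_fraction(self):
        singles = self._singles()
        all_pos = np.concatenate([singles["b1"]["pos"],
                                  singles["b2"]["pos"]])
        ranks = np.arange(1, len(all_pos) + 1)
        res = {"F15": _rank_frame("2L", all_pos, ranks)}
        out = enrichment(self._blocks(), singles, res, top_n=40)
        # the 20 block singletons hold ranks 1..20 of the top 40
        assert out["top_capture"]["F15"] == pytest.approx(0.5)


class TestCandidateGenes:
    genes = pd.DataFrame([
        {"chrom": "2L", "start": 1000, "end": 2000, "name": "geneA"},
        {"chrom": "2L", "start": 8000, "end": 9000, "name": "geneB"},
    ])

    def _block(self):
        return {"block": 1, "chrom": "2L", "start": 500, "end": 9500}

    def test_low_frequency_allele_inside_gene(self):
        sites = pd.DataFrame({"chrom": "2L", "pos": [1500],
                              "base_freq": [0.03]})
        assert candidate_genes(self._block(), sites, self.genes) == ["geneA"]

    def test_no_low_frequency_alleles_empty(self):
        sites = pd.DataFrame({"chrom": "2L", "pos": [1500, 8500],
                              "base_freq": [0.5, 0.2]})
        assert candidate_genes(self._block(), sites, self.genes) == []

    def test_padding_irrelevant_without_boundary_snps(self):
        sites = pd.DataFrame({"chrom": "2L", "pos": [1500, 8500],
                              "base_freq": [0.03, 0.05]})
        a = candidate_genes(self._block(), sites, self.genes, padding=0)
        b = candidate_genes(self._block(), sites, self.genes, padding=1000)
        assert a == b == ["geneA", "geneB"]


class TestTrackHaplotypes:
    def test_recovers_constructed_frequencies(self):
        # 2 haplotypes with 20 singletons each at known frequencies
        design = [("R1", 0), ("R1", 15)]
        freqs = np.vstack([np.tile([0.1, 0.4], (20, 1)),
                           np.tile([0.05, 0.02], (20, 1))])
        pool = make_pool(freqs, ["T"] * 40, ["A"] * 40, design, depth=200)
        singles = {
            "b1": pd.DataFrame({"site": range(20), "chrom": "2L",
                                "pos": pool.sites["pos"][:20],
                                "allele": "T"}),
            "b2": pd.DataFrame({"site": range(20), "chrom": "2L",
                                "pos": pool.sites["pos"][20:],
                                "allele": "T"}),
        }
        traj = track_haplotypes(singles, pool)
        t = traj.set_index(["haplotype", "timepoint"])["estimate"]
        assert t[("b1", "F0")] == pytest.approx(0.1)
        assert t[("b1", "F15")] == pytest.approx(0.4)
        assert t[("b2", "F15")] == pytest.approx(0.02)
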
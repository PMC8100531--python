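"""Planted-truth simulator: determinism, planted structure, count model."""

import numpy as np
import pytest
from scipy import stats as sps

from cryopirna import simdata
from cryopirna.homology import match_pair
from cryopirna.readproc import process_reads
from cryopirna.simdata import SimulationConfig


def intervals_overlap(a, b):
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


class TestGenomeGeneration:
    def test_deterministic_for_fixed_seed(self, small_config):
        out = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            genomes, truth = simdata.generate_genome(small_config, rng)
            out.append((genomes, sorted(truth.planted_pirnas["panda"])))
        assert out[0] == out[1]

    def test_no_clusters_gives_empty_truth(self, rng):
        cfg = SimulationConfig(n_clusters=0, n_homolog_pairs=0)
        _, truth = simdata.generate_genome(cfg, rng)
        assert truth.planted_clusters["panda"] == []
        assert truth.planted_pirnas["panda"] == {}

    def test_planted_clusters_disjoint_by_pairwise_comparison(self, rng):
        cfg = SimulationConfig(n_chromosomes=1, chrom_length=50_000,
                               n_clusters=5, cluster_span=2_000,
                               min_cluster_sep=2_500, n_homolog_pairs=0)
        _, truth = simdata.generate_genome(cfg, rng)
        clusters = truth.planted_clusters["panda"]
        assert len(clusters) == 5
        assert all(end - start == 2_000 for _, start, end in clusters)
        for i, a in enumerate(clusters):
            for b in clusters[i + 1:]:
                assert not intervals_overlap(a, b)

    def test_each_cluster_contains_planted_pirna_substrings(self, small_config, rng):
        genomes, truth = simdata.generate_genome(small_config, rng)
        for sp in small_config.species:
            genome = genomes[sp]
            pirnas = list(truth.planted_pirnas[sp].values())
            assert len({p.seq for p in pirnas}) == \
                small_config.n_clusters * small_config.pirnas_per_cluster
            for p in pirnas:
                assert genome[p.chrom][p.start:p.end] == p.seq
                assert any(chrom == p.chrom and start <= p.start and p.end <= end
                           for chrom, start, end in truth.planted_clusters[sp])

    def test_five_prime_u_bias_visible(self, rng):
        cfg = SimulationConfig(u1_bias=0.8, n_homolog_pairs=0)
        _, truth = simdata.generate_genome(cfg, rng)
        seqs = list(truth.planted_pirnas["panda"])
        frac_u = sum(s.startswith("T") for s in seqs) / len(seqs)
        assert 0.65 < frac_u < 0.95

    def test_ncrna_loci_disjoint_from_clusters(self, small_config, rng):
        _, truth = simdata.generate_genome(small_config, rng)
        for sp in small_config.species:
            for chrom, s, e, _ in truth.ncrna_loci[sp]:
                for interval in truth.planted_clusters[sp]:
                    assert not intervals_overlap((chrom, s, e), interval)

    def test_homolog_truth_equals_brute_force_rule_check(self, small_config, rng):
        _, truth = simdata.generate_genome(small_config, rng)
        sp_a, sp_b = small_config.species
        found = {(a, b)
                 for a in truth.planted_pirnas[sp_a]
                 for b in truth.planted_pirnas[sp_b]
                 if match_pair(a, b) is not None}
        assert found == set(truth.homolog_pairs)
        assert len(found) == small_config.n_homolog_pairs

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(u1_bias=1.5), "u1_bias"),
        (dict(nb_dispersion=0.0), "nb_dispersion"),
        (dict(chrom_length=5_000), "chrom_length"),
        (dict(pirna_length_dist={28: 0.5}), "sums"),
    ])
    def test_invalid_config_rejected(self, rng, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            simdata.generate_genome(SimulationConfig(**kwargs), rng)


class TestLibraries:
    def test_null_simulation_has_equal_condition_means(self, rng):
        cfg = SimulationConfig(de_fraction=0.0, n_homolog_pairs=0)
        _, truth = simdata.generate_genome(cfg, rng)
        for sp in cfg.species:
            for p in truth.planted_pirnas[sp].values():
                assert p.fresh_mean == p.frozen_mean and not p.is_de

    def test_all_reads_recover_planted_length_after_trimming(self, rng):
        cfg = SimulationConfig(n_chromosomes=1, chrom_length=30_000,
                               n_clusters=2, pirnas_per_cluster=15,
                               contam_fraction=0.0, n_homolog_pairs=0,
                               nb_mean_range=(5.0, 20.0))
        genomes, truth = simdata.generate_genome(cfg, rng)
        libs = simdata.simulate_libraries(genomes, truth, cfg, rng)
        planted = set(truth.planted_pirnas["panda"])
        reads = libs[("panda", "fresh")]
        clean, stats = process_reads(reads, cfg.adapter_seq)
        assert stats.n_clean == stats.n_raw == len(reads) > 0
        assert all(r.seq in planted for r in clean)

    def test_nb_sample_mean_within_three_standard_errors(self, rng):
        mean, disp, n = 100.0, 0.1, 200
        counts = [simdata._nb_draw(rng, mean, disp) for _ in range(n)]
        se = np.sqrt((mean + mean ** 2 * disp) / n)
        assert abs(np.mean(counts) - mean) < 3 * se

    def test_count_model_variance_consistent_with_nb(self, rng):
        # chi2-style two-sided check at alpha = 0.01 on the empirical
        # variance of repeated draws against mean + mean^2 * dispersion
        mean, disp, n = 50.0, 0.2, 4000
        draws = np.array([simdata._nb_draw(rng, mean, disp) for _ in range(n)])
        sigma2 = mean + mean ** 2 * disp
        statistic = (n - 1) * draws.var(ddof=1) / sigma2
        lo, hi = sps.chi2.ppf([0.005, 0.995], df=n - 1)
        # NB tails are heavier than normal, so allow a 20% margin on the band
        assert 0.8 * lo < statistic < 1.2 * hi

    def test_missing_truth_is_an_error(self, small_config, rng):
        genomes, truth = simdata.generate_genome(small_config, rng)
        truth.planted_pirnas = {}
        with pytest.raises(ValueError, match="truth"):
            simdata.simulate_libraries(genomes, truth, small_config, rng)


class TestAnnotations:
    def test_annotation_maps_deterministic(self, small_config):
        texts = []
        for _ in range(2):
            rng = np.random.default_rng(3)
            genomes, truth = simdata.generate_genome(small_config, rng)
            simdata.generate_annotations(genomes, truth, small_config, rng)
            texts.append(truth.annotation_map["panda"].to_csv(sep="\t"))
        assert texts[0] == texts[1]

    def test_empty_ncrna_bed(self, rng):
        cfg = SimulationConfig(n_ncrna_loci=0, n_homolog_pairs=0)
        _, truth = simdata.generate_genome(cfg, rng)
        assert simdata.ncrna_bed(truth, "panda") == ""

    def test_planted_target_sites_are_antisense_matches(self, small_config, rng):
        from cryopirna.seqio import revcomp
        genomes, truth = simdata.generate_genome(small_config, rng)
        simdata.generate_annotations(genomes, truth, small_config, rng)
        for sp in small_config.species:
            assert truth.target_sites[sp], "no sites planted"
            for seq, tid, pos in truth.target_sites[sp]:
                t = truth.transcripts[sp][tid]
                assert t[pos:pos + len(seq)] == revcomp(seq)


class TestPartitionInstance:
    def test_sizes_and_planted_pair_count(self, rng):
        set_a, set_b, pairs = simdata.make_partition_instance(60, 40, 7, rng)
        assert len(set_a) == 60 and len(set_b) == 40 and len(pairs) == 7
        for a, b in pairs:
            assert match_pair(a, b) is not None

    def test_rejects_impossible_instance(self, rng):
        with pytest.raises(ValueError):
            simdata.make_partition_instance(5, 3, 4, rng)
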
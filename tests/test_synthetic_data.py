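import numpy as np
import pytest

from primeforest.motif_scoring import BackgroundModel, fit_background
from primeforest.seqdata import Region, extract_sequence, gc_fraction
from primeforest.synthetic_data import (
    BenchmarkConfig,
    gen_background_genome,
    implant_cluster,
    make_benchmark,
    random_pwm,
    sample_site,
)


class TestGenBackgroundGenome:
    def test_gc_concentrates_at_target(self):
        genome = gen_background_genome(100_000, gc=0.5, seed=1)
        assert gc_fraction(genome.contigs["chr1"]) == pytest.approx(0.5, abs=0.01)

    def test_deterministic_under_seed(self):
        a = gen_background_genome(5000, gc=0.4, seed=7)
        b = gen_background_genome(5000, gc=0.4, seed=7)
        assert a.contigs == b.contigs

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError):
            gen_background_genome(1000, gc=0.0)

    def test_order1_sampling_follows_model(self):
        # a strongly self-transitioning model produces long runs
        transition = np.full((4, 4), 0.1 / 3)
        np.fill_diagonal(transition, 0.9)
        bg = BackgroundModel(1, np.full(4, 0.25), transition)
        genome = gen_background_genome(30_000, gc=0.5, order1=bg, seed=2)
        fitted = fit_background(genome.contigs["chr1"])
        assert np.diag(fitted.transition).min() > 0.8


class TestImplantCluster:
    def test_returns_requested_sites(self, small_genome):
        rng = np.random.default_rng(0)
        pwm = random_pwm("m", 8, 0.9, rng)
        edited, sites = implant_cluster(
            small_genome, Region("chr1", 1000, 1300), [pwm], n_sites=3, seed=4
        )
        assert len(sites) == 3
        for site in sites:
            assert 1000 <= site.start and site.end <= 1300
            assert site.length == 8

    def test_sites_non_overlapping_and_ordered(self, small_genome):
        rng = np.random.default_rng(0)
        pwm = random_pwm("m", 8, 0.9, rng)
        _, sites = implant_cluster(
            small_genome, Region("chr1", 1000, 1300), [pwm], n_sites=4, seed=5
        )
        for a, b in zip(sites, sites[1:]):
            assert a.end <= b.start

    def test_same_seed_byte_identical(self, small_genome):
        rng = np.random.default_rng(0)
        pwm = random_pwm("m", 8, 0.9, rng)
        g1, _ = implant_cluster(small_genome, Region("chr1", 0, 300), [pwm], 2, seed=6)
        g2, _ = implant_cluster(small_genome, Region("chr1", 0, 300), [pwm], 2, seed=6)
        assert g1.contigs == g2.contigs

    def test_locus_too_small_rejected(self, small_genome):
        rng = np.random.default_rng(0)
        pwm = random_pwm("m", 20, 0.9, rng)
        with pytest.raises(ValueError):
            implant_cluster(small_genome, Region("chr1", 0, 30), [pwm], 5, seed=0)


class TestSampleSite:
    def test_site_drawn_from_support(self):
        rng = np.random.default_rng(1)
        pwm = random_pwm("m", 10, 0.99, rng)
        site = sample_site(pwm, rng, temperature=0.3)
        # sharp sampling at high consensus probability: essentially consensus
        assert site == pwm.consensus()

    def test_length_matches_pwm(self):
        rng = np.random.default_rng(2)
        pwm = random_pwm("m", 7, 0.8, rng)
        assert len(sample_site(pwm, rng)) == 7


class TestMakeBenchmark:
    def test_panel_sizes_match_config(self, tiny_benchmark):
        b = tiny_benchmark
        cfg = b.config
        labels = [lab for _, lab in b.variants]
        assert labels.count("gain") == cfg.n_gain_variants
        assert labels.count("loss") == cfg.n_loss_variants
        assert labels.count("neutral") == cfg.n_neutral_variants

    def test_every_loss_variant_inside_a_site(self, tiny_benchmark):
        b = tiny_benchmark
        site_spans = [(s.region.start, s.region.end) for s in b.sites]
        for variant in b.variants_with_label("loss"):
            assert any(s <= variant.pos < e for s, e in site_spans)

    def test_neutral_variants_far_from_sites(self, tiny_benchmark):
        b = tiny_benchmark
        for variant in b.variants_with_label("neutral"):
            for s in b.sites:
                assert not (s.region.start - 50 <= variant.pos < s.region.end + 50)

    def test_variants_match_reference(self, tiny_benchmark):
        b = tiny_benchmark
        for variant, _ in b.variants:
            assert b.genome.base_at(variant.contig, variant.pos) == variant.ref_allele

    def test_feature_spec_is_20_motifs(self, tiny_benchmark):
        spec = tiny_benchmark.feature_spec
        assert len(spec.motif_features) == 20
        assert spec.n_query_motifs == 10
        assert spec.model_class == "M1"

    def test_positives_carry_expected_site_count(self, tiny_benchmark):
        b = tiny_benchmark
        for region in b.positives:
            n_inside = sum(
                1 for s in b.sites
                if region.start <= s.region.start and s.region.end <= region.end
            )
            assert n_inside == b.config.sites_per_positive

    def test_determinism(self):
        cfg = BenchmarkConfig(
            seed=3, genome_length=200_000, n_positives=10,
            n_gain_variants=3, n_loss_variants=3, n_neutral_variants=3,
            n_distractors_per_class=5, n_background_decoys=100,
        )
        b1 = make_benchmark(cfg)
        b2 = make_benchmark(cfg)
        assert b1.genome.contigs == b2.genome.contigs
        assert b1.variants == b2.variants
        assert b1.positives == b2.positives

    def test_heterotypic_grammar_structure(self):
        cfg = BenchmarkConfig(
            seed=4, grammar="heterotypic", genome_length=400_000, n_positives=12,
            n_gain_variants=3, n_loss_variants=3, n_neutral_variants=3,
            n_distractors_per_class=6, n_background_decoys=100,
        )
        b = make_benchmark(cfg)
        query = b.query_pwm.name
        for region in b.positives:
            inside = [
                s for s in b.sites
                if region.start <= s.region.start and s.region.end <= region.end
            ]
            names = {s.pwm_name for s in inside}
            assert query in names
            assert any(n.startswith("cofactor") for n in names)

    def test_heterotypic_rescan_confirms_grammar(self):
        """Rescanning with the generating PWMs: positives score for both the
        query motif and a co-factor motif; query-only distractors lack the
        co-factor signal."""
        from primeforest.motif_scoring import cluster_score

        cfg = BenchmarkConfig(
            seed=9, grammar="heterotypic", genome_length=400_000, n_positives=10,
            n_gain_variants=2, n_loss_variants=2, n_neutral_variants=2,
            n_distractors_per_class=5, n_background_decoys=0,
        )
        b = make_benchmark(cfg)
        cofactor_pwms = [p for n, p in b.pwms.items()
                         if n.startswith("cofactor") and "_var" not in n]
        def query_and_cofactor_scores(region):
            seq = extract_sequence(b.genome, region)
            q = cluster_score(b.query_pwm, seq, b.background)
            c = max(cluster_score(p, seq, b.background) for p in cofactor_pwms)
            return q, c

        pos_scores = [query_and_cofactor_scores(r) for r in b.positives[:5]]
        assert all(q > 5 and c > 5 for q, c in pos_scores)
        # query-only distractors occupy the first half of the distractor list
        qd_scores = [
            query_and_cofactor_scores(r) for r in b.distractor_loci[:5]
        ]
        mean_pos_c = np.mean([c for _, c in pos_scores])
        mean_qd_c = np.mean([c for _, c in qd_scores])
        assert mean_qd_c < mean_pos_c - 3

    def test_write_benchmark_round_trip(self, tiny_benchmark, tmp_path):
        from primeforest.seqdata import read_genome, read_pwms, read_regions
        from primeforest.synthetic_data import write_benchmark

        write_benchmark(tiny_benchmark, tmp_path)
        genome = read_genome(tmp_path / "genome.fa")
        assert genome.contigs == tiny_benchmark.genome.contigs
        positives = read_regions(tmp_path / "positives.bed")
        assert [(r.contig, r.start, r.end) for r in positives] == [
            (r.contig, r.start, r.end) for r in tiny_benchmark.positives
        ]
        pwms = read_pwms(tmp_path / "motifs.cb")
        assert len(pwms) == 20
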
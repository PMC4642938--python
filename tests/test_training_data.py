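import numpy as np
import pytest
from scipy.stats import ks_2samp

from primeforest.motif_scoring import BackgroundModel
from primeforest.seqdata import (
    GenomeStore,
    PeakTrack,
    Pwm,
    Region,
    extract_sequence,
    gc_fraction,
)
from primeforest.training_data import (
    FeatureBuilder,
    FeatureSpec,
    LabeledSet,
    assemble_training_set,
    motif_feature_vector,
    sample_gc_matched_negatives,
    track_feature,
    track_feature_vector,
)


class TestFeatureSpec:
    def test_model_class_constraints(self):
        with pytest.raises(ValueError):
            FeatureSpec(motif_features=["a", "b"], model_class="M0")
        with pytest.raises(ValueError):
            FeatureSpec(motif_features=["a"], track_features=["t"], model_class="M1")
        with pytest.raises(ValueError):
            FeatureSpec(motif_features=["a"], track_features=["t"], model_class="M2")
        with pytest.raises(ValueError):
            FeatureSpec(model_class="M3")

    def test_groups_split_query_and_coreg(self):
        spec = FeatureSpec(
            motif_features=[f"m{i}" for i in range(6)],
            model_class="M1",
            n_query_motifs=2,
        )
        groups = spec.groups()
        assert groups["query_motifs"] == ["m0", "m1"]
        assert groups["coreg_motifs"] == ["m2", "m3", "m4", "m5"]

    def test_m3_feature_count(self):
        spec = FeatureSpec(
            motif_features=[f"m{i}" for i in range(20)],
            track_features=[f"t{i}" for i in range(15)],
            model_class="M3",
        )
        assert spec.n_features == 35


class TestGcMatchedNegatives:
    def test_count_is_ratio_times_positives(self, tiny_benchmark):
        b = tiny_benchmark
        positives = b.positives[:5]
        negatives = sample_gc_matched_negatives(
            positives, b.genome, ratio=20, seed=1
        )
        assert len(negatives) == 100

    def test_lengths_match_positives(self, tiny_benchmark):
        b = tiny_benchmark
        negatives = sample_gc_matched_negatives(
            b.positives[:5], b.genome, ratio=4, seed=2
        )
        assert {n.length for n in negatives} == {p.length for p in b.positives[:5]}

    def test_gc_within_tolerance_of_some_positive(self, tiny_benchmark):
        b = tiny_benchmark
        positives = b.positives[:8]
        tol = 0.02
        negatives = sample_gc_matched_negatives(
            positives, b.genome, ratio=5, gc_tolerance=tol, seed=3
        )
        pos_gc = [gc_fraction(extract_sequence(b.genome, p)) for p in positives]
        for n in negatives:
            n_gc = gc_fraction(extract_sequence(b.genome, n))
            assert min(abs(n_gc - g) for g in pos_gc) <= tol + 1e-12

    def test_negatives_avoid_positives(self, tiny_benchmark):
        b = tiny_benchmark
        negatives = sample_gc_matched_negatives(
            b.positives, b.genome, ratio=3, seed=4, exclude=b.gain_loci
        )
        for n in negatives:
            assert not any(n.overlaps(p) for p in b.positives)
            assert not any(n.overlaps(g) for g in b.gain_loci)

    def test_deterministic_under_seed(self, tiny_benchmark):
        b = tiny_benchmark
        a = sample_gc_matched_negatives(b.positives[:4], b.genome, ratio=3, seed=9)
        c = sample_gc_matched_negatives(b.positives[:4], b.genome, ratio=3, seed=9)
        assert a == c

    def test_gc_distribution_matches(self):
        """KS distance between positive and negative GC distributions stays
        small when each negative is pairwise-matched (100 positives, 1:20)."""
        from primeforest.synthetic_data import BenchmarkConfig, make_benchmark

        b = make_benchmark(
            BenchmarkConfig(
                seed=31, genome_length=1_000_000, n_positives=100,
                n_gain_variants=0, n_loss_variants=0, n_neutral_variants=0,
                n_distractors_per_class=0, n_background_decoys=0,
            )
        )
        negatives = sample_gc_matched_negatives(b.positives, b.genome, ratio=20, seed=6)
        pos_gc = [gc_fraction(extract_sequence(b.genome, p)) for p in b.positives]
        neg_gc = [gc_fraction(extract_sequence(b.genome, n)) for n in negatives]
        assert ks_2samp(pos_gc, neg_gc).statistic < 0.1

    def test_impossible_gc_raises(self):
        genome = GenomeStore({"chr1": "AT" * 2000 + "GC" * 30})
        positives = [Region("chr1", 4000, 4050)]  # all-GC region
        with pytest.raises(RuntimeError):
            sample_gc_matched_negatives(
                positives, genome, ratio=1, seed=0, max_attempts=200
            )


class TestTrackFeatures:
    def make_track(self):
        return PeakTrack(
            "t",
            [
                (Region("chr1", 100, 200), 3.0),
                (Region("chr1", 150, 260), 7.5),
            ],
        )

    def test_max_signal_of_overlapping_peaks(self):
        assert track_feature(Region("chr1", 120, 180), self.make_track()) == 7.5

    def test_no_overlap_gives_zero(self):
        assert track_feature(Region("chr1", 300, 400), self.make_track()) == 0.0

    def test_touching_boundary_excluded(self):
        # peak [100, 200) and region [200, 300): zero overlap in half-open
        # terms, so only the second peak (reaching 260) contributes
        assert track_feature(Region("chr1", 200, 300), self.make_track()) == 7.5
        assert track_feature(Region("chr1", 260, 300), self.make_track()) == 0.0

    def test_vector_ordering(self):
        t1 = PeakTrack("t1", [(Region("chr1", 0, 50), 2.0)])
        t2 = PeakTrack("t2", [(Region("chr1", 0, 50), 5.0)])
        region = Region("chr1", 10, 40)
        assert track_feature_vector(region, [t1, t2]).tolist() == [2.0, 5.0]
        assert track_feature_vector(region, [t2, t1]).tolist() == [5.0, 2.0]


class TestMotifFeatures:
    def test_vector_length_and_order(self, tiny_benchmark):
        b = tiny_benchmark
        pwms = [b.pwms[n] for n in b.feature_spec.motif_features]
        vec = motif_feature_vector(b.positives[0], b.genome, pwms, b.background)
        assert vec.shape == (20,)
        # permuting the PWM list permutes the vector
        vec_perm = motif_feature_vector(
            b.positives[0], b.genome, pwms[::-1], b.background
        )
        assert np.allclose(vec_perm, vec[::-1])

    def test_background_region_scores_low(self, tiny_benchmark):
        b = tiny_benchmark
        pwms = [b.pwms[n] for n in b.feature_spec.motif_features]
        pos_vec = motif_feature_vector(b.positives[0], b.genome, pwms, b.background)
        # positives should carry strong query-motif signal in feature 0
        assert pos_vec[0] > 15


class TestAssemble:
    def test_shapes_and_counts(self, tiny_benchmark):
        b = tiny_benchmark
        positives = b.positives[:10]
        data = assemble_training_set(
            positives, b.genome, b.feature_spec, b.pwms,
            bg=b.background, ratio=20, seed=1, exclude=b.negative_exclusion,
        )
        assert data.feature_matrix.shape == (210, 20)
        assert data.labels.sum() == 10
        assert (data.labels == 0).sum() == 200

    def test_determinism(self, tiny_benchmark):
        b = tiny_benchmark
        kwargs = dict(bg=b.background, ratio=2, seed=5, exclude=b.negative_exclusion)
        d1 = assemble_training_set(b.positives[:5], b.genome, b.feature_spec, b.pwms, **kwargs)
        d2 = assemble_training_set(b.positives[:5], b.genome, b.feature_spec, b.pwms, **kwargs)
        assert np.array_equal(d1.feature_matrix, d2.feature_matrix)
        assert d1.regions == d2.regions

    def test_same_region_same_row(self, tiny_benchmark):
        b = tiny_benchmark
        builder = FeatureBuilder(b.feature_spec, b.pwms, bg=b.background)
        seq = extract_sequence(b.genome, b.positives[0])
        assert np.array_equal(builder.features_for(seq), builder.features_for(seq))

    def test_m3_assembly_with_tracks(self, tiny_benchmark):
        b = tiny_benchmark
        spec3 = FeatureSpec(
            motif_features=list(b.feature_spec.motif_features),
            track_features=[t.name for t in b.tracks],
            model_class="M3",
            n_query_motifs=b.feature_spec.n_query_motifs,
        )
        data = assemble_training_set(
            b.positives[:5], b.genome, spec3, b.pwms, b.tracks,
            bg=b.background, ratio=2, seed=7, exclude=b.negative_exclusion,
        )
        assert data.feature_matrix.shape == (15, 23)
        assert not np.isnan(data.feature_matrix).any()

    def test_unknown_feature_name_raises(self, tiny_benchmark):
        b = tiny_benchmark
        spec = FeatureSpec(motif_features=["nope"], model_class="M1")
        with pytest.raises(KeyError):
            FeatureBuilder(spec, b.pwms, bg=b.background)

    def test_m0_not_trainable(self, tiny_benchmark):
        b = tiny_benchmark
        spec0 = FeatureSpec(motif_features=["query_TF"], model_class="M0")
        with pytest.raises(ValueError):
            assemble_training_set(
                b.positives[:3], b.genome, spec0, b.pwms, bg=b.background
            )

    def test_tsv_round_numbers(self, tiny_benchmark, tmp_path):
        b = tiny_benchmark
        data = assemble_training_set(
            b.positives[:3], b.genome, b.feature_spec, b.pwms,
            bg=b.background, ratio=1, seed=2, exclude=b.negative_exclusion,
        )
        path = tmp_path / "set.tsv"
        data.to_tsv(path)
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        assert df.shape == (6, 22)  # region + label + 20 features
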
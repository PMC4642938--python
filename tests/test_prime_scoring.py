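import numpy as np
import pytest

from primeforest.crm_classifier import m0_model, train_model
from primeforest.prime_scoring import (
    BackgroundDist,
    Thresholds,
    apply_variant,
    candidate_windows,
    fit_background_dist,
    m0_delta,
    prime,
    saturation_scan,
    saturation_summary,
    score_variants,
)
from primeforest.seqdata import Region, Variant
from primeforest.synthetic_data import neutral_snv_panel
from primeforest.training_data import FeatureBuilder, FeatureSpec, assemble_training_set


@pytest.fixture(scope="module")
def trained(tiny_benchmark):
    b = tiny_benchmark
    data = assemble_training_set(
        b.positives, b.genome, b.feature_spec, b.pwms,
        bg=b.background, seed=1, exclude=b.negative_exclusion,
    )
    model = train_model(data, seed=2, name="m1")
    builder = FeatureBuilder(b.feature_spec, b.pwms, bg=b.background)
    return b, model, builder


class TestApplyVariant:
    def test_snv_substitution(self):
        region = Region("c", 10, 14)
        out = apply_variant("AAAA", region, Variant("c", 11, "A", "C"))
        assert out == "ACAA"

    def test_insertion_after_anchor(self):
        region = Region("c", 10, 14)
        out = apply_variant("AAAA", region, Variant("c", 11, "A", "ATT"))
        assert out == "AATTAA"

    def test_ref_mismatch_rejected(self):
        with pytest.raises(ValueError, match="ref mismatch"):
            apply_variant("AAAA", Region("c", 10, 14), Variant("c", 11, "G", "T"))

    def test_variant_outside_region_rejected(self):
        with pytest.raises(ValueError):
            apply_variant("AAAA", Region("c", 10, 14), Variant("c", 20, "A", "T"))


class TestCandidateWindows:
    def test_interior_variant_has_nine_windows(self, tiny_benchmark):
        b = tiny_benchmark
        variant = Variant("chr1", 200_000, b.genome.base_at("chr1", 200_000), "A")
        if variant.ref_allele == "A":
            variant = Variant("chr1", 200_000, "A", "C")
        windows = candidate_windows(b.genome, variant, 300)
        assert len(windows) == 9
        for w in windows:
            assert w.start <= variant.pos < w.end
            assert w.length == 300

    def test_contig_edge_windows_clipped(self, tiny_benchmark):
        b = tiny_benchmark
        ref = b.genome.base_at("chr1", 3)
        alt = "A" if ref != "A" else "C"
        windows = candidate_windows(b.genome, Variant("chr1", 3, ref, alt), 300)
        assert len(windows) >= 1
        assert all(w.start == 0 for w in windows)


class TestPrime:
    def test_identity_variant_gives_zero(self, trained):
        b, model, builder = trained
        pos = 150_000
        ref = b.genome.base_at("chr1", pos)
        result = prime(model, b.genome, builder, Variant("chr1", pos, ref, ref))
        assert result.prime == 0.0
        assert result.call == "neutral"

    def test_prime_equals_alt_minus_ref(self, trained):
        b, model, builder = trained
        for variant in b.variants_with_label("gain")[:3]:
            r = prime(model, b.genome, builder, variant)
            assert r.prime == pytest.approx(r.alt_score - r.ref_score)
            assert -1 <= r.prime <= 1

    def test_loss_variant_negative(self, trained):
        b, model, builder = trained
        results = score_variants(model, b.genome, builder, b.variants_with_label("loss"))
        assert np.median([r.prime for r in results]) < 0

    def test_max_over_windows_at_least_centred(self, trained):
        """The allele score maxes over the shift grid, so it is at least the
        score of the near-centre window alone."""
        b, model, builder = trained
        variant = b.variants_with_label("loss")[0]
        full = score_variants(model, b.genome, builder, [variant])[0]
        centred = score_variants(
            model, b.genome, builder, [variant], fractions=(0.5,)
        )[0]
        assert full.ref_score >= centred.ref_score - 1e-12
        assert full.alt_score >= centred.alt_score - 1e-12

    def test_snv_reversion_symmetry(self, trained):
        """Applying an SNV and its exact reversion on the mutated genome
        gives opposite PRIME values within ensemble granularity."""
        from primeforest.seqdata import GenomeStore

        b, model, builder = trained
        variant = b.variants_with_label("loss")[0]
        seq = b.genome.contigs["chr1"]
        mutated = GenomeStore(
            {"chr1": seq[: variant.pos] + variant.alt_allele + seq[variant.pos + 1 :]}
        )
        forward = prime(model, b.genome, builder, variant)
        reverted = prime(
            model, mutated, builder,
            Variant("chr1", variant.pos, variant.alt_allele, variant.ref_allele),
        )
        assert reverted.prime == pytest.approx(-forward.prime, abs=2 / 151)


class TestBackgroundDist:
    def test_zscore_is_affine(self):
        dist = BackgroundDist("m", "SNV", np.array([0.0, 0.01, -0.01, 0.02, -0.02]))
        a = dist.zscore(0.1)
        b = dist.zscore(0.2)
        c = dist.zscore(0.3)
        assert c - b == pytest.approx(b - a)
        assert dist.zscore(dist.mean) == pytest.approx(0.0)

    def test_zero_sd_rejected(self):
        dist = BackgroundDist("m", "SNV", np.full(10, 0.5))
        with pytest.raises(ValueError):
            dist.zscore(0.1)

    def test_json_round_trip(self, tmp_path):
        dist = BackgroundDist("m", "insertion", np.array([0.1, -0.1, 0.0, 0.05]))
        path = tmp_path / "bg.json"
        dist.to_json(path)
        back = BackgroundDist.from_json(path)
        assert back.mean == pytest.approx(dist.mean)
        assert back.sd == pytest.approx(dist.sd)
        assert back.variant_class == "insertion"

    def test_fit_requires_enough_controls(self, trained):
        b, model, builder = trained
        with pytest.raises(ValueError):
            fit_background_dist(
                model, b.genome, builder, b.variants_with_label("neutral")[:5], "SNV"
            )

    def test_fit_on_neutral_controls_centred(self, trained):
        b, model, builder = trained
        controls = neutral_snv_panel(b, 120, seed=9, margin=350)
        dist = fit_background_dist(model, b.genome, builder, controls, "SNV")
        assert abs(dist.mean) < 0.05
        assert len(dist.values) == 120


class TestCalls:
    def test_threshold_modes(self):
        thresholds = Thresholds(mode="prime")
        from primeforest.prime_scoring import _make_call

        assert _make_call(0.5, None, "SNV", thresholds) == "gain"
        assert _make_call(-0.5, None, "SNV", thresholds) == "loss"
        assert _make_call(0.1, None, "SNV", thresholds) == "neutral"

    def test_zscore_mode_uses_class_thresholds(self):
        thresholds = Thresholds(mode="zscore")
        from primeforest.prime_scoring import _make_call

        assert _make_call(0.2, 10.0, "SNV", thresholds) == "gain"
        assert _make_call(0.2, 10.0, "insertion", thresholds) == "neutral"
        assert _make_call(-0.2, -15.0, "insertion", thresholds) == "loss"

    def test_default_thresholds(self):
        t = Thresholds()
        assert t.prime_abs == 0.3
        assert t.z_for("SNV") == 9.65
        assert t.z_for("insertion") == 14.03


class TestSaturation:
    def test_three_rows_per_position(self, trained):
        b, model, builder = trained
        region = Region("chr1", b.positives[0].start, b.positives[0].start + 40)
        region = b.positives[0]
        table = saturation_scan(model, b.genome, builder, region)
        assert len(table) == 3 * region.length
        assert set(table["call"]) <= {"gain", "loss", "neutral"}

    def test_summary_has_one_row_per_position(self, trained):
        b, model, builder = trained
        region = b.positives[1]
        table = saturation_scan(model, b.genome, builder, region)
        summary = saturation_summary(table)
        assert len(summary) == region.length
        assert (summary["max_abs_prime"] >= 0).all()


class TestM0Delta:
    def test_identity_variant_zero(self, trained):
        b, _, _ = trained
        spec0 = FeatureSpec(motif_features=["query_TF"], model_class="M0")
        builder0 = FeatureBuilder(spec0, b.pwms, bg=b.background)
        pos = 150_000
        ref = b.genome.base_at("chr1", pos)
        delta = m0_delta("query_TF", b.genome, builder0, Variant("chr1", pos, ref, ref), 300)
        assert delta == 0.0

    def test_core_completion_positive(self, trained):
        """Repairing the broken core of a background decoy raises the
        single-PWM score."""
        b, _, _ = trained
        spec0 = FeatureSpec(motif_features=["query_TF"], model_class="M0")
        builder0 = FeatureBuilder(spec0, b.pwms, bg=b.background)
        decoy = b.decoys[0]
        core_col = int(np.argmax(b.query_pwm.information_content()))
        pos = decoy.region.start + core_col
        ref = b.genome.base_at("chr1", pos)
        alt = b.query_pwm.consensus()[core_col]
        assert ref != alt
        delta = m0_delta("query_TF", b.genome, builder0, Variant("chr1", pos, ref, alt), 300)
        assert delta > 0
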
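"""Standard benchmark evaluation: the end-to-end checks of the method.

Bundles a generated benchmark with a trained model and exposes the canonical
measurements on it: cross-validated classification performance against the
single-PWM baseline, feature-importance group shares, PRIME recovery of the
labeled variant panel, neutral-SNV specificity of PRIME versus the PWM
delta, saturation-hotspot localization, and the context dependence of a
fixed cluster insertion.  Both the test suite and the reproduction script
drive these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crm_classifier import (
    CrmModel,
    CvReport,
    cross_validate,
    feature_importance,
    score_report,
    train_model,
)
from .motif_scoring import (
    candidate_hits,
    cluster_score_bruteforce,
    cluster_score_from_hits,
)
from .prime_scoring import (
    m0_deltas,
    saturation_scan,
    saturation_summary,
    score_variants,
)
from .seqdata import Variant, extract_sequence
from .synthetic_data import (
    Benchmark,
    BenchmarkConfig,
    _ForbiddenIndex,
    make_benchmark,
    neutral_snv_panel,
    random_pwm,
)
from .training_data import FeatureBuilder, FeatureSpec, LabeledSet, assemble_training_set


@dataclass
class BenchmarkBundle:
    """A benchmark with its assembled training set and trained M1 model."""

    benchmark: Benchmark
    data: LabeledSet
    model: CrmModel
    builder: FeatureBuilder
    m0_builder: FeatureBuilder

    @property
    def m0_pwm_name(self) -> str:
        return self.benchmark.feature_spec.motif_features[0]


def build_bundle(
    seed: int, grammar: str = "homotypic", **config_overrides
) -> BenchmarkBundle:
    """Generate a benchmark and train the M1 classifier on it.

    All randomness (generation, negative sampling, forest) derives from
    ``seed``.
    """
    config = BenchmarkConfig(seed=seed, grammar=grammar, **config_overrides)
    benchmark = make_benchmark(config)
    data = assemble_training_set(
        benchmark.positives,
        benchmark.genome,
        benchmark.feature_spec,
        benchmark.pwms,
        bg=benchmark.background,
        ratio=config.negative_ratio,
        seed=seed + 1,
        exclude=benchmark.negative_exclusion,
    )
    model = train_model(data, seed=seed + 2, name=f"M1_{grammar}")
    builder = FeatureBuilder(
        benchmark.feature_spec, benchmark.pwms, bg=benchmark.background
    )
    m0_spec = FeatureSpec(
        motif_features=[benchmark.feature_spec.motif_features[0]],
        model_class="M0",
    )
    m0_builder = FeatureBuilder(m0_spec, benchmark.pwms, bg=benchmark.background)
    return BenchmarkBundle(benchmark, data, model, builder, m0_builder)


# ---------------------------------------------------------------------------
# cluster-score oracle


def cluster_oracle_max_diff(
    seed: int, n_sequences: int = 100, max_length: int = 60, max_hits: int = 12
) -> float:
    """Max |DP - exhaustive| cluster score over random short sequences.

    For each random sequence the candidate hits of a random moderate PWM are
    collected (capped at ``max_hits`` strongest) and the dynamic-program
    score is compared with brute-force enumeration over all hit subsets.
    """
    from .motif_scoring import BackgroundModel

    rng = np.random.default_rng(seed)
    bg = BackgroundModel.uniform()
    worst = 0.0
    for _ in range(n_sequences):
        pwm = random_pwm("m", 5, 0.8, rng)
        length = int(rng.integers(20, max_length + 1))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        hits = candidate_hits([pwm], seq, bg)
        if len(hits) > max_hits:
            hits = sorted(hits, key=lambda h: -h.llr)[:max_hits]
        dp = cluster_score_from_hits(hits)
        brute = cluster_score_bruteforce(hits)
        worst = max(worst, abs(dp - brute))
    return worst


# ---------------------------------------------------------------------------
# classification performance


def cv_performance(bundle: BenchmarkBundle, seed: int) -> dict[str, float]:
    """5-fold CV AuPR/AuROC of M1 and threshold-varied AuPR of the M0 PWM."""
    report: CvReport = cross_validate(bundle.data, k=5, seed=seed)
    seqs = [
        extract_sequence(bundle.benchmark.genome, r) for r in bundle.data.regions
    ]
    m0_scores = bundle.m0_builder.feature_matrix(seqs)[:, 0]
    m0_report = score_report(bundle.data.labels, m0_scores)
    return {
        "m1_au_pr": report.au_pr,
        "m1_au_roc": report.au_roc,
        "m0_au_pr": m0_report.au_pr,
        "m0_au_roc": m0_report.au_roc,
    }


def importance_shares(bundle: BenchmarkBundle) -> dict[str, float]:
    report = feature_importance(bundle.model)
    return dict(report.group_sums)


# ---------------------------------------------------------------------------
# variant-panel recovery and specificity


def panel_medians(bundle: BenchmarkBundle) -> dict[str, float]:
    """Median PRIME of the labeled gain/loss panel and median |PRIME| of the
    neutral panel."""
    b = bundle.benchmark
    out = {}
    for label in ("gain", "loss", "neutral"):
        results = score_variants(
            bundle.model, b.genome, bundle.builder, b.variants_with_label(label)
        )
        primes = np.array([r.prime for r in results])
        if label == "neutral":
            out["median_abs_prime_neutral"] = float(np.median(np.abs(primes)))
        else:
            out[f"median_prime_{label}"] = float(np.median(primes))
        out[f"max_abs_prime_{label}"] = float(np.abs(primes).max()) if len(primes) else 0.0
    return out


def neutral_specificity(
    bundle: BenchmarkBundle, seed: int, n_controls: int = 5000
) -> dict[str, float]:
    """Fractions of neutral background SNVs flagged by PRIME (> 0.3) and by
    the single-PWM delta (>= 0.1).

    Controls are drawn so that no scoring window contains an implanted
    cluster (margin of one region length past the 50 bp panel rule);
    background decoy near-sites are part of the background and not avoided.
    """
    b = bundle.benchmark
    margin = b.config.region_length + 50
    controls = neutral_snv_panel(b, n_controls, seed=seed, margin=margin)
    deltas = m0_deltas(
        bundle.m0_pwm_name, b.genome, bundle.m0_builder, controls,
        bundle.model.window_length,
    )
    results = score_variants(bundle.model, b.genome, bundle.builder, controls)
    primes = np.array([r.prime for r in results])
    return {
        "n_controls": float(n_controls),
        "frac_m0_delta_ge_0.1": float((deltas >= 0.1).mean()),
        "frac_prime_gt_0.3": float((primes > 0.3).mean()),
    }


# ---------------------------------------------------------------------------
# saturation mutagenesis


def saturation_hotspot(bundle: BenchmarkBundle) -> dict[str, float]:
    """Saturation-scan a representative positive region; fraction of
    top-decile per-position max-|PRIME| positions falling inside implanted
    sites.

    The representative region is the positive with the median query-motif
    cluster score: an outlier-strong cluster would sit so far above the
    decision boundary that single-base damage outside the near-invariant
    cores barely moves the classifier.
    """
    b = bundle.benchmark
    n_pos = len(b.positives)
    query_feature = bundle.data.feature_matrix[:n_pos, 0]
    region = b.positives[int(np.argsort(query_feature)[n_pos // 2])]
    table = saturation_scan(bundle.model, b.genome, bundle.builder, region)
    summary = saturation_summary(table)
    site_positions: set[int] = set()
    for site in b.sites:
        if site.region.start >= region.start and site.region.end <= region.end:
            site_positions.update(range(site.region.start, site.region.end))
    n_top = len(summary) // 10
    top = summary.nlargest(n_top, "max_abs_prime")
    frac = float(np.mean([p in site_positions for p in top["position"]]))
    return {
        "n_rows": float(len(table)),
        "n_positions": float(len(summary)),
        "hotspot_site_fraction": frac,
    }


# ---------------------------------------------------------------------------
# insertion context dependence (heterotypic)


def insertion_context(
    het_bundle: BenchmarkBundle, seed: int, n_random: int = 100
) -> dict[str, float]:
    """Insert one fixed query-consensus cluster at its favorable context (a
    co-factor-only locus) and at random background loci; count random loci
    scoring at least the in-context PRIME."""
    b = het_bundle.benchmark
    query = b.query_pwm
    insert_seq = query.consensus() + "ACGTAGCT" + query.consensus()
    contig = next(iter(b.genome.contigs))

    cofactor_loci = [
        r for r in b.distractor_loci
        if any(
            s.pwm_name.startswith("cofactor")
            and s.region.start >= r.start
            and s.region.end <= r.end
            for s in b.sites
        )
    ]
    if not cofactor_loci:
        raise ValueError("benchmark has no co-factor-only loci")
    context_locus = cofactor_loci[0]
    context_sites = [
        s for s in b.sites
        if s.region.start >= context_locus.start and s.region.end <= context_locus.end
    ]
    pos = max(s.region.end for s in context_sites) + 12
    ref = b.genome.base_at(contig, pos)
    context_variant = Variant(contig, pos, ref, ref + insert_seq)

    forbidden = _ForbiddenIndex([s.region for s in b.sites], margin=400)
    rng = np.random.default_rng(seed)
    randoms: list[Variant] = []
    while len(randoms) < n_random:
        p = int(rng.integers(1000, b.config.genome_length - 1000))
        if forbidden.contains(p):
            continue
        r0 = b.genome.base_at(contig, p)
        randoms.append(Variant(contig, p, r0, r0 + insert_seq))

    results = score_variants(
        het_bundle.model, b.genome, het_bundle.builder,
        [context_variant] + randoms,
    )
    context_prime = results[0].prime
    random_primes = np.array([r.prime for r in results[1:]])
    return {
        "context_prime": float(context_prime),
        "n_random": float(n_random),
        "n_random_ge_context": float((random_primes >= context_prime).sum()),
        "median_random_prime": float(np.median(random_primes)),
    }
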
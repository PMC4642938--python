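"""PRIME scoring of variants: shifted windows, empirical z-scores, saturation.

For each variant, candidate windows of the model's window length are placed
so the variant sits at fractions 0.1, 0.2, ..., 0.9 of the window (a shift
grid of 10% of the region; 9 windows for interior variants, clipped at
contig ends).  Both alleles are scored over the same window set — the edit
is applied to the window sequence before feature extraction for the
alternate allele — and each allele's score is the maximum classifier score
over its windows.  PRIME = alt score - ref score, in [-1, 1].

Significance comes from an empirical background distribution of PRIME
scores on control variants of the same class (SNV or insertion):
z = (PRIME - mean) / sd, called gain/loss when |z| exceeds the class
threshold (defaults 9.65 for SNVs, 14.03 for insertions), or when
|PRIME| >= 0.3 in the simple-threshold mode.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .crm_classifier import CrmModel, m0_model
from .motif_scoring import BackgroundModel
from .seqdata import BASES, GenomeStore, Region, Variant, extract_sequence
from .training_data import FeatureBuilder, FeatureSpec

logger = logging.getLogger(__name__)

WINDOW_FRACTIONS = tuple((i + 1) / 10 for i in range(9))

PRIME_ABS_THRESHOLD = 0.3
Z_THRESHOLD_SNV = 9.65
Z_THRESHOLD_INSERTION = 14.03


@dataclass
class Thresholds:
    """Significance thresholds; ``mode`` is "zscore", "prime" or "auto"
    (zscore when a background distribution is available, else prime)."""

    prime_abs: float = PRIME_ABS_THRESHOLD
    z_snv: float = Z_THRESHOLD_SNV
    z_insertion: float = Z_THRESHOLD_INSERTION
    mode: str = "auto"

    def z_for(self, variant_class: str) -> float:
        return self.z_snv if variant_class == "SNV" else self.z_insertion


@dataclass
class BackgroundDist:
    """Empirical PRIME distribution on control variants of one class."""

    model_name: str
    variant_class: str
    values: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mean = float(self.values.mean())
        self.sd = float(self.values.std(ddof=1))
        if self.sd < 0:
            raise ValueError("negative sd")

    def zscore(self, prime: float) -> float:
        if self.sd == 0:
            raise ValueError("background sd is zero; z-scores undefined")
        return (prime - self.mean) / self.sd

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "model_name": self.model_name,
                    "variant_class": self.variant_class,
                    "values": self.values.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "BackgroundDist":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            payload["model_name"],
            payload["variant_class"],
            np.array(payload["values"]),
        )


@dataclass
class PrimeResult:
    """Per-variant scoring record."""

    variant: Variant
    model_name: str
    ref_score: float
    alt_score: float
    prime: float
    zscore: float | None
    call: str
    best_window: Region


def apply_variant(seq: str, region: Region, variant: Variant) -> str:
    """Apply an SNV or insertion to the sequence anchored at ``region``."""
    if variant.contig != region.contig:
        raise ValueError("variant and region are on different contigs")
    offset = variant.pos - region.start
    if not 0 <= offset < region.length:
        raise ValueError(f"{variant} outside {region}")
    if seq[offset] != variant.ref_allele[0]:
        raise ValueError(
            f"ref mismatch at {variant.contig}:{variant.pos}: "
            f"sequence has {seq[offset]!r}, variant says {variant.ref_allele[0]!r}"
        )
    if variant.is_snv:
        return seq[:offset] + variant.alt_allele + seq[offset + 1 :]
    # insertion: inserted bases go right after the anchor base
    return seq[: offset + 1] + variant.alt_allele[1:] + seq[offset + 1 :]


def candidate_windows(
    genome: GenomeStore,
    variant: Variant,
    window_length: int,
    fractions: Sequence[float] = WINDOW_FRACTIONS,
) -> list[Region]:
    """Windows placing the variant at the given window fractions, clipped to
    the contig; duplicates after clipping are merged.  Error if no window of
    at least half the nominal length contains the variant."""
    contig_len = genome.contig_length(variant.contig)
    windows: list[Region] = []
    seen: set[tuple[int, int]] = set()
    for fraction in fractions:
        start = variant.pos - int(round(fraction * window_length))
        start = min(start, contig_len - window_length)
        start = max(start, 0)
        end = min(start + window_length, contig_len)
        if (end - start) * 2 < window_length:
            continue
        if not start <= variant.pos < end:
            continue
        if (start, end) in seen:
            continue
        seen.add((start, end))
        windows.append(Region(variant.contig, start, end))
    if not windows:
        raise ValueError(f"no valid scoring window for {variant}")
    return windows


@dataclass
class AlleleScores:
    ref_score: float
    alt_score: float
    ref_window: Region
    alt_window: Region


def score_allele_windows(
    model: CrmModel,
    genome: GenomeStore,
    builder: FeatureBuilder,
    variant: Variant,
    allele: str,
    fractions: Sequence[float] = WINDOW_FRACTIONS,
) -> tuple[float, Region]:
    """Max classifier score over the shifted windows for one allele."""
    scores = _batch_allele_scores(model, genome, builder, [variant], fractions)[0]
    if allele == "ref":
        return scores.ref_score, scores.ref_window
    if allele == "alt":
        return scores.alt_score, scores.alt_window
    raise ValueError("allele must be 'ref' or 'alt'")


def _batch_allele_scores(
    model: CrmModel,
    genome: GenomeStore,
    builder: FeatureBuilder,
    variants: Sequence[Variant],
    fractions: Sequence[float] = WINDOW_FRACTIONS,
) -> list[AlleleScores]:
    """Score ref and alt alleles of many variants with one batched predict.

    Reference windows are deduplicated across variants (saturation scans and
    dense panels revisit the same windows many times).
    """
    seqs: list[str] = []
    regions: list[Region] = []
    ref_index: dict[tuple[str, int, int], int] = {}
    jobs: list[tuple[list[int], list[int], list[Region]]] = []

    for variant in variants:
        windows = candidate_windows(genome, variant, model.window_length, fractions)
        ref_rows: list[int] = []
        alt_rows: list[int] = []
        for window in windows:
            key = (window.contig, window.start, window.end)
            if key not in ref_index:
                ref_index[key] = len(seqs)
                seqs.append(extract_sequence(genome, window))
                regions.append(window)
            ref_rows.append(ref_index[key])
            ref_seq = seqs[ref_index[key]]
            alt_rows.append(len(seqs))
            seqs.append(apply_variant(ref_seq, window, variant))
            regions.append(window)
        jobs.append((ref_rows, alt_rows, windows))

    X = builder.feature_matrix(seqs, regions)
    scores = model.predict(X)

    out: list[AlleleScores] = []
    for ref_rows, alt_rows, windows in jobs:
        ref_scores = scores[ref_rows]
        alt_scores = scores[alt_rows]
        i_ref = int(np.argmax(ref_scores))
        i_alt = int(np.argmax(alt_scores))
        out.append(
            AlleleScores(
                float(ref_scores[i_ref]),
                float(alt_scores[i_alt]),
                windows[i_ref],
                windows[i_alt],
            )
        )
    return out


def _make_call(
    prime_value: float,
    zscore: float | None,
    variant_class: str,
    thresholds: Thresholds,
) -> str:
    mode = thresholds.mode
    if mode == "auto":
        mode = "zscore" if zscore is not None else "prime"
    if mode == "zscore":
        if zscore is None:
            raise ValueError("z-score mode requires a background distribution")
        significant = abs(zscore) >= thresholds.z_for(variant_class)
    elif mode == "prime":
        significant = abs(prime_value) >= thresholds.prime_abs
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    if not significant or prime_value == 0:
        return "neutral"
    return "gain" if prime_value > 0 else "loss"


def score_variants(
    model: CrmModel,
    genome: GenomeStore,
    builder: FeatureBuilder,
    variants: Sequence[Variant],
    background: BackgroundDist | dict[str, BackgroundDist] | None = None,
    thresholds: Thresholds | None = None,
    fractions: Sequence[float] = WINDOW_FRACTIONS,
) -> list[PrimeResult]:
    """PRIME scores for a batch of variants (one batched model evaluation)."""
    thresholds = thresholds or Thresholds()
    allele_scores = _batch_allele_scores(model, genome, builder, variants, fractions)
    results: list[PrimeResult] = []
    for variant, scores in zip(variants, allele_scores):
        prime_value = scores.alt_score - scores.ref_score
        bg = background
        if isinstance(background, dict):
            bg = background.get(variant.variant_class)
        zscore = bg.zscore(prime_value) if bg is not None else None
        call = _make_call(prime_value, zscore, variant.variant_class, thresholds)
        results.append(
            PrimeResult(
                variant=variant,
                model_name=model.name,
                ref_score=scores.ref_score,
                alt_score=scores.alt_score,
                prime=prime_value,
                zscore=zscore,
                call=call,
                best_window=scores.alt_window,
            )
        )
    return results


def prime(
    model: CrmModel,
    genome: GenomeStore,
    builder: FeatureBuilder,
    variant: Variant,
    background: BackgroundDist | None = None,
    thresholds: Thresholds | None = None,
) -> PrimeResult:
    """PRIME score of a single variant."""
    return score_variants(model, genome, builder, [variant], background, thresholds)[0]


def fit_background_dist(
    model: CrmModel,
    genome: GenomeStore,
    builder: FeatureBuilder,
    control_variants: Sequence[Variant],
    variant_class: str,
    min_controls: int = 100,
) -> BackgroundDist:
    """Empirical PRIME distribution from control variants of one class."""
    controls = [v for v in control_variants if v.variant_class == variant_class]
    if len(controls) < min_controls:
        raise ValueError(
            f"need >= {min_controls} control {variant_class}s, got {len(controls)}"
        )
    results = score_variants(model, genome, builder, controls)
    return BackgroundDist(
        model.name, variant_class, np.array([r.prime for r in results])
    )


def saturation_scan(
    model: CrmModel,
    genome: GenomeStore,
    builder: FeatureBuilder,
    region: Region,
    background: BackgroundDist | None = None,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Score every possible substitution in the region (3 rows per position).

    Returns a DataFrame with columns position (0-based), ref, alt,
    ref_score, alt_score, prime, zscore, call.  Positions whose reference
    base is N are skipped (logged).
    """
    variants: list[Variant] = []
    n_skipped = 0
    for pos in range(region.start, region.end):
        ref = genome.base_at(region.contig, pos)
        if ref not in BASES:
            n_skipped += 1
            continue
        for alt in BASES:
            if alt != ref:
                variants.append(Variant(region.contig, pos, ref, alt))
    if n_skipped:
        logger.info("saturation: skipped %d N positions", n_skipped)
    results = score_variants(
        model, genome, builder, variants, background, thresholds
    )
    return pd.DataFrame(
        {
            "position": [r.variant.pos for r in results],
            "ref": [r.variant.ref_allele for r in results],
            "alt": [r.variant.alt_allele for r in results],
            "ref_score": [r.ref_score for r in results],
            "alt_score": [r.alt_score for r in results],
            "prime": [r.prime for r in results],
            "zscore": [r.zscore for r in results],
            "call": [r.call for r in results],
        }
    )


def saturation_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-position max |PRIME| (for hotspot plots)."""
    summary = (
        table.assign(abs_prime=table["prime"].abs())
        .groupby("position", as_index=False)["abs_prime"]
        .max()
        .rename(columns={"abs_prime": "max_abs_prime"})
    )
    return summary


def m0_delta(
    pwm_name: str,
    genome: GenomeStore,
    builder: FeatureBuilder,
    variant: Variant,
    window_length: int,
    fractions: Sequence[float] = WINDOW_FRACTIONS,
) -> float:
    """Best-site-score delta (alt - ref) over the same shifted-window grid.

    ``builder`` must be an M0 FeatureBuilder for ``pwm_name``.
    """
    model = m0_model(pwm_name, window_length)
    scores = _batch_allele_scores(model, genome, builder, [variant], fractions)[0]
    return scores.alt_score - scores.ref_score


def m0_deltas(
    pwm_name: str,
    genome: GenomeStore,
    builder: FeatureBuilder,
    variants: Sequence[Variant],
    window_length: int,
    fractions: Sequence[float] = WINDOW_FRACTIONS,
) -> np.ndarray:
    """Batched :func:`m0_delta`."""
    model = m0_model(pwm_name, window_length)
    scored = _batch_allele_scores(model, genome, builder, variants, fractions)
    return np.array([s.alt_score - s.ref_score for s in scored])


def results_to_frame(results: Sequence[PrimeResult]) -> pd.DataFrame:
    """Tabular form of PRIME results (TSV-ready)."""
    return pd.DataFrame(
        {
            "chrom": [r.variant.contig for r in results],
            "pos": [r.variant.pos + 1 for r in results],
            "ref": [r.variant.ref_allele for r in results],
            "alt": [r.variant.alt_allele for r in results],
            "model": [r.model_name for r in results],
            "ref_score": [r.ref_score for r in results],
            "alt_score": [r.alt_score for r in results],
            "prime": [r.prime for r in results],
            "zscore": [r.zscore for r in results],
            "call": [r.call for r in results],
            "best_window": [
                f"{r.best_window.contig}:{r.best_window.start}-{r.best_window.end}"
                for r in results
            ],
        }
    )
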
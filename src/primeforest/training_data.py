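"""Labeled training sets: GC/length-matched negatives and feature matrices.

Model classes and their features:

* M0 — one PWM; the "feature" is its normalized best-site score.
* M1 — motif-cluster scores for an ordered list of PWMs (convention: 10 PWMs
  of the query TF followed by 10 PWMs of co-regulatory TFs).
* M2 — per-track max signalValue of peaks overlapping the region.
* M3 — M1 and M2 features concatenated.

Negatives are sampled genome-wide with the same length and (within a
tolerance) the same GC content as the positives, at a 1:20 ratio by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motif_scoring import (
    BackgroundModel,
    PwmScorer,
    _cluster_dp,
    gap_penalty_rate as _gap_penalty_rate,
)
from .seqdata import (
    GenomeStore,
    PeakTrack,
    Pwm,
    Region,
    extract_sequence,
    gc_fraction,
    seq_to_ints,
)

logger = logging.getLogger(__name__)

MODEL_CLASSES = ("M0", "M1", "M2", "M3")


@dataclass
class FeatureSpec:
    """Ordered feature lists for one model class.

    ``motif_features`` lists PWM names, query-TF motifs first
    (``n_query_motifs`` of them), co-regulatory motifs after.
    """

    motif_features: list[str] = field(default_factory=list)
    track_features: list[str] = field(default_factory=list)
    model_class: str = "M1"
    n_query_motifs: int | None = None

    def __post_init__(self):
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"unknown model class {self.model_class!r}")
        if self.model_class == "M0" and len(self.motif_features) != 1:
            raise ValueError("M0 uses exactly one PWM")
        if self.model_class in ("M0", "M1") and self.track_features:
            raise ValueError(f"{self.model_class} takes no track features")
        if self.model_class == "M2" and self.motif_features:
            raise ValueError("M2 takes no motif features")
        if self.model_class in ("M2", "M3") and not self.track_features:
            raise ValueError(f"{self.model_class} needs track features")
        if self.model_class in ("M1", "M3") and not self.motif_features:
            raise ValueError(f"{self.model_class} needs motif features")
        if self.n_query_motifs is None:
            # convention: half the motifs target the query TF
            self.n_query_motifs = (
                1 if self.model_class == "M0" else len(self.motif_features) // 2
            )

    @property
    def feature_names(self) -> list[str]:
        return list(self.motif_features) + list(self.track_features)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def groups(self) -> dict[str, list[str]]:
        """Feature-name groups for importance summaries."""
        out: dict[str, list[str]] = {}
        if self.motif_features:
            out["query_motifs"] = list(self.motif_features[: self.n_query_motifs])
            coreg = list(self.motif_features[self.n_query_motifs :])
            if coreg:
                out["coreg_motifs"] = coreg
        if self.track_features:
            out["tracks"] = list(self.track_features)
        return out


@dataclass
class LabeledSet:
    """Aligned regions, 0/1 labels and the n x p feature matrix."""

    regions: list[Region]
    labels: np.ndarray
    feature_matrix: np.ndarray
    feature_names: list[str]
    spec: FeatureSpec | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.feature_matrix = np.asarray(self.feature_matrix, dtype=float)
        n = len(self.regions)
        if self.labels.shape != (n,):
            raise ValueError("labels do not align with regions")
        if self.feature_matrix.shape != (n, len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        if np.isnan(self.feature_matrix).any():
            raise ValueError("feature matrix has missing values")

    @property
    def n_positives(self) -> int:
        return int(self.labels.sum())

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.feature_matrix, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(
            0,
            "region",
            [f"{r.contig}:{r.start}-{r.end}" for r in self.regions],
        )
        df.to_csv(path, sep="\t", index=False)


def sample_gc_matched_negatives(
    positives: Sequence[Region],
    genome: GenomeStore,
    ratio: int = 20,
    gc_tolerance: float = 0.02,
    seed: int = 0,
    max_attempts: int = 10_000,
    exclude: Sequence[Region] | None = None,
    max_n_fraction: float = 0.1,
) -> list[Region]:
    """Sample ``ratio * len(positives)`` negatives matched in length and GC.

    Each negative copies the length of a positive drawn with replacement and
    must match that positive's GC fraction within ``gc_tolerance``.  Negatives
    never overlap a positive (or any ``exclude`` region); they may overlap
    each other.  Rejection sampling, deterministic under ``seed``.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if not positives:
        raise ValueError("no positives given")
    rng = np.random.default_rng(seed)
    forbidden = list(positives) + list(exclude or [])
    by_contig: dict[str, list[Region]] = {}
    for region in forbidden:
        by_contig.setdefault(region.contig, []).append(region)

    contigs = list(genome.contigs)
    lengths = np.array([genome.contig_length(c) for c in contigs], dtype=float)
    weights = lengths / lengths.sum()
    pos_gc = [gc_fraction(extract_sequence(genome, p)) for p in positives]

    seen: set[tuple[str, int, int]] = set()
    negatives: list[Region] = []
    n_needed = ratio * len(positives)
    for _ in range(n_needed):
        pick = int(rng.integers(len(positives)))
        want_len = positives[pick].length
        want_gc = pos_gc[pick]
        for attempt in range(max_attempts):
            ci = int(rng.choice(len(contigs), p=weights))
            contig = contigs[ci]
            limit = genome.contig_length(contig) - want_len
            if limit < 0:
                continue
            start = int(rng.integers(limit + 1))
            candidate = Region(contig, start, start + want_len)
            if (candidate.contig, candidate.start, candidate.end) in seen:
                continue
            if any(candidate.overlaps(f) for f in by_contig.get(contig, ())):
                continue
            seq = extract_sequence(genome, candidate)
            ints = seq_to_ints(seq)
            if (ints == 4).mean() > max_n_fraction:
                continue
            if abs(gc_fraction(seq) - want_gc) <= gc_tolerance:
                negatives.append(candidate)
                seen.add((candidate.contig, candidate.start, candidate.end))
                break
        else:
            raise RuntimeError(
                f"could not find a GC-matched negative for GC={want_gc:.3f}, "
                f"length={want_len} within {max_attempts} attempts"
            )
    return negatives


class FeatureBuilder:
    """Computes feature vectors for a FeatureSpec.

    Holds precomputed PWM scoring tables so that scoring many windows (the
    dominant cost of genome scans and variant scoring) reuses them.
    """

    def __init__(
        self,
        spec: FeatureSpec,
        pwms: Mapping[str, Pwm] | Sequence[Pwm] = (),
        tracks: Mapping[str, PeakTrack] | Sequence[PeakTrack] = (),
        bg: BackgroundModel | None = None,
        gap_param: float = 35.0,
        cluster_mode: str = "best",
    ):
        self.spec = spec
        self.bg = bg or BackgroundModel.uniform()
        self.gap_param = gap_param
        self.cluster_mode = cluster_mode
        pwm_map = (
            dict(pwms) if isinstance(pwms, Mapping) else {p.name: p for p in pwms}
        )
        track_map = (
            dict(tracks)
            if isinstance(tracks, Mapping)
            else {t.name: t for t in tracks}
        )
        missing = [n for n in spec.motif_features if n not in pwm_map]
        missing += [n for n in spec.track_features if n not in track_map]
        if missing:
            raise KeyError(f"features not found: {missing}")
        self.scorers = [
            PwmScorer(pwm_map[name], self.bg) for name in spec.motif_features
        ]
        self.tracks = [track_map[name] for name in spec.track_features]

    # -- motif features ----------------------------------------------------
    def motif_vector(self, seq: str) -> np.ndarray:
        ints = seq_to_ints(seq)
        if self.spec.model_class == "M0":
            return np.array([self.scorers[0].best_site_score(ints)])
        out = np.empty(len(self.scorers))
        gamma = (
            _gap_penalty_rate(self.gap_param) if self.cluster_mode == "best" else 0.0
        )
        for j, scorer in enumerate(self.scorers):
            starts, ends, llrs = scorer.hit_arrays(ints)
            out[j] = _cluster_dp(starts, ends, llrs, gamma) if len(starts) else 0.0
        return out

    # -- track features ----------------------------------------------------
    def track_vector(self, region: Region) -> np.ndarray:
        return np.array([track_feature(region, t) for t in self.tracks])

    # -- combined ----------------------------------------------------------
    def features_for(self, seq: str, region: Region | None = None) -> np.ndarray:
        parts = []
        if self.spec.model_class in ("M0", "M1", "M3"):
            parts.append(self.motif_vector(seq))
        if self.spec.model_class in ("M2", "M3"):
            if region is None:
                raise ValueError("track features need the genomic region")
            parts.append(self.track_vector(region))
        return np.concatenate(parts)

    def feature_matrix(
        self,
        seqs: Sequence[str],
        regions: Sequence[Region] | None = None,
    ) -> np.ndarray:
        n = len(seqs)
        X = np.empty((n, self.spec.n_features))
        for i in range(n):
            region = regions[i] if regions is not None else None
            X[i] = self.features_for(seqs[i], region)
        return X

    def feature_matrix_for_regions(
        self, regions: Sequence[Region], genome: GenomeStore
    ) -> np.ndarray:
        seqs = [extract_sequence(genome, r) for r in regions]
        return self.feature_matrix(seqs, regions)


def track_feature(region: Region, track: PeakTrack) -> float:
    """Max signalValue among peaks overlapping the region by >= 1 bp (0 if none)."""
    index = track.interval_index().get(region.contig)
    if index is None:
        return 0.0
    overlapping = index.overlap(region.start, region.end)
    if not overlapping:
        return 0.0
    return max(iv.data[1] for iv in overlapping)


def motif_feature_vector(
    region: Region,
    genome: GenomeStore,
    pwms: Sequence[Pwm],
    bg: BackgroundModel,
    gap_param: float = 35.0,
    cluster_mode: str = "best",
) -> np.ndarray:
    """Cluster score of each PWM on the region's sequence (M1 feature vector)."""
    spec = FeatureSpec(motif_features=[p.name for p in pwms], model_class="M1")
    builder = FeatureBuilder(spec, pwms, bg=bg, gap_param=gap_param,
                             cluster_mode=cluster_mode)
    return builder.motif_vector(extract_sequence(genome, region))


def track_feature_vector(
    region: Region, tracks: Sequence[PeakTrack]
) -> np.ndarray:
    return np.array([track_feature(region, t) for t in tracks])


def assemble_training_set(
    positives: Sequence[Region],
    genome: GenomeStore,
    spec: FeatureSpec,
    pwms: Mapping[str, Pwm] | Sequence[Pwm] = (),
    tracks: Mapping[str, PeakTrack] | Sequence[PeakTrack] = (),
    bg: BackgroundModel | None = None,
    ratio: int = 20,
    gc_tolerance: float = 0.02,
    seed: int = 0,
    negatives: Sequence[Region] | None = None,
    exclude: Sequence[Region] | None = None,
    gap_param: float = 35.0,
    cluster_mode: str = "best",
) -> LabeledSet:
    """Positives + GC/length-matched negatives with features per model class.

    Pass ``negatives`` explicitly to reuse a sampled set; otherwise they are
    drawn via :func:`sample_gc_matched_negatives` (deterministic under seed).
    """
    if spec.model_class == "M0":
        raise ValueError("M0 is not trained; build an M1/M2/M3 set instead")
    if negatives is None:
        negatives = sample_gc_matched_negatives(
            positives,
            genome,
            ratio=ratio,
            gc_tolerance=gc_tolerance,
            seed=seed,
            exclude=exclude,
        )
    regions = list(positives) + list(negatives)
    labels = np.concatenate(
        [np.ones(len(positives), dtype=int), np.zeros(len(negatives), dtype=int)]
    )
    builder = FeatureBuilder(
        spec, pwms, tracks, bg=bg, gap_param=gap_param, cluster_mode=cluster_mode
    )
    X = builder.feature_matrix_for_regions(regions, genome)
    return LabeledSet(regions, labels, X, spec.feature_names, spec=spec)
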
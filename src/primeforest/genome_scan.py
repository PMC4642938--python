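"""Genome-wide sliding-window CRM prediction.

Windows have the model's window length (the mean positive training-region
length) and consecutive windows overlap by 200 bp.  Tail windows shorter
than half the window length are dropped; windows with more than 10% N are
skipped; windows overlapping an exclusion list (typically the training
regions) are dropped before scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .crm_classifier import CrmModel
from .seqdata import GenomeStore, Region, extract_sequence, seq_to_ints
from .training_data import FeatureBuilder

logger = logging.getLogger(__name__)

DEFAULT_OVERLAP = 200
MAX_N_FRACTION = 0.1


@dataclass
class ScanResult:
    windows: list[tuple[Region, float]]
    window_length: int
    step: int

    def __post_init__(self):
        self.windows = sorted(self.windows, key=lambda ws: ws[0].sort_key())

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, (region, score) in enumerate(self.windows):
                fh.write(
                    f"{region.contig}\t{region.start}\t{region.end}\t"
                    f"window_{i}\t{score:.6f}\t.\n"
                )


def make_windows(
    genome: GenomeStore, window_length: int, overlap: int = DEFAULT_OVERLAP
) -> list[Region]:
    """Tile every contig with windows of ``window_length`` stepping by
    ``window_length - overlap``; a final partial window is kept iff its
    length is at least half the window length."""
    if window_length <= overlap:
        raise ValueError(
            f"window length ({window_length}) must exceed overlap ({overlap})"
        )
    step = window_length - overlap
    windows: list[Region] = []
    for contig, seq in genome.contigs.items():
        n = len(seq)
        start = 0
        while start < n:
            end = min(start + window_length, n)
            if end - start == window_length or (end - start) * 2 >= window_length:
                windows.append(Region(contig, start, end))
            if end == n:
                break
            start += step
    return windows


def scan_genome(
    model: CrmModel,
    genome: GenomeStore,
    builder: FeatureBuilder,
    exclude: Sequence[Region] = (),
    overlap: int = DEFAULT_OVERLAP,
) -> ScanResult:
    """Score every window of the genome with the model.

    Windows overlapping any ``exclude`` region (>= 1 bp) are dropped, as are
    windows with more than 10% N.  Feature extraction and prediction are
    batched across windows.
    """
    windows = make_windows(genome, model.window_length, overlap)
    exclude_by_contig: dict[str, list[Region]] = {}
    for region in exclude:
        exclude_by_contig.setdefault(region.contig, []).append(region)

    kept: list[Region] = []
    seqs: list[str] = []
    n_dropped_excluded = 0
    n_dropped_n = 0
    for window in windows:
        if any(window.overlaps(e) for e in exclude_by_contig.get(window.contig, ())):
            n_dropped_excluded += 1
            continue
        seq = extract_sequence(genome, window)
        if (seq_to_ints(seq) == 4).mean() > MAX_N_FRACTION:
            n_dropped_n += 1
            continue
        kept.append(window)
        seqs.append(seq)
    if n_dropped_excluded or n_dropped_n:
        logger.info(
            "scan: dropped %d excluded and %d N-rich windows",
            n_dropped_excluded,
            n_dropped_n,
        )
    if not kept:
        return ScanResult([], model.window_length, model.window_length - overlap)
    X = builder.feature_matrix(seqs, kept)
    scores = model.predict(X)
    return ScanResult(
        list(zip(kept, scores.tolist())),
        model.window_length,
        model.window_length - overlap,
    )


def top_predictions(scan: ScanResult, n: int = 1000) -> list[Region]:
    """Top-n windows by score; ties broken by genomic order."""
    ranked = sorted(
        scan.windows, key=lambda ws: (-ws[1], ws[0].sort_key())
    )
    return [region for region, _ in ranked[:n]]


@dataclass
class RecoveryReport:
    """Overlap of top predictions with a known region set, with a
    hypergeometric enrichment p-value over the scanned windows."""

    n_top: int
    n_hits: int
    overlap_fraction: float
    p_value: float


def peak_recovery(
    scan: ScanResult, known: Sequence[Region], n_top: int = 1000
) -> RecoveryReport:
    """Fraction of the top-n predicted windows overlapping a known region,
    and the hypergeometric tail probability of that many hits given how many
    scanned windows overlap the known set overall."""
    top = top_predictions(scan, n_top)
    known_by_contig: dict[str, list[Region]] = {}
    for region in known:
        known_by_contig.setdefault(region.contig, []).append(region)

    def hits(regions):
        return sum(
            any(r.overlaps(k) for k in known_by_contig.get(r.contig, ()))
            for r in regions
        )

    n_hits = hits(top)
    total = len(scan.windows)
    total_hits = hits([r for r, _ in scan.windows])
    p = float(hypergeom.sf(n_hits - 1, total, total_hits, len(top)))
    return RecoveryReport(len(top), n_hits, n_hits / max(len(top), 1), p)
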
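"""Cross-sample chromatin-activity specificity of regulatory regions.

A region's activity score under one sample's peak track (e.g. H3K27Ac
broadPeak) is the peak signal multiplied by the fraction of the *peak*
length overlapping the region, averaged when several peaks overlap.  Given
many samples, per-region z-scores across samples quantify how exclusive a
region's activity is to one sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .seqdata import PeakTrack, Region


def region_activity_score(region: Region, track: PeakTrack) -> float:
    """Mean over overlapping peaks of signal * (overlap length / peak length);
    0.0 when no peak overlaps."""
    index = track.interval_index().get(region.contig)
    if index is None:
        return 0.0
    overlapping = index.overlap(region.start, region.end)
    if not overlapping:
        return 0.0
    contributions = []
    for iv in overlapping:
        peak, signal = iv.data
        overlap = min(region.end, peak.end) - max(region.start, peak.start)
        contributions.append(signal * overlap / peak.length)
    return float(np.mean(contributions))


@dataclass
class ActivityMatrix:
    """Regions x samples activity scores and per-region cross-sample z-scores.

    Rows with zero standard deviation get an all-zero z row and are flagged
    in ``degenerate_rows``.  Sample (n-1) standard deviation.
    """

    regions: list[Region]
    samples: list[str]
    scores: np.ndarray
    zscores: np.ndarray
    degenerate_rows: np.ndarray

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        labels = [f"{r.contig}:{r.start}-{r.end}" for r in self.regions]
        return (
            pd.DataFrame(self.scores, index=labels, columns=self.samples),
            pd.DataFrame(self.zscores, index=labels, columns=self.samples),
        )


def activity_zscores(
    regions: Sequence[Region], tracks: Sequence[PeakTrack]
) -> ActivityMatrix:
    """Score every region against every sample track and z-score per region
    across samples."""
    if len(tracks) < 2:
        raise ValueError("need at least 2 sample tracks for cross-sample z-scores")
    scores = np.array(
        [[region_activity_score(r, t) for t in tracks] for r in regions]
    )
    means = scores.mean(axis=1, keepdims=True)
    sds = scores.std(axis=1, ddof=1, keepdims=True)
    degenerate = (sds[:, 0] == 0)
    safe_sds = np.where(sds == 0, 1.0, sds)
    zscores = (scores - means) / safe_sds
    zscores[degenerate] = 0.0
    return ActivityMatrix(
        list(regions), [t.name for t in tracks], scores, zscores, degenerate
    )
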
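"""Markov background model, PWM best-hit scoring, and motif-cluster scoring.

Two scores feed the classifiers:

* :func:`best_site_score` — the single-PWM baseline (model class M0): the
  best log-likelihood-ratio window on either strand, min-max normalized to
  [0, 1] against the best and worst raw scores achievable by the PWM.
* :func:`cluster_score` — a Cluster-Buster-style motif-cluster score: the
  best-scoring local run of non-overlapping PWM hits, where each candidate
  hit contributes its log-likelihood ratio against the background and each
  background nucleotide between hits inside the cluster costs
  ``gamma = log(1 + 1/gap_param)`` nats (a geometric gap-length model with
  mean ``gap_param``).  The score is local (Smith-Waterman style, floored at
  zero), so every sequence gets a score even when no placement beats the
  background.

All log-likelihood ratios are computed against the order-0 stationary
distribution of the background model, which keeps hit scores
position-independent; the order-1 transitions are retained for sequence
simulation.  Natural log throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seqdata import Pwm, seq_to_ints

# llr assigned to an N base inside a PWM window: forbids hits through Ns
# without producing -inf arithmetic.
_N_PENALTY = -50.0


@dataclass
class BackgroundModel:
    """Order-0/1 Markov model of background DNA.

    ``initial`` holds the stationary nucleotide frequencies; ``transition``
    the 4x4 row-stochastic conditional probabilities (for order 0 every row
    equals ``initial``).
    """

    order: int
    initial: np.ndarray
    transition: np.ndarray

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if self.order not in (0, 1):
            raise ValueError("order must be 0 or 1")
        if abs(self.initial.sum() - 1) > 1e-9:
            raise ValueError("initial probabilities must sum to 1")
        if np.abs(self.transition.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("transition rows must sum to 1")
        if (self.initial <= 0).any() or (self.transition <= 0).any():
            raise ValueError("all background probabilities must be > 0")

    @property
    def base_probs(self) -> np.ndarray:
        """Order-0 (stationary) nucleotide distribution used for llr scoring."""
        return self.initial

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(0, np.full(4, 0.25), np.full((4, 4), 0.25))

    @classmethod
    def from_gc(cls, gc: float) -> "BackgroundModel":
        if not 0 < gc < 1:
            raise ValueError("gc must be in (0, 1)")
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return cls(0, p, np.tile(p, (4, 1)))


def _stationary(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    values, vectors = np.linalg.eig(transition.T)
    idx = int(np.argmin(np.abs(values - 1.0)))
    pi = np.real(vectors[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def fit_background(sequences: Iterable[str] | str, order: int = 1) -> BackgroundModel:
    """Fit a Markov background from sequences (dinucleotide counts, +1 smoothing).

    The initial distribution is the stationary distribution of the fitted
    transition matrix.  N bases break the dinucleotide chain.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    counts = np.ones((4, 4), dtype=float)  # +1 smoothing
    total = 0
    for seq in sequences:
        ints = seq_to_ints(seq)
        total += len(ints)
        valid = ints < 4
        a, b = ints[:-1], ints[1:]
        ok = valid[:-1] & valid[1:]
        np.add.at(counts, (a[ok], b[ok]), 1.0)
    if total == 0:
        raise ValueError("no input sequence")
    transition = counts / counts.sum(axis=1, keepdims=True)
    initial = _stationary(transition)
    if order == 0:
        return BackgroundModel(0, initial, np.tile(initial, (4, 1)))
    return BackgroundModel(1, initial, transition)


@dataclass(frozen=True)
class MotifHit:
    """A candidate PWM placement with positive llr against the background."""

    pwm_name: str
    start: int
    end: int
    strand: str
    llr: float


class PwmScorer:
    """Precomputed scoring tables for one PWM against one background.

    Scans both strands by scoring the forward llr table and the
    reverse-complemented table against the same (forward) sequence encoding.
    The min-max normalization bounds are strand-independent because each
    column of the reverse-complement table is a permutation of a forward
    column.
    """

    def __init__(self, pwm: Pwm, bg: BackgroundModel):
        self.pwm = pwm
        bg0 = bg.base_probs
        llr = np.log(pwm.probs) - np.log(bg0)[None, :]
        self.length = len(pwm)
        # 5th column handles N bases
        self.fwd = np.column_stack([llr, np.full(self.length, _N_PENALTY)])
        self.rev = self.fwd[::-1][:, [3, 2, 1, 0, 4]]
        self.raw_max = float(llr.max(axis=1).sum())
        self.raw_min = float(llr.min(axis=1).sum())

    def _window_scores(self, table: np.ndarray, ints: np.ndarray) -> np.ndarray:
        m = self.length
        n = len(ints)
        if n < m:
            raise ValueError(f"sequence ({n} nt) shorter than PWM ({m} nt)")
        w = n - m + 1
        acc = table[0][ints[:w]].astype(float)
        for i in range(1, m):
            acc += table[i][ints[i : i + w]]
        return acc

    def strand_scores(self, ints: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self._window_scores(self.fwd, ints), self._window_scores(self.rev, ints)

    def best_site_score(self, ints: np.ndarray) -> float:
        fwd, rev = self.strand_scores(ints)
        raw = max(float(fwd.max()), float(rev.max()))
        span = self.raw_max - self.raw_min
        if span <= 0:  # degenerate PWM: every sequence scores the same
            return 1.0
        return float(np.clip((raw - self.raw_min) / span, 0.0, 1.0))

    def hit_arrays(
        self, ints: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, llrs) of positive-llr placements, both strands pooled.

        Array form of :meth:`positive_hits` for the scoring hot path.
        """
        fwd, rev = self.strand_scores(ints)
        pf = np.nonzero(fwd > 0)[0]
        pr = np.nonzero(rev > 0)[0]
        starts = np.concatenate([pf, pr])
        llrs = np.concatenate([fwd[pf], rev[pr]])
        return starts, starts + self.length, llrs

    def positive_hits(self, ints: np.ndarray) -> list[MotifHit]:
        """All placements with llr > 0 on either strand."""
        fwd, rev = self.strand_scores(ints)
        hits = []
        for scores, strand in ((fwd, "+"), (rev, "-")):
            for pos in np.nonzero(scores > 0)[0]:
                hits.append(
                    MotifHit(
                        self.pwm.name,
                        int(pos),
                        int(pos) + self.length,
                        strand,
                        float(scores[pos]),
                    )
                )
        return hits


def gap_penalty_rate(gap_param: float) -> float:
    """Per-nucleotide gap cost in nats for an expected gap of ``gap_param``."""
    if gap_param <= 0:
        raise ValueError("gap_param must be > 0")
    return float(np.log1p(1.0 / gap_param))


def best_site_score(pwm: Pwm, seq: str, bg: BackgroundModel) -> float:
    """Best normalized PWM match over both strands, in [0, 1].

    Min-max normalized: 1.0 for the consensus window, 0.0 for the
    worst-scoring achievable window.  No score threshold: the best window is
    always returned (MotifLocator ``-t 0`` semantics).
    """
    return PwmScorer(pwm, bg).best_site_score(seq_to_ints(seq))


def candidate_hits(
    pwms: Sequence[Pwm], seq: str, bg: BackgroundModel
) -> list[MotifHit]:
    """Positive-llr placements of all PWMs on both strands of ``seq``."""
    ints = seq_to_ints(seq)
    hits: list[MotifHit] = []
    for pwm in pwms:
        hits.extend(PwmScorer(pwm, bg).positive_hits(ints))
    return hits


def _cluster_dp(
    starts: np.ndarray, ends: np.ndarray, llrs: np.ndarray, gamma: float
) -> float:
    """Best single-cluster score: max over chains of non-overlapping hits of
    sum(llr) - gamma * (background nt between consecutive hits), floored at 0.

    O(H log H) sweep: with A_i = best_i + gamma * end_i, the best predecessor
    term for a hit starting at s is max(A_i over end_i <= s) - gamma * s.
    """
    order = np.argsort(starts, kind="stable")
    starts, ends, llrs = starts[order], ends[order], llrs[order]
    by_end = np.argsort(ends, kind="stable")
    best = np.empty(len(starts))
    pref_a = -np.inf
    k = 0
    answer = 0.0
    for j in range(len(starts)):
        while k < len(by_end) and ends[by_end[k]] <= starts[j]:
            i = by_end[k]
            pref_a = max(pref_a, best[i] + gamma * ends[i])
            k += 1
        chain = pref_a - gamma * starts[j]
        best[j] = llrs[j] + (chain if chain > 0 else 0.0)
        answer = max(answer, best[j])
    return answer


def _interval_scheduling(starts, ends, llrs) -> float:
    """Max total llr over non-overlapping hits (summed-cluster mode)."""
    return _cluster_dp(starts, ends, llrs, 0.0)


def cluster_score(
    pwms: Sequence[Pwm] | Pwm,
    seq: str,
    bg: BackgroundModel,
    gap_param: float = 35.0,
    mode: str = "best",
) -> float:
    """Motif-cluster score of ``seq`` for one or more PWMs (>= 0).

    ``mode="best"`` (default) returns the best single cluster;
    ``mode="sum"`` the max total llr over all non-overlapping hits (with no
    cluster-score threshold, splitting a chain is free, so the summed mode
    reduces to weighted interval scheduling).
    """
    if isinstance(pwms, Pwm):
        pwms = [pwms]
    hits = candidate_hits(pwms, seq, bg)
    return cluster_score_from_hits(hits, gap_param=gap_param, mode=mode)


def cluster_score_from_hits(
    hits: Sequence[MotifHit], gap_param: float = 35.0, mode: str = "best"
) -> float:
    if not hits:
        return 0.0
    starts = np.array([h.start for h in hits])
    ends = np.array([h.end for h in hits])
    llrs = np.array([h.llr for h in hits])
    if mode == "best":
        return _cluster_dp(starts, ends, llrs, gap_penalty_rate(gap_param))
    if mode == "sum":
        return _interval_scheduling(starts, ends, llrs)
    raise ValueError(f"unknown mode {mode!r}")


def cluster_score_bruteforce(
    hits: Sequence[MotifHit], gap_param: float = 35.0
) -> float:
    """Exhaustive oracle: enumerate every subset of hits, keep chains of
    non-overlapping hits, score = sum(llr) - gamma * sum(gaps); max with 0.

    Exponential in the number of hits; intended for <= ~20 candidate hits.
    """
    gamma = gap_penalty_rate(gap_param)
    hits = sorted(hits, key=lambda h: (h.start, h.end))
    n = len(hits)
    best = 0.0
    for mask in range(1, 1 << n):
        chosen = [hits[i] for i in range(n) if mask >> i & 1]
        ok = all(
            chosen[i].end <= chosen[i + 1].start for i in range(len(chosen) - 1)
        )
        if not ok:
            continue
        score = sum(h.llr for h in chosen) - gamma * sum(
            chosen[i + 1].start - chosen[i].end for i in range(len(chosen) - 1)
        )
        best = max(best, score)
    return best
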
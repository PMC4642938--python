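"""Deterministic synthetic benchmarks: background genomes, implanted motif
clusters, and labeled gain/loss/neutral variant panels.

The generator emulates the structure of a TF-specific enhancer training set:

* an i.i.d. (or first-order Markov) background genome of controllable GC;
* positive CRMs carrying implanted motif-site clusters — homotypic (several
  sites of the query TF) or heterotypic (a query site plus co-factor sites);
* in the heterotypic grammar, "distractor" loci carrying query-only or
  co-factor-only clusters, left unlabeled so sampled negatives can contain
  either kind of site alone;
* unlabeled "gain loci" holding a near-miss site (consensus with one core
  mismatch) whose repair is a labeled gain variant;
* loss variants that break a consensus-matching core base of an implanted
  site, and neutral variants at least 50 bp from any site.

All randomness flows from one seed through named substreams (pwms, genome,
implant, panel, tracks), so each stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .motif_scoring import BackgroundModel, fit_background
from .seqdata import (
    BASES,
    GenomeStore,
    PeakTrack,
    Pwm,
    Region,
    Variant,
    write_genome,
    write_pwms,
    write_regions,
)
from .training_data import FeatureSpec

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])


@dataclass
class BenchmarkConfig:
    """Study conditions for one synthetic benchmark."""

    seed: int = 0
    genome_length: int = 2_000_000
    gc: float = 0.41  # human-like background GC
    n_positives: int = 200
    region_length: int = 300
    sites_per_positive: int = 3
    grammar: str = "homotypic"  # or "heterotypic"
    pwm_length: int = 12
    # mixed column-strength profile: 1 near-invariant core + n_strong strong
    # columns + weak columns (real motifs mix informative and degenerate
    # positions; single-base changes at strong columns move the normalized
    # best-site score appreciably, as for real PWMs)
    consensus_prob: float = 0.96  # strong columns
    weak_prob: float = 0.75  # weak columns
    n_strong_cols: int = 8
    core_prob: float = 0.99999  # near-invariant core column of each motif
    motif_jitter: float = 0.35  # log-normal jitter of derived group motifs
    n_query_motifs: int = 10
    n_coreg_motifs: int = 10
    n_cofactors: int = 3
    site_spacing: int = 15  # mean background gap between implanted sites
    site_temperature: float = 0.6  # sharpening of implanted-site sampling
    # heterotypic query sites are sampled at the motif's natural fidelity
    # (noisier than the sharpened co-factor sites), emulating TFs whose own
    # motif is only weakly enriched in their functional CRMs
    query_site_temperature: float | None = 1.0
    n_gain_variants: int = 30
    n_loss_variants: int = 30
    n_neutral_variants: int = 40
    # unlabeled decayed/partial clusters in the background (negatives may
    # sample them); None -> 100 for homotypic, n_positives per class for
    # heterotypic
    n_distractors_per_class: int | None = None
    # isolated decoy near-sites (query consensus with one broken informative
    # column) scattered through the background, emulating the degenerate
    # binding sites that saturate real genomes and drive PWM false positives
    n_background_decoys: int = 6000
    n_tracks: int = 0
    negative_ratio: int = 20

    def __post_init__(self):
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if self.grammar not in ("homotypic", "heterotypic"):
            raise ValueError(f"unknown grammar {self.grammar!r}")
        for name in (
            "genome_length",
            "n_positives",
            "region_length",
            "sites_per_positive",
            "n_gain_variants",
            "n_loss_variants",
            "n_neutral_variants",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ImplantedSite:
    region: Region  # genomic coordinates, strand records implant orientation
    pwm_name: str
    site_seq: str  # as implanted on the + strand of the genome


@dataclass
class Benchmark:
    """A generated benchmark: genome, truth, features, labeled variants."""

    config: BenchmarkConfig
    genome: GenomeStore
    positives: list[Region]
    sites: list[ImplantedSite]
    gain_loci: list[Region]
    distractor_loci: list[Region]
    variants: list[tuple[Variant, str]]  # (variant, label in {gain, loss, neutral})
    pwms: dict[str, Pwm]
    feature_spec: FeatureSpec
    background: BackgroundModel
    tracks: list[PeakTrack] = field(default_factory=list)
    decoys: list[ImplantedSite] = field(default_factory=list)

    @property
    def query_pwm(self) -> Pwm:
        return self.pwms[self.feature_spec.motif_features[0]]

    def variants_with_label(self, label: str) -> list[Variant]:
        return [v for v, lab in self.variants if lab == label]

    @property
    def negative_exclusion(self) -> list[Region]:
        """Loci negatives must not overlap: positives plus gain loci.

        Distractor loci are deliberately NOT excluded — in the heterotypic
        grammar a lone query or co-factor cluster is a true negative.
        """
        return list(self.positives) + list(self.gain_loci)

    def site_index(self) -> tuple[np.ndarray, np.ndarray]:
        starts = np.array(sorted(s.region.start for s in self.sites))
        ends = np.array(sorted(s.region.end for s in self.sites))
        return starts, ends


def random_pwm(
    name: str,
    length: int,
    consensus_prob: float | Sequence[float] = 0.85,
    rng: np.random.Generator | None = None,
    core_prob: float | None = None,
    base_probs: np.ndarray | None = None,
    n_strong: int = 0,
    weak_prob: float | None = None,
) -> Pwm:
    """A PWM with a random consensus and a mixed column-strength profile.

    Real motifs mix column strengths; three tiers are modeled:

    * one near-invariant **core** column (``core_prob``) at the center — as
      for real binding-site cores, mutating it effectively destroys a site;
    * ``n_strong`` **strong** columns at ``consensus_prob``;
    * remaining **weak** columns at ``weak_prob`` (defaults to
      ``consensus_prob`` for a flat profile).

    Strong/weak roles are shuffled per PWM.  ``base_probs`` biases the
    consensus draw (e.g. to the genome's base composition, so implanted
    sites do not shift a region's GC away from the background).
    """
    rng = rng or np.random.default_rng()
    if base_probs is None:
        consensus = rng.integers(0, 4, size=length)
    else:
        consensus = rng.choice(4, size=length, p=base_probs)
    core = length // 2 if core_prob is not None else -1
    others = [i for i in range(length) if i != core]
    roles = rng.permutation(len(others))
    probs = np.empty((length, 4))
    for k, col in enumerate(others):
        cp = (
            consensus_prob
            if (weak_prob is None or roles[k] < n_strong)
            else weak_prob
        )
        probs[col] = (1 - cp) / 3
        probs[col, consensus[col]] = cp
    if core >= 0:
        probs[core] = (1 - core_prob) / 3
        probs[core, consensus[core]] = core_prob
    return Pwm.from_probs(name, probs)


def derive_pwm(
    base: Pwm, name: str, rng: np.random.Generator, jitter: float = 0.35
) -> Pwm:
    """A noisy derivative of a PWM (log-normal per-cell jitter, renormalized).

    Emulates a motif collection holding several similar PWMs for one TF: the
    derivatives score the same sites with slightly different strengths.
    """
    probs = base.probs * np.exp(rng.normal(0.0, jitter, size=base.probs.shape))
    probs /= probs.sum(axis=1, keepdims=True)
    return Pwm.from_probs(name, probs)


def sample_site(
    pwm: Pwm, rng: np.random.Generator, temperature: float = 1.0
) -> str:
    """Draw one site sequence from the PWM's probability rows.

    ``temperature`` < 1 sharpens the distribution (probs ** (1/T),
    renormalized), yielding higher-fidelity sites than i.i.d. draws.
    """
    probs = pwm.probs ** (1.0 / temperature)
    probs /= probs.sum(axis=1, keepdims=True)
    return "".join(BASES[rng.choice(4, p=probs[i])] for i in range(len(pwm)))


def gen_background_genome(
    length: int,
    gc: float,
    order1: BackgroundModel | None = None,
    seed: int = 0,
    contig: str = "chr1",
) -> GenomeStore:
    """An i.i.d. background genome at target GC, or a sample from an
    order-1 model when one is given; deterministic under seed."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if order1 is None or order1.order == 0:
        probs = (
            order1.base_probs
            if order1 is not None
            else np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        )
        ints = rng.choice(4, size=length, p=probs)
    else:
        ints = np.empty(length, dtype=np.int64)
        ints[0] = rng.choice(4, p=order1.initial)
        cum = order1.transition.cumsum(axis=1)
        u = rng.random(length)
        for i in range(1, length):
            ints[i] = np.searchsorted(cum[ints[i - 1]], u[i])
    seq = _BASE_BYTES[ints].tobytes().decode("ascii")
    return GenomeStore({contig: seq})


def _reverse_complement_ints(site_ints: np.ndarray) -> np.ndarray:
    return _COMPLEMENT_IDX[site_ints[::-1]]


def implant_cluster(
    genome: GenomeStore,
    locus: Region,
    pwm_list: Sequence[Pwm],
    n_sites: int,
    spacing: int = 15,
    seed: int = 0,
    temperature: float = 1.0,
) -> tuple[GenomeStore, list[Region]]:
    """Implant ``n_sites`` sampled sites (cycling over ``pwm_list``) into the
    locus of a copy of the genome; returns the edited genome and the
    ground-truth site regions.  Strands are random."""
    rng = np.random.default_rng(seed)
    buffers = {name: bytearray(seq, "ascii") for name, seq in genome.contigs.items()}
    sites = _implant_into_buffer(
        buffers[locus.contig], locus, pwm_list, n_sites, spacing, rng, temperature
    )
    edited = GenomeStore(
        {name: buf.decode("ascii") for name, buf in buffers.items()}
    )
    return edited, [s.region for s in sites]


def _implant_into_buffer(
    buffer: bytearray,
    locus: Region,
    pwm_list: Sequence[Pwm],
    n_sites: int,
    spacing: int,
    rng: np.random.Generator,
    temperature: float | Sequence[float] = 1.0,
) -> list[ImplantedSite]:
    pwms = [pwm_list[i % len(pwm_list)] for i in range(n_sites)]
    if np.isscalar(temperature):
        temps = [float(temperature)] * n_sites
    else:
        temps = [float(temperature[i % len(temperature)]) for i in range(n_sites)]
    site_lengths = [len(p) for p in pwms]
    gaps = [
        int(rng.integers(max(1, spacing // 2), spacing + spacing // 2 + 1))
        for _ in range(n_sites - 1)
    ] if n_sites > 1 else []
    total = sum(site_lengths) + sum(gaps)
    slack = locus.length - total
    if slack < 0:
        raise ValueError(
            f"locus {locus} too small for {n_sites} sites plus spacing"
        )
    offset = locus.start + int(rng.integers(slack + 1))
    sites: list[ImplantedSite] = []
    for i, pwm in enumerate(pwms):
        site = sample_site(pwm, rng, temps[i])
        strand = "+" if rng.random() < 0.5 else "-"
        placed = site
        if strand == "-":
            placed = "".join(
                BASES[_COMPLEMENT_IDX[BASES.index(b)]] for b in reversed(site)
            )
        buffer[offset : offset + len(placed)] = placed.encode("ascii")
        sites.append(
            ImplantedSite(
                Region(locus.contig, offset, offset + len(placed), strand),
                pwm.name,
                placed,
            )
        )
        offset += len(placed)
        if i < len(gaps):
            offset += gaps[i]
    return sites


class _ForbiddenIndex:
    """Merged, margin-expanded intervals for fast 'near a site?' queries."""

    def __init__(self, regions: Sequence[Region], margin: int):
        intervals = sorted((r.start - margin, r.end + margin) for r in regions)
        merged: list[list[int]] = []
        for start, end in intervals:
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        self.starts = np.array([m[0] for m in merged] or [0])
        self.ends = np.array([m[1] for m in merged] or [0])

    def contains(self, pos: int) -> bool:
        idx = int(np.searchsorted(self.starts, pos, side="right")) - 1
        return idx >= 0 and pos < self.ends[idx]


def _break_site_column(
    buffer: bytearray, site: ImplantedSite, pwm: Pwm, column_rank: int = 0
) -> None:
    """Write the PWM's least likely base into one column of an implanted
    site (strand-aware).  ``column_rank`` indexes columns by decreasing
    information content: 0 is the near-invariant core (a deep break that
    kills the site), 1 the strongest ordinary column (a shallow break that
    only weakens it)."""
    order = np.argsort(-pwm.information_content(), kind="stable")
    col = int(order[column_rank])
    offset = col if site.region.strand == "+" else len(pwm) - 1 - col
    worst = BASES[int(pwm.probs[col].argmin())]
    base = (
        worst
        if site.region.strand == "+"
        else BASES[_COMPLEMENT_IDX[BASES.index(worst)]]
    )
    buffer[site.region.start + offset] = ord(base)


def make_benchmark(config: BenchmarkConfig) -> Benchmark:
    """Generate the full benchmark for a config (deterministic)."""
    ss = np.random.SeedSequence(config.seed)
    rng_pwm, rng_genome, rng_implant, rng_panel, rng_tracks = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    # --- PWMs and the feature list (query group first, co-regulatory after).
    # The query group holds the true query motif plus noisy derivatives (a
    # motif collection has several similar PWMs per TF).  In the homotypic
    # grammar the co-regulatory group holds motifs of absent TFs; in the
    # heterotypic grammar it holds the co-factor motifs plus derivatives.
    base_probs = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    query = random_pwm(
        "query_TF", config.pwm_length, config.consensus_prob, rng_pwm,
        core_prob=config.core_prob, base_probs=base_probs,
        n_strong=config.n_strong_cols, weak_prob=config.weak_prob,
    )
    query_group = [query] + [
        derive_pwm(query, f"query_TF_var{i}", rng_pwm, config.motif_jitter)
        for i in range(1, config.n_query_motifs)
    ]
    cofactors = [
        random_pwm(
            f"cofactor_{i}", config.pwm_length, config.consensus_prob, rng_pwm,
            core_prob=config.core_prob, base_probs=base_probs,
            n_strong=config.n_strong_cols, weak_prob=config.weak_prob,
        )
        for i in range(1, config.n_cofactors + 1)
    ]
    if config.grammar == "homotypic":
        coreg_group = [
            random_pwm(
                f"coreg_decoy_{i}", config.pwm_length, config.consensus_prob,
                rng_pwm, core_prob=config.core_prob, base_probs=base_probs,
                n_strong=config.n_strong_cols, weak_prob=config.weak_prob,
            )
            for i in range(1, config.n_coreg_motifs + 1)
        ]
    else:
        coreg_group = list(cofactors)
        i = 0
        while len(coreg_group) < config.n_coreg_motifs:
            base = cofactors[i % len(cofactors)]
            coreg_group.append(
                derive_pwm(
                    base, f"{base.name}_var{i // len(cofactors) + 1}",
                    rng_pwm, config.motif_jitter,
                )
            )
            i += 1
    pwms = {p.name: p for p in query_group + coreg_group}
    spec = FeatureSpec(
        motif_features=[p.name for p in query_group + coreg_group],
        model_class="M1",
        n_query_motifs=len(query_group),
    )

    # --- background genome
    genome0 = gen_background_genome(
        config.genome_length, config.gc, seed=rng_genome.integers(2**31)
    )
    contig = next(iter(genome0.contigs))
    buffer = bytearray(genome0.contigs[contig], "ascii")
    bg = fit_background(genome0.contigs[contig][: min(200_000, config.genome_length)])

    # --- allocate non-overlapping loci slots.  The margin keeps shifted
    # scoring windows (which extend up to ~0.9 window lengths beyond a
    # variant) from reaching a neighboring implanted locus.
    margin = config.region_length
    slot = config.region_length + margin
    if config.n_distractors_per_class is not None:
        n_distract = config.n_distractors_per_class
    elif config.grammar == "homotypic":
        n_distract = 100
    else:
        n_distract = config.n_positives
    # heterotypic: query-only clusters outnumber co-factor-only ones, so
    # rejecting them (which only co-factor features can do) carries most of
    # the impurity reduction, as for TFs whose co-regulatory motifs dominate
    n_distract_query = (
        n_distract if config.grammar == "homotypic" else 2 * n_distract
    )
    n_distract_cof = 0 if config.grammar == "homotypic" else n_distract
    n_loci = (
        config.n_positives
        + config.n_gain_variants
        + n_distract_query
        + n_distract_cof
    )
    n_slots = config.genome_length // slot
    # implant only into GC-typical slots: a locus on an extreme-GC stretch
    # would make length/GC-matched negative sampling needlessly hard
    ints = genome0.contig_ints(contig)
    is_gc = (ints == 1) | (ints == 2)
    cum = np.concatenate([[0], np.cumsum(is_gc)])
    slot_gc = np.array(
        [
            (cum[k * slot + slot] - cum[k * slot]) / slot
            for k in range(n_slots)
        ]
    )
    eligible = np.nonzero(np.abs(slot_gc - config.gc) <= 0.04)[0]
    if n_loci > len(eligible):
        raise ValueError(
            f"genome too small: need {n_loci} loci but only "
            f"{len(eligible)} GC-typical slots"
        )
    slot_ids = eligible[rng_implant.permutation(len(eligible))[:n_loci]]

    def slot_region(slot_id: int) -> Region:
        start = int(slot_id) * slot + margin // 2
        return Region(contig, start, start + config.region_length)

    cursor = 0
    positives = [slot_region(s) for s in slot_ids[cursor : cursor + config.n_positives]]
    cursor += config.n_positives
    gain_loci = [
        slot_region(s) for s in slot_ids[cursor : cursor + config.n_gain_variants]
    ]
    cursor += config.n_gain_variants
    query_distractors = [
        slot_region(s) for s in slot_ids[cursor : cursor + n_distract_query]
    ]
    cursor += n_distract_query
    cofactor_distractors = [
        slot_region(s) for s in slot_ids[cursor : cursor + n_distract_cof]
    ]

    # --- implant positives.  Homotypic: sites_per_positive query sites.
    # Heterotypic: one query site amid the co-factor trio, so both the
    # query-TF and the co-factor content are required.
    sites: list[ImplantedSite] = []
    positive_sites: list[list[ImplantedSite]] = []
    for i, region in enumerate(positives):
        if config.grammar == "homotypic":
            cluster_pwms: Sequence[Pwm] = [query]
            n_sites = config.sites_per_positive
            temps: float | Sequence[float] = config.site_temperature
        else:
            # one query site amid the full co-factor trio: the query motif
            # is individually weak relative to the co-factor content, as for
            # TFs whose co-regulatory motifs dominate the classifier
            rotated = [cofactors[(i + k) % len(cofactors)] for k in range(3)]
            cluster_pwms = [rotated[0], query, rotated[1], rotated[2]]
            n_sites = 4
            q_temp = (
                config.query_site_temperature
                if config.query_site_temperature is not None
                else config.site_temperature
            )
            temps = [
                config.site_temperature, q_temp,
                config.site_temperature, config.site_temperature,
            ]
        implanted = _implant_into_buffer(
            buffer, region, cluster_pwms, n_sites, config.site_spacing,
            rng_implant, temps,
        )
        sites.extend(implanted)
        positive_sites.append(implanted)

    # --- distractors: unlabeled decayed clusters in the background.
    # Homotypic: full positive-like clusters whose first site carries either
    # a deep (core) or a shallow (strong-column) break — decayed CRMs of
    # varying severity.  Sampled as negatives they spread the learned
    # decision thresholds densely between "intact cluster" and "one
    # functional site short", which is what makes the classifier respond
    # gradually to single-base damage anywhere in a site.  Heterotypic:
    # query-only and co-factor-only clusters, so neither motif group alone
    # is sufficient.
    n_partial = max(config.sites_per_positive - 1, 1)
    for i, region in enumerate(query_distractors):
        if config.grammar == "homotypic":
            implanted = _implant_into_buffer(
                buffer, region, [query], config.sites_per_positive,
                config.site_spacing, rng_implant, config.site_temperature,
            )
            # one third shallow (strong-column) breaks, two thirds deep
            # (core) breaks: the shallow tier pins the top of the learned
            # threshold band just below intact clusters while keeping
            # near-positive negatives rare enough not to erode ranking
            _break_site_column(
                buffer, implanted[0], query,
                column_rank=1 if i % 3 == 0 else 0,
            )
        else:
            implanted = _implant_into_buffer(
                buffer, region, [query], 1,
                config.site_spacing, rng_implant, config.site_temperature,
            )
        sites.extend(implanted)
    for i, region in enumerate(cofactor_distractors):
        trio = [cofactors[(i + k) % len(cofactors)] for k in range(3)]
        implanted = _implant_into_buffer(
            buffer, region, trio, 3,
            config.site_spacing, rng_implant, config.site_temperature,
        )
        sites.extend(implanted)

    # --- gain loci: a real partial cluster plus one near-miss query site
    # (a sampled site whose near-invariant core carries the wrong base, so
    # the site is effectively dead until the gain variant repairs it)
    miss_col = config.pwm_length // 2
    consensus_base = query.consensus()[miss_col]
    miss_base = BASES[int(query.probs[miss_col].argmin())]
    gain_variants: list[Variant] = []
    for i, region in enumerate(gain_loci):
        if config.grammar == "homotypic":
            context_pwms: Sequence[Pwm] = [query]
            n_context = max(config.sites_per_positive - 1, 1)
        else:
            # the co-factor trio only; the repaired near-miss supplies the
            # missing query site
            context_pwms = [cofactors[(i + k) % len(cofactors)] for k in range(3)]
            n_context = 3
        implanted = _implant_into_buffer(
            buffer, region, context_pwms, n_context, config.site_spacing,
            rng_implant, config.site_temperature,
        )
        sites.extend(implanted)
        site = sample_site(query, rng_implant, config.site_temperature)
        near_miss = site[:miss_col] + miss_base + site[miss_col + 1 :]
        # place the near-miss right after the context cluster (+ strand)
        last_end = max(s.region.end for s in implanted)
        gap = int(rng_implant.integers(5, config.site_spacing + 1))
        start = last_end + gap
        if start + len(near_miss) > region.end:
            start = region.end - len(near_miss)
        buffer[start : start + len(near_miss)] = near_miss.encode("ascii")
        sites.append(
            ImplantedSite(
                Region(contig, start, start + len(near_miss), "+"),
                query.name,
                near_miss,
            )
        )
        pos = start + miss_col
        gain_variants.append(Variant(contig, pos, miss_base, consensus_base))

    # --- background decoy near-sites: the query consensus with one broken
    # informative column, isolated in the background.  They emulate the
    # degenerate motif matches that saturate real genomes: invisible to the
    # cluster-level classifier, but a single substitution repairing the
    # broken column produces a large single-PWM (M0) score change.
    decoys: list[ImplantedSite] = []
    if config.n_background_decoys:
        all_loci = (
            positives + gain_loci + query_distractors + cofactor_distractors
        )
        # decoys stay well clear of implanted loci: strict control-SNV
        # panels exclude a one-region-length neighborhood of every cluster
        # site, and decoys placed inside that ring would be unreachable
        locus_index = _ForbiddenIndex(all_loci, margin=400)
        info_order = np.argsort(-query.information_content(), kind="stable")
        consensus = query.consensus()
        occupied: set[int] = set()
        max_tries = config.n_background_decoys * 50
        tries = 0
        while len(decoys) < config.n_background_decoys and tries < max_tries:
            tries += 1
            pos = int(rng_implant.integers(500, config.genome_length - 500))
            # keep decoys >= ~150 bp apart: the cluster gap penalty then
            # keeps chains of decoys well below the classifier boundary
            cell = pos // 75
            if occupied & {cell - 2, cell - 1, cell, cell + 1, cell + 2}:
                continue
            if locus_index.contains(pos) or locus_index.contains(
                pos + config.pwm_length
            ):
                continue
            # break the near-invariant core: the decoy is then invisible
            # to cluster scoring, but repairing it is a large M0 score gain
            col = int(info_order[0])
            worst = BASES[int(query.probs[col].argmin())]
            broken = consensus[:col] + worst + consensus[col + 1 :]
            buffer[pos : pos + len(broken)] = broken.encode("ascii")
            decoys.append(
                ImplantedSite(
                    Region(contig, pos, pos + len(broken), "+"),
                    query.name,
                    broken,
                )
            )
            occupied.add(cell)

    genome = GenomeStore({contig: buffer.decode("ascii")})

    # --- loss variants: break a consensus-matching core base of an
    # implanted query site (several sites of one positive may be used)
    loss_variants: list[Variant] = []
    candidates = [
        site
        for implanted in positive_sites
        for site in implanted
        if site.pwm_name == query.name
    ]
    order = rng_panel.permutation(len(candidates))
    for idx in order:
        if len(loss_variants) >= config.n_loss_variants:
            break
        variant = _site_breaking_variant(
            candidates[int(idx)], pwms[candidates[int(idx)].pwm_name], genome
        )
        if variant is not None:
            loss_variants.append(variant)
    if len(loss_variants) < config.n_loss_variants:
        raise RuntimeError("could not construct the requested number of loss variants")

    # --- neutral variants: >= 50 bp from every implanted site
    forbidden = _ForbiddenIndex([s.region for s in sites], margin=50)
    neutral_variants = sample_neutral_snvs(
        genome, forbidden, config.n_neutral_variants, rng_panel
    )

    variants = (
        [(v, "gain") for v in gain_variants[: config.n_gain_variants]]
        + [(v, "loss") for v in loss_variants]
        + [(v, "neutral") for v in neutral_variants]
    )

    # --- tracks (optional): peaks over a subset of positives plus noise peaks
    tracks: list[PeakTrack] = []
    for t in range(config.n_tracks):
        peaks: list[tuple[Region, float]] = []
        for region in positives:
            if rng_tracks.random() < 0.7:
                pad = int(rng_tracks.integers(20, 80))
                peaks.append(
                    (
                        Region(
                            contig,
                            max(0, region.start - pad),
                            min(config.genome_length, region.end + pad),
                        ),
                        float(rng_tracks.lognormal(2.0, 0.5)),
                    )
                )
        for _ in range(config.n_positives):
            start = int(rng_tracks.integers(config.genome_length - 500))
            peaks.append(
                (
                    Region(contig, start, start + 500),
                    float(rng_tracks.lognormal(0.0, 0.5)),
                )
            )
        tracks.append(PeakTrack(f"track_{t}", peaks))

    return Benchmark(
        config=config,
        genome=genome,
        positives=positives,
        sites=sites,
        gain_loci=gain_loci,
        distractor_loci=query_distractors + cofactor_distractors,
        variants=variants,
        pwms=pwms,
        feature_spec=spec,
        background=bg,
        tracks=tracks,
        decoys=decoys,
    )


def _site_breaking_variant(
    site: ImplantedSite, pwm: Pwm, genome: GenomeStore
) -> Variant | None:
    """SNV turning a consensus-matching base of the implanted site into the
    PWM's least likely base (in genome coordinates, strand-aware).

    Columns are tried in order of decreasing information content, so the
    near-invariant core column is hit whenever it matches consensus.
    """
    length = len(pwm)
    columns = np.argsort(-pwm.information_content(), kind="stable")
    for motif_col in (int(c) for c in columns):
        offset = motif_col if site.region.strand == "+" else length - 1 - motif_col
        genome_base = genome.base_at(site.region.contig, site.region.start + offset)
        motif_base = (
            genome_base
            if site.region.strand == "+"
            else BASES[_COMPLEMENT_IDX[BASES.index(genome_base)]]
        )
        if motif_base != pwm.consensus()[motif_col]:
            continue
        worst = BASES[int(pwm.probs[motif_col].argmin())]
        alt = (
            worst
            if site.region.strand == "+"
            else BASES[_COMPLEMENT_IDX[BASES.index(worst)]]
        )
        if alt == genome_base:
            continue
        return Variant(
            site.region.contig, site.region.start + offset, genome_base, alt
        )
    return None


def sample_neutral_snvs(
    genome: GenomeStore,
    forbidden: _ForbiddenIndex,
    n: int,
    rng: np.random.Generator,
    edge_margin: int = 1000,
) -> list[Variant]:
    """Random SNVs at positions outside the forbidden index."""
    contig = next(iter(genome.contigs))
    length = genome.contig_length(contig)
    out: list[Variant] = []
    while len(out) < n:
        pos = int(rng.integers(edge_margin, length - edge_margin))
        if forbidden.contains(pos):
            continue
        ref = genome.base_at(contig, pos)
        if ref not in BASES:
            continue
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        out.append(Variant(contig, pos, ref, alt))
    return out


def neutral_snv_panel(
    benchmark: Benchmark, n: int, seed: int, margin: int = 50
) -> list[Variant]:
    """Extra neutral background SNVs at least ``margin`` bp from any
    implanted cluster site, e.g. for fitting empirical background
    distributions.  Use a margin of about one window length for strict
    controls whose scoring windows contain no implanted cluster at all.
    Background decoy near-sites are not avoided: they are part of the
    background."""
    forbidden = _ForbiddenIndex([s.region for s in benchmark.sites], margin=margin)
    rng = np.random.default_rng(seed)
    return sample_neutral_snvs(benchmark.genome, forbidden, n, rng)


def write_benchmark(benchmark: Benchmark, outdir) -> None:
    """Write genome FASTA, positives BED, truth-site BED, PWMs and the
    labeled variant panel as plain text."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_genome(benchmark.genome, os.path.join(outdir, "genome.fa"))
    write_regions(benchmark.positives, os.path.join(outdir, "positives.bed"))
    write_regions(
        [s.region for s in benchmark.sites], os.path.join(outdir, "sites.bed")
    )
    write_pwms(list(benchmark.pwms.values()), os.path.join(outdir, "motifs.cb"))
    with open(os.path.join(outdir, "variants.tsv"), "w") as fh:
        fh.write("#chrom\tpos\tref\talt\tlabel\n")
        for variant, label in benchmark.variants:
            fh.write(
                f"{variant.contig}\t{variant.pos + 1}\t{variant.ref_allele}\t"
                f"{variant.alt_allele}\t{label}\n"
            )
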
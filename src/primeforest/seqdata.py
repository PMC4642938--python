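"""Genomic data model and readers for the standard formats.

Everything downstream works on four small value types: :class:`Region`
(0-based half-open intervals), :class:`Variant` (SNVs and small insertions),
:class:`Pwm` (position weight matrices), and :class:`PeakTrack` (scored peak
sets, e.g. ENCODE broadPeak).  Sequences live in a :class:`GenomeStore`.

Coordinate convention: 0-based half-open everywhere.  BED is native; VCF
positions (1-based) are converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

logger = logging.getLogger(__name__)

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# integer encoding used by the scoring kernels: A=0 C=1 G=2 T=3 N=4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_ints(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 (A=0, C=1, G=2, T=3, N/other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C among non-N bases (0.0 for an all-N sequence)."""
    ints = seq_to_ints(seq)
    acgt = int((ints < 4).sum())
    if acgt == 0:
        return 0.0
    gc = int(((ints == 1) | (ints == 2)).sum())
    return gc / acgt


@dataclass(frozen=True)
class Region:
    """0-based half-open genomic interval with an optional strand."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted region: {self}")
        if self.strand not in "+-.":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def sort_key(self):
        return (self.contig, self.start, self.end)


@dataclass(frozen=True)
class Variant:
    """An SNV or small insertion, anchored at a 0-based reference position.

    Insertions follow VCF convention: ``ref`` is the single anchor base and
    ``alt`` is that base followed by the inserted sequence.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative position: {self}")
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or any(b not in BASES for b in allele):
                raise ValueError(f"bad allele in {self}")
        if not (self.is_snv or self.is_insertion):
            raise ValueError(f"not an SNV or insertion: {self}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_insertion(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) > 1
            and self.alt_allele[0] == self.ref_allele
        )

    @property
    def variant_class(self) -> str:
        return "SNV" if self.is_snv else "insertion"


class GenomeStore:
    """In-memory reference genome: contig name -> uppercase A/C/G/T/N string."""

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValueError("genome has no contigs")
        self.contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            seq = seq.upper()
            if any(b not in "ACGTN" for b in set(seq)):
                raise ValueError(f"contig {name!r} has bases outside ACGTN")
            self.contigs[name] = seq
        self._ints_cache: dict[str, np.ndarray] = {}

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def contig_length(self, name: str) -> int:
        return len(self.contigs[name])

    def contig_ints(self, name: str) -> np.ndarray:
        """Cached integer encoding of a whole contig."""
        if name not in self._ints_cache:
            self._ints_cache[name] = seq_to_ints(self.contigs[name])
        return self._ints_cache[name]

    def base_at(self, contig: str, pos: int) -> str:
        return self.contigs[contig][pos]

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


def extract_sequence(genome: GenomeStore, region: Region) -> str:
    """Sequence of a region; reverse-complemented for strand '-'."""
    if region.contig not in genome:
        raise KeyError(f"unknown contig {region.contig!r}")
    if region.end > genome.contig_length(region.contig):
        raise ValueError(
            f"{region} beyond contig end {genome.contig_length(region.contig)}"
        )
    seq = genome.contigs[region.contig][region.start : region.end]
    if region.strand == "-":
        seq = reverse_complement(seq)
    return seq


def read_genome(path) -> GenomeStore:
    """Read a FASTA file into a GenomeStore.

    Lowercase is uppercased; characters outside ACGTN become N.  Duplicate
    record names are an error.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig name {record.id!r}")
        seq = str(record.seq).upper()
        seq = "".join(b if b in "ACGTN" else "N" for b in seq)
        contigs[record.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeStore(contigs)


def write_genome(genome: GenomeStore, path, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# BED / peak files


def read_regions(path) -> list[Region]:
    """Read BED3/BED6 regions (0-based half-open, native)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    regions = []
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) > 5 and row[5] in "+-" else "."
        regions.append(Region(str(row[0]), int(row[1]), int(row[2]), strand))
    return regions


def write_regions(regions: Iterable[Region], path, scores=None) -> None:
    """Write BED; with scores -> BED5+strand, else BED6 with '.' score."""
    with open(path, "w") as fh:
        for i, region in enumerate(regions):
            score = "." if scores is None else f"{scores[i]:.6g}"
            fh.write(
                f"{region.contig}\t{region.start}\t{region.end}\t"
                f"region_{i}\t{score}\t{region.strand if region.strand != '.' else '.'}\n"
            )


@dataclass
class PeakTrack:
    """A named set of scored peaks (signalValue per peak, peaks may overlap)."""

    name: str
    peaks: list[tuple[Region, float]] = field(default_factory=list)

    def __post_init__(self):
        for _, signal in self.peaks:
            if not np.isfinite(signal) or signal < 0:
                raise ValueError(f"bad signalValue {signal} in track {self.name}")

    def interval_index(self) -> dict[str, "intervaltree.IntervalTree"]:
        """Per-contig IntervalTree of (start, end) -> (Region, signal)."""
        if not hasattr(self, "_index"):
            from intervaltree import IntervalTree

            index: dict[str, IntervalTree] = {}
            for region, signal in self.peaks:
                index.setdefault(region.contig, IntervalTree()).addi(
                    region.start, region.end, (region, signal)
                )
            self._index = index
        return self._index


def read_peak_track(path, name: str | None = None) -> PeakTrack:
    """Read broadPeak/narrowPeak (signalValue = column 7).

    Plain BED6 falls back to column 5 ("score") as the signal.
    """
    import os

    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    peaks = []
    for row in df.itertuples(index=False):
        region = Region(str(row[0]), int(row[1]), int(row[2]))
        if len(row) >= 7:
            signal = float(row[6])
        elif len(row) >= 5:
            signal = float(row[4])
        else:
            signal = 0.0
        peaks.append((region, signal))
    track_name = name or os.path.splitext(os.path.basename(str(path)))[0]
    return PeakTrack(track_name, peaks)


def write_peak_track(track: PeakTrack, path) -> None:
    with open(path, "w") as fh:
        for i, (region, signal) in enumerate(track.peaks):
            fh.write(
                f"{region.contig}\t{region.start}\t{region.end}\t"
                f"{track.name}_{i}\t0\t.\t{signal:.6g}\t-1\t-1\n"
            )


# ---------------------------------------------------------------------------
# Variants


def read_variants(path, genome: GenomeStore | None = None) -> list[Variant]:
    """Read SNVs and insertions from a VCF (1-based) or 4-column TSV.

    Deletions, multi-allelic records and (if a genome is given) records whose
    REF does not match the reference are skipped; counts are logged.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        raw = _read_vcf(path)
    else:
        raw = _read_variant_tsv(path)
    variants: list[Variant] = []
    skipped = {"deletion_or_mnv": 0, "multi_allelic": 0, "ref_mismatch": 0}
    for contig, pos0, ref, alts in raw:
        if len(alts) != 1:
            skipped["multi_allelic"] += 1
            continue
        alt = alts[0]
        is_snv = len(ref) == 1 and len(alt) == 1
        is_ins = len(ref) == 1 and len(alt) > 1 and alt[0] == ref
        if not (is_snv or is_ins):
            skipped["deletion_or_mnv"] += 1
            continue
        if genome is not None:
            if contig not in genome or genome.base_at(contig, pos0) != ref:
                skipped["ref_mismatch"] += 1
                logger.warning("REF mismatch at %s:%d (%s)", contig, pos0 + 1, ref)
                continue
        variants.append(Variant(contig, pos0, ref, alt))
    for reason, n in skipped.items():
        if n:
            logger.info("read_variants: skipped %d records (%s)", n, reason)
    return variants


def _read_vcf(path):
    from cyvcf2 import VCF

    out = []
    for record in VCF(path):
        out.append((record.CHROM, record.POS - 1, record.REF, list(record.ALT)))
    return out


def _read_variant_tsv(path):
    """Minimal dialect: chrom, pos (1-based), ref, alt; '#' comments allowed."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError("variant TSV needs >= 4 columns: chrom pos ref alt")
    return [
        (str(r[0]), int(r[1]) - 1, str(r[2]).upper(), str(r[3]).upper().split(","))
        for r in df.itertuples(index=False)
    ]


def write_variants_tsv(variants: Iterable[Variant], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\n")
        for v in variants:
            fh.write(f"{v.contig}\t{v.pos + 1}\t{v.ref_allele}\t{v.alt_allele}\n")


# ---------------------------------------------------------------------------
# PWMs


@dataclass
class Pwm:
    """Position weight matrix over A/C/G/T.

    ``probs`` rows are Laplace-smoothed count rows:
    probs[i] = (counts[i] + pseudocount) / (counts[i].sum() + 4 * pseudocount).
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 1.0
    probs: np.ndarray = field(init=False)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError(f"PWM {self.name}: counts must be L x 4")
        if counts.shape[0] < 4:
            raise ValueError(f"PWM {self.name}: need length >= 4")
        if (counts < 0).any():
            raise ValueError(f"PWM {self.name}: negative counts")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        denom = counts.sum(axis=1) + 4 * self.pseudocount
        if (denom == 0).any():
            raise ValueError(
                f"PWM {self.name}: all-zero count row with zero pseudocount"
            )
        self.counts = counts
        self.probs = (counts + self.pseudocount) / denom[:, None]

    def __len__(self) -> int:
        return self.counts.shape[0]

    @classmethod
    def from_probs(cls, name: str, probs, scale: float = 1000.0) -> "Pwm":
        """Build from a probability matrix (counts = probs * scale, pc ~ 0)."""
        probs = np.asarray(probs, dtype=float)
        return cls(name, probs * scale, pseudocount=1e-9)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (uniform background)."""
        p = self.probs
        return 2.0 + (p * np.log2(p)).sum(axis=1)


def read_pwms(path, pseudocount: float = 1.0) -> list[Pwm]:
    """Read PWMs from JASPAR 4-row count files or Cluster-Buster-style blocks.

    Cluster-Buster style: ``>name`` followed by L whitespace-separated rows of
    4 counts (A C G T).  JASPAR files are parsed via Bio.motifs.
    """
    with open(path) as fh:
        text = fh.read()
    if _looks_like_jaspar(text):
        pwms = []
        from io import StringIO

        for motif in bio_motifs.parse(StringIO(text), "jaspar"):
            counts = np.array(
                [[motif.counts[b][i] for b in BASES] for i in range(motif.length)]
            )
            pwms.append(Pwm(motif.name or motif.matrix_id, counts, pseudocount))
        return pwms
    return _parse_clusterbuster(text, pseudocount)


def _looks_like_jaspar(text: str) -> bool:
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(">"):
            continue
        return line[0] in "ACGT" and not line.split()[0].replace(".", "").isdigit()
    return False


def _parse_clusterbuster(text: str, pseudocount: float) -> list[Pwm]:
    pwms: list[Pwm] = []
    name = None
    rows: list[list[float]] = []

    def flush():
        if name is not None:
            pwms.append(Pwm(name, np.array(rows), pseudocount))

    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0]
            rows = []
        else:
            values = [float(x) for x in line.split()]
            if len(values) != 4:
                raise ValueError(f"PWM row with {len(values)} columns: {line!r}")
            rows.append(values)
    flush()
    if not pwms:
        raise ValueError("no PWMs found")
    return pwms


def write_pwms(pwms: Sequence[Pwm], path) -> None:
    """Write Cluster-Buster-style count blocks."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for row in pwm.counts:
                fh.write("\t".join(f"{x:.6g}" for x in row) + "\n")
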
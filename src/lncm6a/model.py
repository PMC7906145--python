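"""Shared genomic data model.

All coordinates are 0-based half-open on the forward strand; format-specific
conventions (GTF's 1-based closed intervals, MACS tables) are converted at the
I/O boundary and nowhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from intervaltree import IntervalTree

__all__ = [
    "ValidationError",
    "ParseError",
    "ConfigError",
    "Strand",
    "GenomicInterval",
    "TranscriptRecord",
    "TranscriptCatalog",
    "PeakRecord",
    "DiffPeakRecord",
    "ExpressionRecord",
    "BindingPrediction",
    "GeneSetCollection",
    "PositionalClass",
    "HYPER",
    "HYPO",
    "strands_compatible",
]


class ValidationError(ValueError):
    """A record violates a structural invariant."""


class ParseError(ValueError):
    """A line of an input file could not be parsed.

    Carries the 1-based line number where the problem was found.
    """

    def __init__(self, message: str, line_no: Optional[int] = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class ConfigError(ValueError):
    """An invalid configuration value."""


HYPER = "hypermethylated"
HYPO = "hypomethylated"


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"
    UNSTRANDED = "."

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _as_strand(value) -> Strand:
    if isinstance(value, Strand):
        return value
    try:
        return Strand(value)
    except ValueError:
        raise ValidationError(f"invalid strand {value!r}; expected one of +, -, .")


def strands_compatible(a, b) -> bool:
    """True when two stranded features can be considered to lie on the same
    strand; an unstranded feature matches both strands."""
    a, b = _as_strand(a), _as_strand(b)
    if Strand.UNSTRANDED in (a, b):
        return True
    return a == b


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: Strand = Strand.UNSTRANDED

    def __post_init__(self):
        object.__setattr__(self, "strand", _as_strand(self.strand))
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlap in bp, ignoring strand; 0 when on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_bp(other) > 0

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TranscriptRecord:
    """An exon-resolved transcript model (mRNA or lncRNA)."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: tuple
    biotype: str  # "mRNA" | "lncRNA"

    def __post_init__(self):
        object.__setattr__(self, "exons", tuple(self.exons))
        if self.biotype not in ("mRNA", "lncRNA"):
            raise ValidationError(
                f"transcript {self.transcript_id}: biotype must be mRNA or lncRNA, "
                f"got {self.biotype!r}"
            )
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: needs >= 1 exon")
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.interval.chrom or not strands_compatible(
                exon.strand, self.interval.strand
            ):
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon on a different "
                    "chrom/strand than the transcript"
                )
            if not self.interval.contains(exon):
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon "
                    f"[{exon.start}, {exon.end}) outside transcript bounds "
                    f"[{self.interval.start}, {self.interval.end})"
                )
            if prev_end is not None and exon.start < prev_end + 1:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons must be sorted and "
                    "separated by >= 1 bp"
                )
            prev_end = exon.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> Strand:
        return self.interval.strand

    @property
    def exonic_length(self) -> int:
        """Mature transcript length: the sum of exon lengths."""
        return sum(e.length for e in self.exons)

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware genomic coordinate)."""
        if self.strand == Strand.MINUS:
            return self.interval.end - 1
        return self.interval.start

    def introns(self) -> Iterator[GenomicInterval]:
        for left, right in zip(self.exons, self.exons[1:]):
            if right.start > left.end:
                yield GenomicInterval(
                    self.chrom, left.end, right.start, self.strand
                )

    def exon_overlap_bp(self, other: "TranscriptRecord") -> int:
        """Total exon-exon overlap bp with another transcript (strand ignored)."""
        total = 0
        for a in self.exons:
            for b in other.exons:
                total += a.overlap_bp(b)
        return total


class TranscriptCatalog:
    """A collection of transcripts with a per-chromosome interval index."""

    def __init__(self, records: Iterable[TranscriptRecord]):
        self.records: list[TranscriptRecord] = list(records)
        seen: dict[str, TranscriptRecord] = {}
        for rec in self.records:
            if rec.transcript_id in seen:
                raise ValidationError(
                    f"duplicate transcript_id {rec.transcript_id!r}"
                )
            seen[rec.transcript_id] = rec
        self._by_id = seen
        self._trees: dict[str, IntervalTree] = {}
        for rec in self.records:
            tree = self._trees.setdefault(rec.chrom, IntervalTree())
            tree.addi(rec.interval.start, rec.interval.end, rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TranscriptRecord]:
        return iter(self.records)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def get(self, transcript_id: str) -> TranscriptRecord:
        try:
            return self._by_id[transcript_id]
        except KeyError:
            raise KeyError(f"unknown transcript {transcript_id!r}") from None

    def overlapping(
        self,
        query: GenomicInterval,
        biotype: Optional[str] = None,
        same_strand: Optional[bool] = None,
    ) -> list[TranscriptRecord]:
        """Transcripts whose genomic span overlaps ``query`` by >= 1 bp.

        ``same_strand=True`` keeps strand-compatible records only,
        ``same_strand=False`` keeps records on the opposite strand
        (unstranded queries match both ways). Results are sorted by
        (start, transcript_id) for determinism.
        """
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(query.start, query.end)]
        if biotype is not None:
            hits = [r for r in hits if r.biotype == biotype]
        if same_strand is True:
            hits = [r for r in hits if strands_compatible(r.strand, query.strand)]
        elif same_strand is False:
            hits = [
                r
                for r in hits
                if Strand.UNSTRANDED in (r.strand, query.strand)
                or r.strand != query.strand
            ]
        return sorted(hits, key=lambda r: (r.interval.start, r.transcript_id))

    def lncrnas(self) -> list[TranscriptRecord]:
        return [r for r in self.records if r.biotype == "lncRNA"]

    def mrnas(self) -> list[TranscriptRecord]:
        return [r for r in self.records if r.biotype == "mRNA"]


@dataclass(frozen=True)
class PeakRecord:
    """An m6A peak with IP-over-input fold enrichment."""

    interval: GenomicInterval
    fold_enrichment: float
    condition: str = ""
    p_value: Optional[float] = None
    name: str = ""

    def __post_init__(self):
        if not (self.fold_enrichment > 0):
            raise ValidationError(
                f"fold_enrichment must be > 0, got {self.fold_enrichment}"
            )
        if self.p_value is not None and not (0 <= self.p_value <= 1):
            raise ValidationError(f"p_value outside [0,1]: {self.p_value}")


@dataclass(frozen=True)
class DiffPeakRecord:
    """A differentially methylated peak (case vs control)."""

    interval: GenomicInterval
    fold_change: float  # > 0, may be +inf
    direction: str  # hypermethylated | hypomethylated
    lncrna_id: Optional[str] = None

    def __post_init__(self):
        if not (self.fold_change > 0):
            raise ValidationError(f"fold_change must be > 0, got {self.fold_change}")
        if self.direction not in (HYPER, HYPO):
            raise ValidationError(
                f"direction must be {HYPER!r} or {HYPO!r}, got {self.direction!r}"
            )


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-transcript FPKM across samples with a case/control fold change.

    ``fpkm`` maps sample label -> FPKM; ``sample_condition`` maps sample
    label -> condition label. ``fold_change`` is the case/control magnitude
    (direction carried by ``regulation``) and may be +inf when the control
    mean is zero.
    """

    transcript_id: str
    fpkm: Mapping[str, float]
    sample_condition: Mapping[str, str]
    fold_change: float
    p_value: float = 1.0
    regulation: str = "unchanged"  # up | down | unchanged
    biotype: str = "lncRNA"

    def __post_init__(self):
        for sample, value in self.fpkm.items():
            if value < 0:
                raise ValidationError(
                    f"{self.transcript_id}: negative FPKM {value} in {sample}"
                )
        if self.fold_change < 0:
            raise ValidationError(
                f"{self.transcript_id}: fold_change must be >= 0"
            )
        if self.regulation not in ("up", "down", "unchanged"):
            raise ValidationError(
                f"{self.transcript_id}: bad regulation {self.regulation!r}"
            )

    def condition_means(self) -> dict[str, float]:
        sums: dict[str, list[float]] = {}
        for sample, value in self.fpkm.items():
            sums.setdefault(self.sample_condition[sample], []).append(value)
        return {cond: sum(v) / len(v) for cond, v in sums.items()}


@dataclass(frozen=True)
class BindingPrediction:
    """A scored binding prediction (lncRNA->miRNA or miRNA->mRNA)."""

    source_id: str
    target_id: str
    score: float
    layer: str  # "lncRNA-miRNA" | "miRNA-mRNA"

    def __post_init__(self):
        if self.layer not in ("lncRNA-miRNA", "miRNA-mRNA"):
            raise ValidationError(f"unknown binding layer {self.layer!r}")


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional universe, for enrichment tests."""

    sets: dict[str, frozenset]
    universe: Optional[frozenset] = None

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


class PositionalClass(str, Enum):
    """Positional relationship of a lncRNA to the mRNA annotation."""

    EXON_SENSE_OVERLAPPING = "exon_sense_overlapping"
    INTRON_SENSE_OVERLAPPING = "intron_sense_overlapping"
    NATURAL_ANTISENSE = "natural_antisense"
    INTRONIC_ANTISENSE = "intronic_antisense"
    BIDIRECTIONAL = "bidirectional"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value
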
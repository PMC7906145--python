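"""Six-way positional classification of lncRNAs against the mRNA annotation.

Each lncRNA receives exactly one class, the first rule that fires in a
configurable priority order (overlap evidence outranks proximity evidence):

1. ``exon_sense_overlapping``   — >= 1 bp exon-exon overlap with an mRNA on
   the same strand;
2. ``intron_sense_overlapping`` — genomic span overlaps a same-strand mRNA
   but with zero exon-exon bp (the lncRNA sits in introns);
3. ``natural_antisense``        — >= 1 bp exon-exon overlap with an mRNA on
   the opposite strand;
4. ``intronic_antisense``       — the whole lncRNA lies inside one intron of
   an opposite-strand mRNA;
5. ``bidirectional``            — no span overlap with any mRNA, but an
   opposite-strand, divergently oriented mRNA has its TSS within
   ``bidirectional_window`` bp of the lncRNA's TSS;
6. ``intergenic``               — no rule fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    GenomicInterval,
    PositionalClass,
    Strand,
    TranscriptCatalog,
    TranscriptRecord,
    ValidationError,
)

__all__ = ["ClassifyParams", "classify_lncrna", "classify_catalog", "DEFAULT_PRIORITY"]

DEFAULT_PRIORITY = (
    PositionalClass.EXON_SENSE_OVERLAPPING,
    PositionalClass.INTRON_SENSE_OVERLAPPING,
    PositionalClass.NATURAL_ANTISENSE,
    PositionalClass.INTRONIC_ANTISENSE,
    PositionalClass.BIDIRECTIONAL,
)


@dataclass(frozen=True)
class ClassifyParams:
    """Tunables of the positional classifier."""

    bidirectional_window: int = 1000
    priority: tuple = DEFAULT_PRIORITY

    def __post_init__(self):
        if self.bidirectional_window < 0:
            raise ValidationError("bidirectional_window must be >= 0")
        if set(self.priority) != set(DEFAULT_PRIORITY):
            raise ValidationError(
                "priority must be a permutation of the five non-intergenic classes"
            )


def _same_strand(lnc: TranscriptRecord, mrna: TranscriptRecord) -> bool:
    if Strand.UNSTRANDED in (lnc.strand, mrna.strand):
        return True
    return lnc.strand == mrna.strand


def _opposite_strand(lnc: TranscriptRecord, mrna: TranscriptRecord) -> bool:
    if Strand.UNSTRANDED in (lnc.strand, mrna.strand):
        return True
    return lnc.strand != mrna.strand


def _span_overlap(lnc: TranscriptRecord, mrna: TranscriptRecord) -> bool:
    return lnc.interval.overlaps(mrna.interval)


def _within_an_intron(lnc: TranscriptRecord, mrna: TranscriptRecord) -> bool:
    return any(intron.contains(lnc.interval) for intron in mrna.introns())


def _divergent_within_window(
    lnc: TranscriptRecord, mrna: TranscriptRecord, window: int
) -> bool:
    """Head-to-head pair: opposite strands, non-overlapping, transcribing
    away from each other, TSS-to-TSS distance <= window."""
    if _span_overlap(lnc, mrna) or not _opposite_strand(lnc, mrna):
        return False
    if Strand.UNSTRANDED in (lnc.strand, mrna.strand):
        return False  # orientation undefined without strands
    if abs(lnc.tss - mrna.tss) > window:
        return False
    lnc_dir = 1 if lnc.strand == Strand.PLUS else -1
    # divergent: the partner TSS lies behind the lncRNA's direction of travel
    return (mrna.tss - lnc.tss) * lnc_dir < 0


def _rule_fires(
    rule: PositionalClass,
    lnc: TranscriptRecord,
    mrnas: Sequence[TranscriptRecord],
    params: ClassifyParams,
) -> bool:
    if rule == PositionalClass.EXON_SENSE_OVERLAPPING:
        return any(
            _same_strand(lnc, m) and lnc.exon_overlap_bp(m) > 0 for m in mrnas
        )
    if rule == PositionalClass.INTRON_SENSE_OVERLAPPING:
        return any(
            _same_strand(lnc, m)
            and _span_overlap(lnc, m)
            and lnc.exon_overlap_bp(m) == 0
            for m in mrnas
        )
    if rule == PositionalClass.NATURAL_ANTISENSE:
        return any(
            _opposite_strand(lnc, m) and lnc.exon_overlap_bp(m) > 0 for m in mrnas
        )
    if rule == PositionalClass.INTRONIC_ANTISENSE:
        return any(
            _opposite_strand(lnc, m) and _within_an_intron(lnc, m) for m in mrnas
        )
    if rule == PositionalClass.BIDIRECTIONAL:
        if any(_span_overlap(lnc, m) for m in mrnas):
            return False
        return any(
            _divergent_within_window(lnc, m, params.bidirectional_window)
            for m in mrnas
        )
    raise ValidationError(f"unknown classification rule {rule}")


def classify_lncrna(
    lncrna: TranscriptRecord,
    catalog: TranscriptCatalog,
    params: Optional[ClassifyParams] = None,
) -> PositionalClass:
    """Assign the positional class of one lncRNA against the catalog's mRNAs."""
    if lncrna.biotype != "lncRNA":
        raise ValidationError(
            f"classify_lncrna expects a lncRNA, got {lncrna.biotype} "
            f"({lncrna.transcript_id})"
        )
    params = params or ClassifyParams()
    window = params.bidirectional_window
    query = GenomicInterval(
        lncrna.chrom,
        max(0, lncrna.interval.start - window - 1),
        lncrna.interval.end + window + 1,
        lncrna.strand,
    )
    mrnas = catalog.overlapping(query, biotype="mRNA")
    for rule in params.priority:
        if _rule_fires(rule, lncrna, mrnas, params):
            return rule
    return PositionalClass.INTERGENIC


def classify_catalog(
    catalog: TranscriptCatalog,
    params: Optional[ClassifyParams] = None,
    lncrna_ids: Optional[Iterable[str]] = None,
) -> tuple[dict[str, PositionalClass], dict[PositionalClass, float]]:
    """Classify every lncRNA (or a subset) and return per-class proportions.

    Returns ``(assignment, proportions)``; proportions are over the
    classified subset and sum to 1 (empty subset -> empty mappings).
    """
    params = params or ClassifyParams()
    if lncrna_ids is None:
        subset = catalog.lncrnas()
    else:
        subset = [catalog.get(t) for t in lncrna_ids]
    assignment = {
        rec.transcript_id: classify_lncrna(rec, catalog, params) for rec in subset
    }
    if not assignment:
        return {}, {}
    n = len(assignment)
    proportions = {
        cls: sum(1 for v in assignment.values() if v == cls) / n
        for cls in PositionalClass
    }
    return assignment, proportions
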
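"""Peak-to-lncRNA annotation and cross-condition peak-landscape statistics.

An m6A peak is kept only when it overlaps at least ``min_overlap_bp`` of an
exon of at least one lncRNA with a compatible strand (unstranded peaks match
both strands); peaks falling entirely in introns or inside mRNAs are
discarded. A peak overlapping exons of several lncRNAs is annotated to all of
them, so lncRNA-level counts can exceed peak-level counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import (
    GenomicInterval,
    PeakRecord,
    PositionalClass,
    TranscriptCatalog,
    ValidationError,
    strands_compatible,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotatedPeak",
    "PeakVenn",
    "filter_peaks_to_lncrna_exons",
    "peaks_per_lncrna_distribution",
    "compare_peak_sets",
    "match_peaks",
    "fold_enrichment_by_class",
]


@dataclass(frozen=True)
class AnnotatedPeak:
    """A peak together with the lncRNAs whose exons it overlaps."""

    peak: PeakRecord
    overlap_bp: Mapping[str, int]  # lncrna_id -> exonic overlap bp

    def __post_init__(self):
        if not self.overlap_bp:
            raise ValidationError("AnnotatedPeak requires >= 1 host lncRNA")
        for lnc, bp in self.overlap_bp.items():
            if bp < 1:
                raise ValidationError(f"overlap with {lnc} must be >= 1 bp")

    @property
    def lncrna_ids(self) -> tuple:
        return tuple(sorted(self.overlap_bp))


@dataclass(frozen=True)
class PeakVenn:
    """Two-condition peak Venn counts."""

    unique_a: int
    unique_b: int
    shared: int

    @property
    def shared_fraction(self) -> float:
        denom = self.unique_a + self.unique_b + self.shared
        return self.shared / denom if denom else 0.0


def filter_peaks_to_lncrna_exons(
    peaks: Iterable[PeakRecord],
    catalog: TranscriptCatalog,
    min_overlap_bp: int = 1,
) -> list[AnnotatedPeak]:
    """Keep peaks with >= ``min_overlap_bp`` exonic overlap on >= 1 lncRNA."""
    annotated = []
    for peak in peaks:
        hosts: dict[str, int] = {}
        for rec in catalog.overlapping(peak.interval, biotype="lncRNA", same_strand=True):
            bp = sum(peak.interval.overlap_bp(exon) for exon in rec.exons)
            if bp >= min_overlap_bp:
                hosts[rec.transcript_id] = bp
        if hosts:
            annotated.append(AnnotatedPeak(peak=peak, overlap_bp=hosts))
    return annotated


def peaks_per_lncrna_distribution(
    annotated_peaks: Sequence[AnnotatedPeak],
    max_bin: int = 4,
) -> dict[int, float]:
    """Fraction of methylated lncRNAs harboring 1, 2, ..., >= ``max_bin`` peaks.

    Returned keys are peak counts; the key ``max_bin`` aggregates all lncRNAs
    with >= ``max_bin`` peaks. Fractions sum to 1 over methylated lncRNAs.
    """
    counts: dict[str, int] = {}
    for ap in annotated_peaks:
        for lnc in ap.overlap_bp:
            counts[lnc] = counts.get(lnc, 0) + 1
    if not counts:
        return {}
    n = len(counts)
    dist: dict[int, float] = {}
    for c in counts.values():
        key = min(c, max_bin)
        dist[key] = dist.get(key, 0) + 1
    return {k: v / n for k, v in sorted(dist.items())}


def match_peaks(
    peaks_a: Sequence[PeakRecord],
    peaks_b: Sequence[PeakRecord],
    min_overlap_bp: int = 1,
    min_reciprocal_overlap: float = 0.0,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy 1-1 matching of peaks across conditions by descending overlap.

    Two peaks are matchable when they overlap by >= ``min_overlap_bp`` with
    compatible strands and, optionally, reciprocal overlap >= the given
    fraction of both peak lengths. Returns (matched index pairs,
    unmatched a-indices, unmatched b-indices); ties broken by index order so
    the matching is deterministic.
    """
    trees: dict[str, IntervalTree] = {}
    for j, pb in enumerate(peaks_b):
        trees.setdefault(pb.interval.chrom, IntervalTree()).addi(
            pb.interval.start, pb.interval.end, j
        )
    candidates = []
    for i, pa in enumerate(peaks_a):
        tree = trees.get(pa.interval.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(pa.interval.start, pa.interval.end):
            j = iv.data
            pb = peaks_b[j]
            if not strands_compatible(pa.interval.strand, pb.interval.strand):
                continue
            bp = pa.interval.overlap_bp(pb.interval)
            if bp < min_overlap_bp:
                continue
            if min_reciprocal_overlap > 0 and (
                bp < min_reciprocal_overlap * pa.interval.length
                or bp < min_reciprocal_overlap * pb.interval.length
            ):
                continue
            candidates.append((bp, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _bp, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    unmatched_a = [i for i in range(len(peaks_a)) if i not in used_a]
    unmatched_b = [j for j in range(len(peaks_b)) if j not in used_b]
    return pairs, unmatched_a, unmatched_b


def compare_peak_sets(
    peaks_a: Sequence[PeakRecord],
    peaks_b: Sequence[PeakRecord],
    min_overlap_bp: int = 1,
    min_reciprocal_overlap: float = 0.0,
) -> PeakVenn:
    """Two-condition Venn of peak sets under greedy 1-1 overlap matching."""
    pairs, unmatched_a, unmatched_b = match_peaks(
        peaks_a, peaks_b, min_overlap_bp, min_reciprocal_overlap
    )
    return PeakVenn(
        unique_a=len(unmatched_a), unique_b=len(unmatched_b), shared=len(pairs)
    )


def fold_enrichment_by_class(
    annotated_peaks: Sequence[AnnotatedPeak],
    class_assignment: Mapping[str, PositionalClass],
) -> pd.DataFrame:
    """Per-positional-class summary of peak fold enrichments.

    A peak hosted by lncRNAs of several classes contributes once to each of
    those classes. Returns a frame indexed by class with columns
    ``n, median, q1, q3``; classes with no peaks report n=0 and NaN quartiles.
    """
    values: dict[PositionalClass, list[float]] = {c: [] for c in PositionalClass}
    for ap in annotated_peaks:
        classes = set()
        for lnc in ap.overlap_bp:
            if lnc not in class_assignment:
                raise ValidationError(f"no positional class for lncRNA {lnc!r}")
            cls = class_assignment[lnc]
            if not isinstance(cls, PositionalClass):
                cls = PositionalClass(cls)
            classes.add(cls)
        for cls in classes:
            values[cls].append(ap.peak.fold_enrichment)
    rows = []
    for cls in PositionalClass:
        v = np.asarray(values[cls], dtype=float)
        if v.size:
            q1, med, q3 = np.percentile(v, [25, 50, 75])
        else:
            q1 = med = q3 = np.nan
        rows.append({"class": cls.value, "n": v.size, "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(rows).set_index("class")
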
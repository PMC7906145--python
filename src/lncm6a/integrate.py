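"""Differential-methylation / differential-expression summaries and
integration statistics.

Conventions used throughout:

* percentages are rounded half-away-from-zero to 1 decimal place;
* infinite fold changes sort above all finite values, are excluded from
  means and correlations (excluded counts are logged), and are clamped to
  ``max finite + 1`` in cumulative |log2FC| curves;
* lncRNA "length" means the mature (summed exonic) length unless
  ``use_genomic_span`` is requested.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    HYPER,
    HYPO,
    DiffPeakRecord,
    ExpressionRecord,
    GeneSetCollection,
    PeakRecord,
    PositionalClass,
    TranscriptCatalog,
    ValidationError,
)
from .peaks import AnnotatedPeak, match_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "RegulationSummary",
    "LengthBinning",
    "CumulativeCurve",
    "round_pct",
    "call_differential_peaks",
    "summarize_regulation",
    "bin_lengths",
    "chromosome_distribution",
    "mean_fold_change_by_class",
    "join_methylation_expression",
    "correlate_levels",
    "cumulative_log2fc",
    "ddct_fold_change",
    "enrichment_test",
]


def round_pct(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage rounded half-away-from-zero to ``digits`` decimals."""
    if denominator == 0:
        return math.nan
    pct = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-digits)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RegulationSummary:
    """Counts and percentages of the two differential directions."""

    n_total: int
    n_hyper: int  # or n_up for expression
    n_hypo: int  # or n_down
    pct_hyper: float
    pct_hypo: float
    labels: tuple = (HYPER, HYPO)


def summarize_regulation(
    records: Iterable,
    labels: Optional[tuple] = None,
) -> RegulationSummary:
    """Summarize direction labels of differential records.

    Accepts :class:`DiffPeakRecord` (direction hyper/hypo),
    :class:`ExpressionRecord` (regulation up/down; ``unchanged`` rows are
    ignored), or bare label strings. ``labels`` overrides the
    (positive, negative) label pair.
    """
    raw = []
    for rec in records:
        if isinstance(rec, DiffPeakRecord):
            raw.append(rec.direction)
        elif isinstance(rec, ExpressionRecord):
            raw.append(rec.regulation)
        else:
            raw.append(str(rec))
    if labels is None:
        labels = ("up", "down") if ("up" in raw or "down" in raw) else (HYPER, HYPO)
    pos, neg = labels
    n_pos = sum(1 for r in raw if r == pos)
    n_neg = sum(1 for r in raw if r == neg)
    n_total = n_pos + n_neg
    return RegulationSummary(
        n_total=n_total,
        n_hyper=n_pos,
        n_hypo=n_neg,
        pct_hyper=round_pct(n_pos, n_total),
        pct_hypo=round_pct(n_neg, n_total),
        labels=labels,
    )


def call_differential_peaks(
    peaks_a: Sequence[PeakRecord],
    peaks_b: Sequence[PeakRecord],
    min_overlap_bp: int = 1,
    fold_change_floor: Optional[float] = None,
) -> list[DiffPeakRecord]:
    """Minimal ratio-based differential caller for matched peak sets.

    Condition A is the case: matched pairs get ``fold_change =
    larger/smaller enrichment`` with direction hypermethylated when the
    A-side enrichment is >= the B-side. Peaks present in only one condition
    are called in their host condition's direction with infinite fold change
    (or ``fold_change_floor`` when configured). This is a deliberately simple
    stand-in used for synthetic end-to-end runs, not a replication of a
    count-based differential caller.
    """
    pairs, unmatched_a, unmatched_b = match_peaks(peaks_a, peaks_b, min_overlap_bp)
    out = []
    for i, j in pairs:
        pa, pb = peaks_a[i], peaks_b[j]
        hi, lo = max(pa.fold_enrichment, pb.fold_enrichment), min(
            pa.fold_enrichment, pb.fold_enrichment
        )
        fc = hi / lo if lo > 0 else math.inf
        direction = HYPER if pa.fold_enrichment >= pb.fold_enrichment else HYPO
        out.append(
            DiffPeakRecord(interval=pa.interval, fold_change=fc, direction=direction)
        )
    inf_fc = math.inf if fold_change_floor is None else fold_change_floor
    for i in unmatched_a:
        out.append(
            DiffPeakRecord(
                interval=peaks_a[i].interval, fold_change=inf_fc, direction=HYPER
            )
        )
    for j in unmatched_b:
        out.append(
            DiffPeakRecord(
                interval=peaks_b[j].interval, fold_change=inf_fc, direction=HYPO
            )
        )
    return out


_COARSE_BIN = 1000
_FINE_BIN = 200


@dataclass
class LengthBinning:
    """Length histograms of differential lncRNAs, split by direction.

    ``coarse`` bins are 1,000 bp wide from 1 bp upward; ``fine`` bins are
    200 bp wide inside 1-1,000 bp. Both frames carry per-direction counts and
    fractions (fractions over that direction's records in the binning range).
    """

    coarse: pd.DataFrame
    fine: pd.DataFrame
    unresolved: list


def _bin_frame(lengths: dict, width: int, upper: Optional[int]) -> pd.DataFrame:
    rows = []
    for direction, values in lengths.items():
        in_range = [v for v in values if upper is None or v <= upper]
        total = len(in_range)
        binned: dict[int, int] = {}
        for v in in_range:
            b = (v - 1) // width  # length 1 falls in the first bin
            binned[b] = binned.get(b, 0) + 1
        for b, count in sorted(binned.items()):
            rows.append(
                {
                    "direction": direction,
                    "bin_start": b * width + 1,
                    "bin_end": (b + 1) * width,
                    "count": count,
                    "fraction": count / total if total else math.nan,
                }
            )
    return pd.DataFrame(rows, columns=["direction", "bin_start", "bin_end", "count", "fraction"])


def bin_lengths(
    diff_lncrnas: Mapping[str, str],
    catalog: TranscriptCatalog,
    use_genomic_span: bool = False,
) -> LengthBinning:
    """Bin lengths of differentially methylated lncRNAs by direction.

    ``diff_lncrnas`` maps lncRNA id -> direction. Ids absent from the catalog
    are reported in ``unresolved`` rather than silently dropped.
    """
    lengths: dict[str, list[int]] = {}
    unresolved = []
    for lnc_id, direction in sorted(diff_lncrnas.items()):
        if lnc_id not in catalog:
            unresolved.append(lnc_id)
            continue
        rec = catalog.get(lnc_id)
        value = rec.interval.length if use_genomic_span else rec.exonic_length
        lengths.setdefault(direction, []).append(value)
    return LengthBinning(
        coarse=_bin_frame(lengths, _COARSE_BIN, None),
        fine=_bin_frame(lengths, _FINE_BIN, 1000),
        unresolved=unresolved,
    )


def chromosome_distribution(
    diff_records: Sequence[DiffPeakRecord],
) -> pd.DataFrame:
    """Per-chromosome, per-direction fractions of differential records."""
    rows: dict[tuple, int] = {}
    totals: dict[str, int] = {}
    for rec in diff_records:
        chrom = rec.interval.chrom
        if not chrom.startswith("chr"):
            chrom = "chr" + chrom
        rows[(rec.direction, chrom)] = rows.get((rec.direction, chrom), 0) + 1
        totals[rec.direction] = totals.get(rec.direction, 0) + 1
    out = [
        {
            "direction": direction,
            "chrom": chrom,
            "count": count,
            "fraction": count / totals[direction],
        }
        for (direction, chrom), count in sorted(rows.items())
    ]
    return pd.DataFrame(out, columns=["direction", "chrom", "count", "fraction"])


def mean_fold_change_by_class(
    diff_records: Sequence[DiffPeakRecord],
    class_mapping: Mapping[str, PositionalClass],
) -> pd.DataFrame:
    """Mean fold change and SEM per (positional class, direction).

    Records with infinite fold change are excluded (count logged); classes
    with no finite records report NaN with n=0.
    """
    groups: dict[tuple, list[float]] = {}
    n_inf = 0
    for rec in diff_records:
        if rec.lncrna_id is None or rec.lncrna_id not in class_mapping:
            continue
        if math.isinf(rec.fold_change):
            n_inf += 1
            continue
        cls = class_mapping[rec.lncrna_id]
        if not isinstance(cls, PositionalClass):
            cls = PositionalClass(cls)
        groups.setdefault((cls, rec.direction), []).append(rec.fold_change)
    if n_inf:
        logger.info("mean_fold_change_by_class: excluded %d infinite fold changes", n_inf)
    rows = []
    for cls in PositionalClass:
        for direction in (HYPER, HYPO):
            values = np.asarray(groups.get((cls, direction), []), dtype=float)
            if values.size:
                mean = float(values.mean())
                sem = float(values.std(ddof=1) / math.sqrt(values.size)) if values.size > 1 else math.nan
            else:
                mean = sem = math.nan
            rows.append(
                {
                    "class": cls.value,
                    "direction": direction,
                    "n": values.size,
                    "mean_fold_change": mean,
                    "sem": sem,
                }
            )
    return pd.DataFrame(rows)


def join_methylation_expression(
    diff_meth: Mapping[str, str],
    diff_expr: Mapping[str, str],
) -> pd.DataFrame:
    """Cross-tabulate methylation direction against expression regulation.

    ``diff_meth`` maps lncRNA id -> hyper/hypo; ``diff_expr`` maps lncRNA id
    -> up/down. Every lncRNA seen in either table lands in exactly one cell;
    margins labelled ``not_differential`` hold the non-overlapping ids.
    """
    for name, mapping in (("diff_meth", diff_meth), ("diff_expr", diff_expr)):
        ids = list(mapping)
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate ids in {name}")
    meth_levels = [HYPER, HYPO, "not_differential"]
    expr_levels = ["up", "down", "not_differential"]
    table = pd.DataFrame(0, index=meth_levels, columns=expr_levels)
    for lnc in set(diff_meth) | set(diff_expr):
        m = diff_meth.get(lnc, "not_differential")
        e = diff_expr.get(lnc, "not_differential")
        table.loc[m, e] += 1
    table.index.name = "methylation"
    table.columns.name = "expression"
    return table


def correlate_levels(
    x: Mapping[str, float],
    y: Mapping[str, float],
    method: str = "spearman",
) -> tuple[float, float, int]:
    """Correlate two per-lncRNA value maps paired by id.

    Pairs with infinite or missing values are dropped; returns
    (coefficient, p_value, n_pairs_used). Requires n >= 3.
    """
    pairs = [
        (x[k], y[k])
        for k in sorted(set(x) & set(y))
        if math.isfinite(x[k]) and math.isfinite(y[k])
    ]
    n = len(pairs)
    if n < 3:
        raise ValidationError(f"correlation needs >= 3 finite pairs, got {n}")
    xv = np.array([p[0] for p in pairs])
    yv = np.array([p[1] for p in pairs])
    if method == "spearman":
        res = stats.spearmanr(xv, yv)
    elif method == "pearson":
        res = stats.pearsonr(xv, yv)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue), n


@dataclass
class CumulativeCurve:
    """Empirical cumulative |log2FC| curves for m6A vs non-m6A lncRNAs."""

    m6a_values: np.ndarray  # sorted |log2FC|
    m6a_fractions: np.ndarray  # cumulative fractions, nondecreasing 0..1
    non_m6a_values: np.ndarray
    non_m6a_fractions: np.ndarray
    ks_statistic: float
    n_clamped: int


def _abs_log2fc(record: ExpressionRecord) -> float:
    if record.fold_change in (0.0,) or math.isinf(record.fold_change):
        return math.inf
    return abs(math.log2(record.fold_change))


def cumulative_log2fc(
    expression: Sequence[ExpressionRecord],
    m6a_ids: Iterable[str],
) -> CumulativeCurve:
    """Cumulative |log2FC| curves of m6A-modified vs unmodified lncRNAs.

    ``m6a_ids`` is the set of lncRNAs hosting >= 1 exonic m6A peak in either
    condition. Infinite |log2FC| values (infinite or zero fold change) are
    clamped to the maximum finite value + 1 so every lncRNA stays on the
    curve; the clamp count is reported. A two-sample Kolmogorov-Smirnov D
    between the groups is included.
    """
    m6a_ids = set(m6a_ids)
    groups: dict[str, list[float]] = {"m6a": [], "non": []}
    for rec in expression:
        groups["m6a" if rec.transcript_id in m6a_ids else "non"].append(
            _abs_log2fc(rec)
        )
    for name, label in (("m6a", "m6A"), ("non", "non-m6A")):
        if not groups[name]:
            raise ValidationError(f"cumulative_log2fc: the {label} group is empty")
    finite = [v for vs in groups.values() for v in vs if math.isfinite(v)]
    clamp = (max(finite) + 1.0) if finite else 1.0
    n_clamped = sum(1 for vs in groups.values() for v in vs if not math.isfinite(v))
    cleaned = {
        k: np.sort([v if math.isfinite(v) else clamp for v in vs])
        for k, vs in groups.items()
    }
    fractions = {
        k: np.arange(1, len(v) + 1) / len(v) for k, v in cleaned.items()
    }
    d = float(stats.ks_2samp(cleaned["m6a"], cleaned["non"], method="asymp").statistic)
    return CumulativeCurve(
        m6a_values=cleaned["m6a"],
        m6a_fractions=fractions["m6a"],
        non_m6a_values=cleaned["non"],
        non_m6a_fractions=fractions["non"],
        ks_statistic=d,
        n_clamped=n_clamped,
    )


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative qRT-PCR fold change by the 2^-ddCt method."""
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def enrichment_test(
    query_genes: Iterable[str],
    gene_sets: GeneSetCollection,
    universe: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation test against every gene set.

    For each set, p = P(X >= k) with X ~ Hypergeom(N, K, n) where N is the
    universe size, K the set size in the universe, n the query size in the
    universe, and k the overlap. Benjamini-Hochberg adjustment across all
    tested sets; rows sorted by (p, set name).
    """
    if universe is None:
        universe = gene_sets.universe
    if universe is None:
        universe = frozenset().union(*gene_sets.sets.values()) if gene_sets.sets else frozenset()
    universe = frozenset(universe)
    if not universe:
        raise ValidationError("enrichment_test: empty universe")
    query = frozenset(query_genes) & universe
    rows = []
    for name in sorted(gene_sets.sets):
        members = gene_sets.sets[name] & universe
        k = len(query & members)
        K = len(members)
        n = len(query)
        N = len(universe)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    frame = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    if len(frame):
        frame["p_adj"] = stats.false_discovery_control(frame["p"].to_numpy(), method="bh")
    else:
        frame["p_adj"] = []
    return frame.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
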
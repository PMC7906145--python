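"""Synthetic two-condition m6A study generator with known ground truth.

The generator emulates the structure of a paired MeRIP-seq + RNA-seq study of
tumor vs adjacent-normal tissue: an exon-resolved transcript annotation with
lncRNAs planted in each of the six positional classes, per-condition m6A peak
sets with a configurable shared fraction, hyper/hypomethylated differential
peaks, an FPKM matrix with planted differential expression, a planted
methylation-expression correlation (Gaussian copula), planted trans-target
and co-expression-hub pairs, and scored binding tables with unique top-5
selections. Every planted label is recorded in :class:`GroundTruth` so each
downstream stage can be tested for exact recovery.

Geometry is deliberately sparse — one transcript unit per 500 kbp region,
100 regions per synthetic chromosome — so a lncRNA satisfies exactly its
planted positional rule and nothing else.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import (
    HYPER,
    HYPO,
    BindingPrediction,
    ConfigError,
    DiffPeakRecord,
    ExpressionRecord,
    GenomicInterval,
    PeakRecord,
    PositionalClass,
    Strand,
    TranscriptCatalog,
    TranscriptRecord,
)
from . import io as lio
from .networks import ScreenCriteria

__all__ = ["SimConfig", "GroundTruth", "generate_annotation", "generate_peak_sets",
           "generate_expression_matrix", "generate_binding_predictions",
           "generate_full_study", "expression_frame"]

_REGION = 500_000
_REGIONS_PER_CHROM = 100
_ANCHOR_OFFSET = 100_000

_CLASS_ORDER = (
    PositionalClass.EXON_SENSE_OVERLAPPING,
    PositionalClass.INTRON_SENSE_OVERLAPPING,
    PositionalClass.NATURAL_ANTISENSE,
    PositionalClass.INTRONIC_ANTISENSE,
    PositionalClass.BIDIRECTIONAL,
    PositionalClass.INTERGENIC,
)

#: default class mix: sense-exon heavy, few bidirectional, a fifth intergenic,
#: following the positional pie typical of tumor MeRIP profiles.
DEFAULT_CLASS_PROPORTIONS = (0.52, 0.05, 0.12, 0.06, 0.035, 0.215)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of a synthetic study; ``seed`` fixes every random choice."""

    seed: int = 0
    n_mrna: int = 450
    n_lncrna: int = 500
    class_proportions: tuple = DEFAULT_CLASS_PROPORTIONS
    n_peaks_per_condition: tuple = (250, 215)
    shared_peak_fraction: float = 0.375
    peaks_per_host_probs: tuple = (0.91, 0.07, 0.02)  # P(1), P(2), P(3) peaks
    n_diff_peaks: int = 60
    frac_hyper: float = 0.341
    n_de_lncrna: int = 50
    frac_up_de: float = 44.0 / 163.0
    de_log2fc_mean: float = 3.0
    de_log2fc_sd: float = 0.5
    n_meth_expr_overlap: int = 5  # hypomethylated & down-expressed lncRNAs
    meth_expr_corr: float = 0.5
    samples_per_condition: int = 5
    conditions: tuple = ("CRC", "NC")
    fpkm_meanlog: float = 3.0
    fpkm_sdlog: float = 1.0
    noise_sd: float = 0.3
    n_trans_pairs: int = 10
    trans_target_r: float = 0.95
    hub_targets: int = 61
    hub_r: float = 0.995
    n_screen_meth: int = 8  # disease-flagged hosts planted above the FC>7 screen
    n_screen_expr: int = 8  # disease-flagged DE lncRNAs planted above FC>2.5
    n_mirna: int = 200
    n_binding_mrna: int = 1200
    bindings_per_lncrna: int = 8
    bindings_per_mirna: int = 8

    def __post_init__(self):
        if len(self.class_proportions) != 6:
            raise ConfigError("class_proportions needs 6 entries")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ConfigError("class_proportions must sum to 1")
        if not (0 <= self.shared_peak_fraction <= 1):
            raise ConfigError("shared_peak_fraction must be in [0, 1]")
        if not (0 <= self.frac_hyper <= 1):
            raise ConfigError("frac_hyper must be in [0, 1]")
        if not (-1 <= self.meth_expr_corr <= 1):
            raise ConfigError("meth_expr_corr must be in [-1, 1]")
        if self.bindings_per_lncrna < 5 or self.bindings_per_mirna < 5:
            raise ConfigError("bindings per source must be >= 5")
        for name in ("n_mrna", "n_lncrna", "n_diff_peaks", "n_de_lncrna", "n_mirna"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    def rng(self, offset: int) -> np.random.Generator:
        """Component RNG: the run seed plus a fixed per-component offset."""
        return np.random.default_rng((self.seed * 1009 + offset) % (2**31 - 1))


@dataclass
class GroundTruth:
    """Planted labels, updated in place as study components are generated."""

    planted_class: dict = field(default_factory=dict)  # lncRNA -> class value
    peak_groups: dict = field(default_factory=dict)  # peak name -> shared|unique_a|unique_b
    peak_hosts: dict = field(default_factory=dict)  # peak name -> lncRNA id
    diff_direction: dict = field(default_factory=dict)  # lncRNA -> hyper/hypo
    diff_fold_change: dict = field(default_factory=dict)  # lncRNA -> fold change
    de_direction: dict = field(default_factory=dict)  # lncRNA -> up/down
    de_log2fc: dict = field(default_factory=dict)
    meth_expr_corr: float = 0.0
    methylation_level: dict = field(default_factory=dict)  # lncRNA -> case FE
    trans_pairs: list = field(default_factory=list)  # (lncRNA, mRNA, r)
    hub_lncrna: Optional[str] = None
    hub_mrnas: list = field(default_factory=list)
    disease_flags: list = field(default_factory=list)
    screened_lncrnas: list = field(default_factory=list)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        truth = cls()
        for key, value in payload.items():
            setattr(truth, key, value)
        truth.trans_pairs = [tuple(t) for t in truth.trans_pairs]
        return truth


def _apportion(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items over the class mix."""
    raw = [n * p for p in proportions]
    counts = [int(math.floor(x)) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _region_base(index: int) -> tuple[str, int]:
    chrom = f"chr{index // _REGIONS_PER_CHROM + 1}"
    return chrom, (index % _REGIONS_PER_CHROM) * _REGION


def _make_mrna(tid: str, gene: str, chrom: str, at: int, strand: Strand) -> TranscriptRecord:
    # 3 exons of 500 bp with 8 kbp introns: span 17.5 kbp
    exons = (
        GenomicInterval(chrom, at, at + 500, strand),
        GenomicInterval(chrom, at + 8500, at + 9000, strand),
        GenomicInterval(chrom, at + 17_000, at + 17_500, strand),
    )
    return TranscriptRecord(
        transcript_id=tid,
        gene_id=gene,
        interval=GenomicInterval(chrom, at, at + 17_500, strand),
        exons=exons,
        biotype="mRNA",
    )


def _single_exon_lnc(tid: str, chrom: str, start: int, length: int, strand: Strand) -> TranscriptRecord:
    iv = GenomicInterval(chrom, start, start + length, strand)
    return TranscriptRecord(
        transcript_id=tid, gene_id="g" + tid, interval=iv, exons=(iv,), biotype="lncRNA"
    )


def _two_exon_lnc(tid: str, chrom: str, start: int, length: int, strand: Strand) -> TranscriptRecord:
    l1 = max(1, length // 2)
    l2 = max(1, length - l1)
    exons = (
        GenomicInterval(chrom, start, start + l1, strand),
        GenomicInterval(chrom, start + l1 + 50, start + l1 + 50 + l2, strand),
    )
    iv = GenomicInterval(chrom, start, start + l1 + 50 + l2, strand)
    return TranscriptRecord(
        transcript_id=tid, gene_id="g" + tid, interval=iv, exons=exons, biotype="lncRNA"
    )


def _draw_length(rng: np.random.Generator) -> int:
    # mature length, mostly sub-kilobase as in tumor lncRNA profiles
    return int(np.clip(rng.lognormal(6.6, 0.9), 100, 6000))


def generate_annotation(config: SimConfig) -> tuple[TranscriptCatalog, GroundTruth]:
    """Build a catalog whose lncRNAs satisfy exactly their planted class."""
    rng = config.rng(11)
    counts = _apportion(config.n_lncrna, config.class_proportions)
    classes: list[PositionalClass] = []
    for cls, count in zip(_CLASS_ORDER, counts):
        classes.extend([cls] * count)
    rng.shuffle(classes)

    truth = GroundTruth()
    records: list[TranscriptRecord] = []
    n_anchors = sum(1 for c in classes if c != PositionalClass.INTERGENIC)
    if config.n_mrna < n_anchors:
        raise ConfigError(
            f"n_mrna={config.n_mrna} too small: {n_anchors} lncRNAs need a "
            "neighboring mRNA for their planted class"
        )

    region = 0
    mrna_idx = 0
    for i, cls in enumerate(classes):
        chrom, base = _region_base(region)
        region += 1
        lnc_id = f"LNC{i:05d}"
        anchor_at = base + _ANCHOR_OFFSET
        length = _draw_length(rng)
        anchor_strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
        opposite = Strand.MINUS if anchor_strand == Strand.PLUS else Strand.PLUS
        if cls == PositionalClass.INTERGENIC:
            strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
            maker = _two_exon_lnc if length > 300 and rng.random() < 0.5 else _single_exon_lnc
            records.append(maker(lnc_id, chrom, anchor_at, length, strand))
        else:
            anchor = _make_mrna(f"MRNA{mrna_idx:05d}", f"GENE{mrna_idx:05d}", chrom, anchor_at, anchor_strand)
            mrna_idx += 1
            records.append(anchor)
            if cls == PositionalClass.EXON_SENSE_OVERLAPPING:
                records.append(_single_exon_lnc(lnc_id, chrom, anchor_at + 250, length, anchor_strand))
            elif cls == PositionalClass.NATURAL_ANTISENSE:
                records.append(_single_exon_lnc(lnc_id, chrom, anchor_at + 250, length, opposite))
            elif cls == PositionalClass.INTRON_SENSE_OVERLAPPING:
                span = min(length, 6000)
                records.append(_two_exon_lnc(lnc_id, chrom, anchor_at + 9050, span, anchor_strand))
            elif cls == PositionalClass.INTRONIC_ANTISENSE:
                span = min(length, 6000)
                records.append(_two_exon_lnc(lnc_id, chrom, anchor_at + 9050, span, opposite))
            elif cls == PositionalClass.BIDIRECTIONAL:
                if anchor_strand == Strand.PLUS:
                    # lncRNA transcribes leftward away from the anchor's TSS
                    start = anchor_at - 300 - length
                    records.append(_single_exon_lnc(lnc_id, chrom, start, length, Strand.MINUS))
                else:
                    start = anchor_at + 17_500 + 300
                    records.append(_single_exon_lnc(lnc_id, chrom, start, length, Strand.PLUS))
        truth.planted_class[lnc_id] = cls.value

    while mrna_idx < config.n_mrna:
        chrom, base = _region_base(region)
        region += 1
        strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
        records.append(
            _make_mrna(f"MRNA{mrna_idx:05d}", f"GENE{mrna_idx:05d}", chrom, base + _ANCHOR_OFFSET, strand)
        )
        mrna_idx += 1

    return TranscriptCatalog(records), truth


def _peak_slots(rec: TranscriptRecord, count: int) -> list[GenomicInterval]:
    """``count`` non-overlapping subintervals of the first exon."""
    exon = max(rec.exons, key=lambda e: e.length)
    seg = exon.length // count
    slots = []
    for c in range(count):
        start = exon.start + c * seg
        width = min(100, seg - 2) if seg > 2 else 1
        slots.append(GenomicInterval(exon.chrom, start, start + max(1, width), exon.strand))
    return slots


def generate_peak_sets(
    config: SimConfig, catalog: TranscriptCatalog, truth: Optional[GroundTruth] = None
) -> tuple[list[PeakRecord], list[PeakRecord], list[DiffPeakRecord], GroundTruth]:
    """Generate per-condition peak sets on lncRNA exons plus differential calls.

    Shared peaks occupy identical exonic intervals in both conditions; each
    unique peak lives on its own host lncRNA so the downstream Venn is exact.
    A subset of shared peaks (one per host) is planted differential: a
    ``frac_hyper`` share get case-side enrichment raised by a log-normally
    drawn fold change, the rest get it lowered.
    """
    truth = truth or GroundTruth()
    rng = config.rng(23)
    n_a, n_b = config.n_peaks_per_condition
    f = config.shared_peak_fraction
    shared = int(round(f * (n_a + n_b) / (1.0 + f))) if (n_a + n_b) else 0
    shared = min(shared, n_a, n_b)
    unique_a, unique_b = n_a - shared, n_b - shared

    lncs = sorted(catalog.lncrnas(), key=lambda r: r.transcript_id)
    rng.shuffle(lncs)
    host_iter = iter(lncs)
    p1, p2, p3 = config.peaks_per_host_probs

    def _alloc(total: int, prefix: str) -> list[tuple[TranscriptRecord, list[GenomicInterval]]]:
        out = []
        left = total
        while left > 0:
            count = int(rng.choice([1, 2, 3], p=[p1, p2, p3]))
            count = min(count, left)
            try:
                host = next(host_iter)
            except StopIteration:
                raise ConfigError(
                    "not enough lncRNAs to host the requested peak counts"
                ) from None
            out.append((host, _peak_slots(host, count)))
            left -= count
        return out

    cond_a, cond_b = config.conditions
    peaks_a: list[PeakRecord] = []
    peaks_b: list[PeakRecord] = []
    diff_records: list[DiffPeakRecord] = []

    def _fe(rng) -> float:
        return float(rng.lognormal(1.5, 0.8))

    shared_hosts = _alloc(shared, "shared")
    # plant differential peaks on distinct shared hosts, one peak each
    if config.n_diff_peaks > len(shared_hosts):
        raise ConfigError(
            f"n_diff_peaks={config.n_diff_peaks} exceeds the {len(shared_hosts)} "
            "shared peak hosts available"
        )
    diff_idx_order = (
        rng.choice(len(shared_hosts), size=config.n_diff_peaks, replace=False).tolist()
        if config.n_diff_peaks
        else []
    )
    diff_host_idx = set(diff_idx_order)
    # a fixed-size subset of hosts is planted above the FC>7 candidate screen
    screen_idx = set(diff_idx_order[: config.n_screen_meth])

    k = 0
    for idx, (host, slots) in enumerate(shared_hosts):
        for s, slot in enumerate(slots):
            name = f"shared_{k:05d}"
            k += 1
            base = _fe(rng)
            fe_a = fe_b = base
            if idx in diff_host_idx and s == 0:
                if idx in screen_idx:
                    fold = 7.0 + float(rng.lognormal(1.5, 1.0))
                    truth.disease_flags.append(host.transcript_id)
                else:
                    fold = 1.0 + float(rng.lognormal(1.0, 0.7))
                hyper = bool(rng.random() < config.frac_hyper)
                if hyper:
                    fe_a = base * fold
                else:
                    fe_a = base
                    fe_b = base * fold
                direction = HYPER if hyper else HYPO
                diff_records.append(
                    DiffPeakRecord(
                        interval=slot,
                        fold_change=fold,
                        direction=direction,
                        lncrna_id=host.transcript_id,
                    )
                )
                truth.diff_direction[host.transcript_id] = direction
                truth.diff_fold_change[host.transcript_id] = fold
            peaks_a.append(PeakRecord(interval=slot, fold_enrichment=fe_a, condition=cond_a, name=name))
            peaks_b.append(PeakRecord(interval=slot, fold_enrichment=fe_b, condition=cond_b, name=name))
            truth.peak_groups[name] = "shared"
            truth.peak_hosts[name] = host.transcript_id

    for prefix, total, target in (("uniqA", unique_a, peaks_a), ("uniqB", unique_b, peaks_b)):
        j = 0
        for host, slots in _alloc(total, prefix):
            for slot in slots:
                name = f"{prefix}_{j:05d}"
                j += 1
                target.append(
                    PeakRecord(
                        interval=slot,
                        fold_enrichment=_fe(rng),
                        condition=cond_a if prefix == "uniqA" else cond_b,
                        name=name,
                    )
                )
                truth.peak_groups[name] = "unique_a" if prefix == "uniqA" else "unique_b"
                truth.peak_hosts[name] = host.transcript_id

    # case-side methylation level per methylated lncRNA (max fold enrichment)
    for peak in peaks_a:
        host = truth.peak_hosts[peak.name]
        truth.methylation_level[host] = max(
            truth.methylation_level.get(host, 0.0), peak.fold_enrichment
        )
    return peaks_a, peaks_b, diff_records, truth


def _exact_corr_vector(
    rng: np.random.Generator, x: np.ndarray, r: float, loc: float, scale: float
) -> np.ndarray:
    """A vector whose sample Pearson correlation with ``x`` is exactly ``r``."""
    n = len(x)
    xh = (x - x.mean()) / x.std()
    g = rng.normal(size=n)
    g = g - g.mean()
    g = g - (g @ xh) / (xh @ xh) * xh
    norm = np.sqrt((g**2).mean())
    if norm == 0:  # pragma: no cover - measure-zero draw
        raise ConfigError("degenerate noise draw in correlation planting")
    gh = g / norm
    return loc + scale * (r * xh + math.sqrt(max(0.0, 1 - r * r)) * gh)


def generate_expression_matrix(
    config: SimConfig,
    catalog: TranscriptCatalog,
    diff_peaks: Sequence[DiffPeakRecord],
    truth: Optional[GroundTruth] = None,
) -> tuple[list[ExpressionRecord], GroundTruth]:
    """FPKM matrix with planted DE, methylation-expression correlation,
    trans-target pairs and one co-expression hub.

    Log-FPKM baselines are normal (log-normal FPKM); methylated lncRNAs'
    baselines follow a Gaussian copula against their case-condition fold
    enrichment at ``meth_expr_corr``; per-sample noise is ``noise_sd`` on the
    log scale. Trans-target and hub mRNA profiles are constructed to have an
    exact planted sample correlation with their source lncRNA.
    """
    truth = truth or GroundTruth()
    truth.meth_expr_corr = config.meth_expr_corr
    rng = config.rng(37)
    cond_a, cond_b = config.conditions
    samples = [f"{c}_{i + 1}" for c in (cond_a, cond_b) for i in range(config.samples_per_condition)]
    sample_condition = {s: s.rsplit("_", 1)[0] for s in samples}
    n_per = config.samples_per_condition

    lncs = sorted(catalog.lncrnas(), key=lambda r: r.transcript_id)
    mrnas = sorted(catalog.mrnas(), key=lambda r: r.transcript_id)
    lnc_ids = [r.transcript_id for r in lncs]
    mrna_ids = [r.transcript_id for r in mrnas]

    # --- baseline log-FPKM means, with the methylation copula on methylated lncRNAs
    meth = {l: v for l, v in truth.methylation_level.items() if l in set(lnc_ids)}
    mu = {}
    if meth:
        meth_ids = sorted(meth)
        z = np.log(np.array([meth[l] for l in meth_ids]))
        z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
        rho = config.meth_expr_corr
        eta = rng.normal(size=len(meth_ids))
        latent = rho * z + math.sqrt(max(0.0, 1 - rho * rho)) * eta
        for l, value in zip(meth_ids, latent):
            mu[l] = config.fpkm_meanlog + config.fpkm_sdlog * value
    for tid in lnc_ids + mrna_ids:
        if tid not in mu:
            mu[tid] = float(rng.normal(config.fpkm_meanlog, config.fpkm_sdlog))

    # --- planted differential expression
    diff_meth_hosts = sorted(truth.diff_direction)
    hypo_hosts = [l for l in diff_meth_hosts if truth.diff_direction[l] == HYPO]
    overlap = hypo_hosts[: min(config.n_meth_expr_overlap, len(hypo_hosts), config.n_de_lncrna)]
    non_meth_pool = [l for l in lnc_ids if l not in truth.diff_direction and l not in meth]
    rng.shuffle(non_meth_pool)
    n_rest = max(0, config.n_de_lncrna - len(overlap))
    de_ids = overlap + non_meth_pool[:n_rest]
    expr_screen = set(de_ids[len(overlap) : len(overlap) + config.n_screen_expr])
    for j, lnc in enumerate(de_ids):
        if lnc in overlap:
            direction = "down"  # hypomethylated & down-expressed overlap cell
        else:
            direction = "up" if rng.random() < config.frac_up_de else "down"
        log2fc = max(1.1, float(rng.normal(config.de_log2fc_mean, config.de_log2fc_sd)))
        if lnc in expr_screen:
            # disease-flagged, planted above the FC>2.5 expression screen
            log2fc = max(log2fc, 1.4)
            truth.disease_flags.append(lnc)
        truth.de_direction[lnc] = direction
        truth.de_log2fc[lnc] = log2fc
    # --- trans-target and hub sources: unmethylated, non-DE lncRNAs
    reserved = set(truth.de_direction) | set(meth)
    source_pool = [l for l in lnc_ids if l not in reserved]
    rng.shuffle(source_pool)
    n_sources = config.n_trans_pairs + (1 if config.hub_targets else 0)
    sources = source_pool[:n_sources]
    target_pool = [m for m in mrna_ids]
    rng.shuffle(target_pool)

    # --- per-sample log-FPKM draws
    log_fpkm: dict[str, np.ndarray] = {}
    source_sd = config.noise_sd if config.noise_sd > 0 else 0.3
    for tid in lnc_ids + mrna_ids:
        sd = source_sd if tid in sources else config.noise_sd
        values = mu[tid] + sd * rng.normal(size=len(samples))
        if tid in truth.de_direction:
            delta = truth.de_log2fc[tid] * math.log(2)
            sign = 1.0 if truth.de_direction[tid] == "up" else -1.0
            values[:n_per] = values[:n_per] + sign * delta
        log_fpkm[tid] = values

    fpkm = {tid: np.exp(v) for tid, v in log_fpkm.items()}

    # --- exact-correlation targets (FPKM scale)
    t_used = 0
    for p in range(config.n_trans_pairs):
        if p >= len(sources) or t_used >= len(target_pool):
            break
        lnc = sources[p]
        mrna = target_pool[t_used]
        t_used += 1
        fpkm[mrna] = np.maximum(
            0.0,
            _exact_corr_vector(rng, fpkm[lnc], config.trans_target_r, loc=100.0, scale=10.0),
        )
        truth.trans_pairs.append((lnc, mrna, config.trans_target_r))
    if config.hub_targets and len(sources) > config.n_trans_pairs:
        hub = sources[config.n_trans_pairs]
        truth.hub_lncrna = hub
        for _ in range(config.hub_targets):
            if t_used >= len(target_pool):
                break
            mrna = target_pool[t_used]
            t_used += 1
            sign = 1.0 if rng.random() < 0.5 else -1.0
            fpkm[mrna] = np.maximum(
                0.0,
                _exact_corr_vector(rng, fpkm[hub], sign * config.hub_r, loc=100.0, scale=10.0),
            )
            truth.hub_mrnas.append(mrna)

    # --- assemble records with fold change and regulation labels
    records = []
    for rec_list, biotype in ((lncs, "lncRNA"), (mrnas, "mRNA")):
        for rec in rec_list:
            tid = rec.transcript_id
            values = fpkm[tid]
            case_mean = float(values[:n_per].mean())
            ctrl_mean = float(values[n_per:].mean())
            if case_mean == 0 and ctrl_mean == 0:
                fc, regulation = 0.0, "unchanged"
            elif min(case_mean, ctrl_mean) == 0:
                fc = math.inf
                regulation = "up" if case_mean > ctrl_mean else "down"
            else:
                fc = max(case_mean, ctrl_mean) / min(case_mean, ctrl_mean)
                if fc >= 2.0:
                    regulation = "up" if case_mean > ctrl_mean else "down"
                else:
                    regulation = "unchanged"
            records.append(
                ExpressionRecord(
                    transcript_id=tid,
                    fpkm={s: float(values[i]) for i, s in enumerate(samples)},
                    sample_condition=sample_condition,
                    fold_change=fc,
                    p_value=1.0,
                    regulation=regulation,
                    biotype=biotype,
                )
            )
    return records, truth


def expression_frame(
    records: Sequence[ExpressionRecord], biotype: Optional[str] = None
) -> pd.DataFrame:
    """FPKM matrix (transcripts x samples) from expression records."""
    rows = [r for r in records if biotype is None or r.biotype == biotype]
    if not rows:
        return pd.DataFrame()
    samples = list(rows[0].fpkm)
    return pd.DataFrame(
        [[r.fpkm[s] for s in samples] for r in rows],
        index=[r.transcript_id for r in rows],
        columns=samples,
    )


def generate_binding_predictions(
    config: SimConfig,
    screened_ids: Sequence[str],
    disjoint: bool = False,
) -> tuple[list[BindingPrediction], list[BindingPrediction]]:
    """Scored lncRNA-miRNA and miRNA-mRNA tables with unique top-5 sets.

    Scores are strictly distinct within each source so top-k selection is
    unambiguous. In ``disjoint`` mode every source draws its partners from
    the pool without replacement globally, so top-5 sets never overlap
    between sources (node-count law: k, k^2 scaling).
    """
    rng = config.rng(53)
    screened = sorted(set(screened_ids))
    mirna_pool = [f"mir_{i:04d}" for i in range(config.n_mirna)]
    mrna_pool = [f"TGT_{i:04d}" for i in range(config.n_binding_mrna)]

    def _scores(n: int) -> np.ndarray:
        raw = rng.random(n)
        return np.sort(raw)[::-1] + np.arange(n)[::-1] * 1e-9  # strictly decreasing

    lnc_mi: list[BindingPrediction] = []
    needed = len(screened) * config.bindings_per_lncrna
    if disjoint and needed > len(mirna_pool):
        raise ConfigError(
            f"disjoint mode needs n_mirna >= {needed}, got {config.n_mirna}"
        )
    free_mirnas = list(mirna_pool)
    rng.shuffle(free_mirnas)
    selected_mirnas: list[str] = []
    for lnc in screened:
        if disjoint:
            partners = [free_mirnas.pop() for _ in range(config.bindings_per_lncrna)]
        else:
            partners = list(
                rng.choice(mirna_pool, size=min(config.bindings_per_lncrna, len(mirna_pool)), replace=False)
            )
        scores = _scores(len(partners))
        for partner, score in zip(partners, scores):
            lnc_mi.append(BindingPrediction(lnc, partner, float(score), "lncRNA-miRNA"))
        selected_mirnas.extend(sorted(partners)[: config.bindings_per_lncrna])

    mi_mrna: list[BindingPrediction] = []
    all_sources = sorted(set(b.target_id for b in lnc_mi))
    needed = len(all_sources) * config.bindings_per_mirna
    if disjoint and needed > len(mrna_pool):
        raise ConfigError(
            f"disjoint mode needs n_binding_mrna >= {needed}, got {config.n_binding_mrna}"
        )
    free_mrnas = list(mrna_pool)
    rng.shuffle(free_mrnas)
    for mi in all_sources:
        if disjoint:
            partners = [free_mrnas.pop() for _ in range(config.bindings_per_mirna)]
        else:
            partners = list(
                rng.choice(mrna_pool, size=min(config.bindings_per_mirna, len(mrna_pool)), replace=False)
            )
        scores = _scores(len(partners))
        for partner, score in zip(partners, scores):
            mi_mrna.append(BindingPrediction(mi, partner, float(score), "miRNA-mRNA"))
    return lnc_mi, mi_mrna


def generate_full_study(
    config: SimConfig, outdir: Union[str, Path], disjoint_bindings: bool = True
) -> dict[str, Path]:
    """Write a complete synthetic study bundle to ``outdir``.

    Emits annotation GTF, two peak BEDs, a differential-methylation table,
    an expression TSV, two binding TSVs, a disease-flag list and the ground
    truth as JSON; byte-deterministic under a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog, truth = generate_annotation(config)
    peaks_a, peaks_b, diff_peaks, truth = generate_peak_sets(config, catalog, truth)
    expression, truth = generate_expression_matrix(config, catalog, diff_peaks, truth)

    criteria = ScreenCriteria()
    flags = sorted(set(truth.disease_flags))
    truth.disease_flags = flags
    screened = sorted(
        {
            l
            for l, fc in truth.diff_fold_change.items()
            if fc > criteria.meth_fc_threshold and l in set(flags)
        }
        | {
            l
            for l, lfc in truth.de_log2fc.items()
            if 2.0**lfc > criteria.expr_fc_threshold and l in set(flags)
        }
    )
    truth.screened_lncrnas = screened
    lnc_mi, mi_mrna = generate_binding_predictions(config, screened, disjoint=disjoint_bindings)

    cond_a, cond_b = config.conditions
    paths = {
        "gtf": outdir / "annotation.gtf",
        "peaks_a": outdir / f"peaks_{cond_a}.bed",
        "peaks_b": outdir / f"peaks_{cond_b}.bed",
        "diff_peaks": outdir / "diff_peaks.tsv",
        "expression": outdir / "expression.tsv",
        "bindings_lnc_mi": outdir / "bindings_lncrna_mirna.tsv",
        "bindings_mi_mrna": outdir / "bindings_mirna_mrna.tsv",
        "disease_flags": outdir / "disease_flags.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    lio.write_gtf(catalog, paths["gtf"])
    lio.write_peak_table(peaks_a, paths["peaks_a"], dialect="bed6+")
    lio.write_peak_table(peaks_b, paths["peaks_b"], dialect="bed6+")
    lio.write_peak_table(diff_peaks, paths["diff_peaks"], dialect="diffreps")
    lio.write_expression_table(expression, paths["expression"])
    lio.write_binding_table(lnc_mi, paths["bindings_lnc_mi"])
    lio.write_binding_table(mi_mrna, paths["bindings_mi_mrna"])
    paths["disease_flags"].write_text("".join(f"{l}\n" for l in flags))
    truth.to_json(paths["ground_truth"])
    return paths
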
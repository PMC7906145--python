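"""Readers and writers for the external formats.

Conversion between file conventions and the internal 0-based half-open
coordinates happens here and only here:

* GTF: 1-based closed -> subtract 1 from start on read, add 1 on write.
* BED6+: already 0-based half-open, passed through.
* MACS peak ``.xls`` and the diffReps-style differential table: 1-based.

Every reader either parses a line or raises :class:`ParseError` with the
1-based line number; nothing is silently dropped except records excluded by
an explicit, counted rule (e.g. unmapped biotypes in GTF).
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

from .model import (
    HYPER,
    HYPO,
    BindingPrediction,
    ConfigError,
    DiffPeakRecord,
    ExpressionRecord,
    GeneSetCollection,
    GenomicInterval,
    ParseError,
    PeakRecord,
    Strand,
    TranscriptCatalog,
    TranscriptRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_BIOTYPE_RULE",
    "read_gtf",
    "write_gtf",
    "read_peak_table",
    "write_peak_table",
    "read_expression_table",
    "write_expression_table",
    "read_binding_table",
    "write_binding_table",
    "read_gmt",
    "write_gmt",
    "write_network_edges",
    "read_network_edges",
]

#: GTF biotype attribute values mapped to the internal two-way biotype.
DEFAULT_BIOTYPE_RULE = {
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "processed_transcript": "lncRNA",
    "protein_coding": "mRNA",
}

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(
    path: Union[str, Path],
    biotype_rule: Optional[dict] = None,
) -> TranscriptCatalog:
    """Read an Ensembl-dialect GTF into a :class:`TranscriptCatalog`.

    ``biotype_rule`` maps the GTF ``gene_biotype``/``transcript_biotype``
    attribute value to ``"lncRNA"`` or ``"mRNA"``; transcripts with an
    unmapped biotype are dropped (the count is logged).
    """
    rule = DEFAULT_BIOTYPE_RULE if biotype_rule is None else biotype_rule
    declared: dict[str, dict] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []

    with open(path) as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}", line_no
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature not in ("transcript", "exon"):
                continue
            try:
                start_1 = int(start_s)
                end_1 = int(end_s)
            except ValueError:
                raise ParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", line_no)
            if start_1 < 1 or end_1 < start_1:
                raise ParseError(f"invalid 1-based interval [{start_1}, {end_1}]", line_no)
            attrs = _parse_attributes(attrs_s)
            if "transcript_id" not in attrs:
                raise ParseError("missing transcript_id attribute", line_no)
            tid = attrs["transcript_id"]
            interval = GenomicInterval(chrom, start_1 - 1, end_1, Strand(strand) if strand in "+-" else Strand.UNSTRANDED)
            biotype_attr = attrs.get("transcript_biotype") or attrs.get("gene_biotype") or ""
            if feature == "transcript":
                declared[tid] = {
                    "interval": interval,
                    "gene_id": attrs.get("gene_id", tid),
                    "biotype_attr": biotype_attr,
                    "line_no": line_no,
                }
                if tid not in exons:
                    order.append(tid)
                    exons[tid] = []
            else:
                if tid not in exons:
                    order.append(tid)
                    exons[tid] = []
                exons[tid].append(interval)
                if tid not in declared:
                    declared[tid] = {
                        "interval": None,
                        "gene_id": attrs.get("gene_id", tid),
                        "biotype_attr": biotype_attr,
                        "line_no": line_no,
                    }
                elif not declared[tid]["biotype_attr"]:
                    declared[tid]["biotype_attr"] = biotype_attr

    records = []
    dropped = 0
    for tid in order:
        meta = declared[tid]
        exon_list = sorted(exons[tid], key=lambda iv: iv.start)
        if not exon_list:
            # transcript feature with no exon lines: treat the span as one exon
            exon_list = [meta["interval"]]
        span = meta["interval"]
        if span is None:
            span = GenomicInterval(
                exon_list[0].chrom,
                exon_list[0].start,
                exon_list[-1].end,
                exon_list[0].strand,
            )
        else:
            for exon in exon_list:
                if not span.contains(exon):
                    raise ValidationError(
                        f"transcript {tid}: exon [{exon.start}, {exon.end}) outside "
                        f"declared transcript bounds [{span.start}, {span.end})"
                    )
        biotype = rule.get(meta["biotype_attr"])
        if biotype is None:
            dropped += 1
            continue
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=meta["gene_id"],
                interval=span,
                exons=tuple(exon_list),
                biotype=biotype,
            )
        )
    if dropped:
        logger.info("read_gtf: dropped %d transcripts with unmapped biotypes", dropped)
    return TranscriptCatalog(records)


def write_gtf(catalog: TranscriptCatalog, path: Union[str, Path]) -> None:
    """Write a catalog back to GTF (1-based closed coordinates)."""
    inverse_biotype = {"lncRNA": "lncRNA", "mRNA": "protein_coding"}
    with open(path, "w") as handle:
        for rec in catalog:
            attrs = (
                f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}"; '
                f'gene_biotype "{inverse_biotype[rec.biotype]}";'
            )
            iv = rec.interval
            handle.write(
                "\t".join(
                    [
                        iv.chrom,
                        "lncm6a",
                        "transcript",
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand.value,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for exon in rec.exons:
                handle.write(
                    "\t".join(
                        [
                            exon.chrom,
                            "lncm6a",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand.value,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# peak tables


_DIRECTION_ALIASES = {
    "hypermethylated": HYPER,
    "hypomethylated": HYPO,
    "hyper": HYPER,
    "hypo": HYPO,
    "up": HYPER,
    "down": HYPO,
}


def _parse_float(token: str, line_no: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"non-numeric {what} {token!r}", line_no)


def read_peak_table(
    path: Union[str, Path],
    condition: str = "",
    dialect: str = "bed6+",
) -> list:
    """Read a peak table.

    Dialects:

    * ``bed6+``  — 0-based half-open BED6 with fold enrichment in column 7
      and an optional p-value in column 8; returns :class:`PeakRecord`.
    * ``macs-xls`` — MACS peak ``.xls`` (1-based; header + comment lines
      starting with ``#``); returns :class:`PeakRecord`.
    * ``diffreps`` — differential table with 1-based closed columns
      ``chrom txStart txEnd name foldchange regulation``; returns
      :class:`DiffPeakRecord`.
    """
    if dialect not in ("bed6+", "macs-xls", "diffreps"):
        raise ConfigError(f"unknown peak-table dialect {dialect!r}")
    records: list = []
    with open(path) as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "bed6+":
                if len(fields) < 7:
                    raise ParseError("bed6+ needs >= 7 columns", line_no)
                chrom, start_s, end_s, name, _score, strand_s = fields[:6]
                start, end = int(start_s), int(end_s)
                if start < 0:
                    raise ParseError(f"negative coordinate {start}", line_no)
                fe = _parse_float(fields[6], line_no, "fold enrichment")
                if fe <= 0:
                    raise ParseError(f"fold enrichment must be > 0, got {fe}", line_no)
                p = _parse_float(fields[7], line_no, "p-value") if len(fields) > 7 else None
                records.append(
                    PeakRecord(
                        interval=GenomicInterval(chrom, start, end, _strand_of(strand_s)),
                        fold_enrichment=fe,
                        condition=condition,
                        p_value=p,
                        name=name,
                    )
                )
            elif dialect == "macs-xls":
                if fields[0] in ("chr", "chrom"):  # header row
                    continue
                if len(fields) < 8:
                    raise ParseError("macs-xls needs >= 8 columns", line_no)
                chrom, start_s, end_s = fields[0], fields[1], fields[2]
                start, end = int(start_s) - 1, int(end_s)
                if start < 0:
                    raise ParseError(f"negative coordinate {start}", line_no)
                fe = _parse_float(fields[7], line_no, "fold enrichment")
                if fe <= 0:
                    raise ParseError(f"fold enrichment must be > 0, got {fe}", line_no)
                neglog_p = _parse_float(fields[6], line_no, "-10*log10(p)")
                p = min(1.0, 10 ** (-neglog_p / 10.0))
                records.append(
                    PeakRecord(
                        interval=GenomicInterval(chrom, start, end, Strand.UNSTRANDED),
                        fold_enrichment=fe,
                        condition=condition,
                        p_value=p,
                    )
                )
            else:  # diffreps
                if fields[0].lower() in ("chrom", "chr"):  # header row
                    continue
                if len(fields) < 6:
                    raise ParseError("diffreps dialect needs >= 6 columns", line_no)
                chrom, start_s, end_s, name, fc_s, reg_s = fields[:6]
                start, end = int(start_s) - 1, int(end_s)
                if start < 0:
                    raise ParseError(f"negative coordinate {start}", line_no)
                fc = _parse_float(fc_s, line_no, "fold change")
                reg = _DIRECTION_ALIASES.get(reg_s.strip().lower())
                if reg is None:
                    # direction from the sign of a log2 fold change
                    reg = HYPER if fc > 0 else HYPO
                    fc = 2.0 ** abs(fc)
                else:
                    fc = abs(fc)
                    if math.isinf(fc):
                        fc = math.inf
                if fc <= 0:
                    raise ParseError(f"fold change must be > 0, got {fc}", line_no)
                records.append(
                    DiffPeakRecord(
                        interval=GenomicInterval(chrom, start, end, Strand.UNSTRANDED),
                        fold_change=fc,
                        direction=reg,
                        lncrna_id=name or None,
                    )
                )
    return records


def _strand_of(token: str) -> Strand:
    return Strand(token) if token in "+-" else Strand.UNSTRANDED


def write_peak_table(records: Sequence, path: Union[str, Path], dialect: str = "bed6+") -> None:
    """Write peaks back out in ``bed6+`` or ``diffreps`` dialect."""
    with open(path, "w") as handle:
        if dialect == "bed6+":
            for i, rec in enumerate(records):
                iv = rec.interval
                p = "" if rec.p_value is None else f"\t{rec.p_value!r}"
                name = rec.name or f"peak{i + 1}"
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t.\t"
                    f"{iv.strand.value}\t{rec.fold_enrichment!r}{p}\n"
                )
        elif dialect == "diffreps":
            handle.write("chrom\ttxStart\ttxEnd\tname\tfoldchange\tregulation\n")
            for rec in records:
                iv = rec.interval
                fc = "Inf" if math.isinf(rec.fold_change) else repr(rec.fold_change)
                handle.write(
                    f"{iv.chrom}\t{iv.start + 1}\t{iv.end}\t"
                    f"{rec.lncrna_id or '.'}\t{fc}\t{rec.direction}\n"
                )
        else:
            raise ConfigError(f"unknown peak-table dialect {dialect!r}")


# ---------------------------------------------------------------------------
# expression tables


_EXPR_META_COLS = ("transcript_id", "biotype", "fold_change", "p_value", "regulation")


def _condition_of_sample(sample: str) -> str:
    """Condition label encoded in the sample name (part before the last '_')."""
    if "_" in sample:
        return sample.rsplit("_", 1)[0]
    return sample


def read_expression_table(path: Union[str, Path]) -> list[ExpressionRecord]:
    """Read a TSV expression matrix.

    Expected header: ``transcript_id  [biotype]  <sample...>  [fold_change
    p_value regulation]`` where sample columns are named ``<condition>_<i>``.
    ``inf``/``-Inf`` fold-change tokens become +infinity with the direction
    carried by the regulation label. Rows with all-zero FPKM and no usable
    fold change are flagged ``unchanged`` with fold change 0.
    """
    with open(path) as handle:
        header_line = handle.readline().rstrip("\n")
        if not header_line:
            return []
        header = header_line.split("\t")
        sample_cols = [c for c in header if c not in _EXPR_META_COLS]
        col_idx = {c: i for i, c in enumerate(header)}
        records = []
        for line_no, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"expected {len(header)} columns, got {len(fields)}", line_no
                )
            tid = fields[col_idx["transcript_id"]]
            fpkm = {}
            for col in sample_cols:
                value = _parse_float(fields[col_idx[col]], line_no, "FPKM")
                if value < 0:
                    raise ValidationError(
                        f"line {line_no}: negative FPKM {value} for {tid}"
                    )
                fpkm[col] = value
            sample_condition = {c: _condition_of_sample(c) for c in sample_cols}
            regulation = (
                fields[col_idx["regulation"]].strip().lower()
                if "regulation" in col_idx
                else "unchanged"
            )
            if regulation.endswith("-expression"):
                regulation = regulation.split("-")[0]
            if "fold_change" in col_idx:
                token = fields[col_idx["fold_change"]].strip().lower()
                if token in ("inf", "+inf", "-inf", "infinity", "-infinity"):
                    fc = math.inf
                else:
                    fc = abs(_parse_float(token, line_no, "fold change"))
            else:
                means = {}
                for sample, value in fpkm.items():
                    means.setdefault(sample_condition[sample], []).append(value)
                cond_means = {c: sum(v) / len(v) for c, v in means.items()}
                fc, regulation = _fold_change_of_means(cond_means, regulation)
            p = (
                _parse_float(fields[col_idx["p_value"]], line_no, "p-value")
                if "p_value" in col_idx
                else 1.0
            )
            records.append(
                ExpressionRecord(
                    transcript_id=tid,
                    fpkm=fpkm,
                    sample_condition=sample_condition,
                    fold_change=fc,
                    p_value=p,
                    regulation=regulation if regulation in ("up", "down", "unchanged") else "unchanged",
                    biotype=fields[col_idx["biotype"]] if "biotype" in col_idx else "lncRNA",
                )
            )
    return records


def _fold_change_of_means(cond_means: dict, regulation: str):
    values = sorted(cond_means.values())
    if len(values) != 2:
        return 0.0, "unchanged"
    low, high = values
    if high == 0:
        return 0.0, "unchanged"  # all-zero row: undefined ratio, flagged
    if low == 0:
        return math.inf, regulation if regulation != "unchanged" else "up"
    return high / low, regulation


def write_expression_table(records: Sequence[ExpressionRecord], path: Union[str, Path]) -> None:
    if not records:
        Path(path).write_text("transcript_id\tbiotype\tfold_change\tp_value\tregulation\n")
        return
    samples = list(records[0].fpkm.keys())
    with open(path, "w") as handle:
        handle.write(
            "\t".join(["transcript_id", "biotype", *samples, "fold_change", "p_value", "regulation"]) + "\n"
        )
        for rec in records:
            fc = "inf" if math.isinf(rec.fold_change) else repr(rec.fold_change)
            handle.write(
                "\t".join(
                    [
                        rec.transcript_id,
                        rec.biotype,
                        *[repr(rec.fpkm[s]) for s in samples],
                        fc,
                        repr(rec.p_value),
                        rec.regulation,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# binding tables


def read_binding_table(path: Union[str, Path], layer: str) -> list[BindingPrediction]:
    """Read a scored binding table: ``source_id  target_id  score``."""
    records = []
    seen = set()
    with open(path) as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("source_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("binding table needs 3 columns", line_no)
            key = (fields[0], fields[1])
            if key in seen:
                raise ParseError(f"duplicate binding pair {key}", line_no)
            seen.add(key)
            records.append(
                BindingPrediction(
                    source_id=fields[0],
                    target_id=fields[1],
                    score=_parse_float(fields[2], line_no, "score"),
                    layer=layer,
                )
            )
    return records


def write_binding_table(records: Sequence[BindingPrediction], path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        handle.write("source_id\ttarget_id\tscore\n")
        for rec in records:
            handle.write(f"{rec.source_id}\t{rec.target_id}\t{rec.score!r}\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: Union[str, Path]) -> GeneSetCollection:
    """Read a tab-separated GMT file (name, description, members...)."""
    sets: dict[str, frozenset] = {}
    with open(path) as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("GMT line needs >= 3 fields", line_no)
            name = fields[0]
            if name in sets:
                raise ParseError(f"duplicate gene-set name {name!r}", line_no)
            sets[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            handle.write(f"{name}\t.\t{members}\n")


# ---------------------------------------------------------------------------
# network edge lists


_EDGE_HEADER = "source\ttarget\tedge_type\tsign\tscore\n"


def write_network_edges(network, path: Union[str, Path]) -> None:
    """Write a ceRNA or CNC network as a Cytoscape-importable TSV edge list.

    Columns: source, target, edge_type, sign (+/-/NA), score; rows sorted by
    (source, target) so the output is byte-deterministic.
    """
    rows = []
    for edge in network.edge_rows():
        rows.append(edge)
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as handle:
        handle.write(_EDGE_HEADER)
        for source, target, edge_type, sign, score in rows:
            score_s = "NA" if score is None else repr(float(score))
            handle.write(f"{source}\t{target}\t{edge_type}\t{sign}\t{score_s}\n")


def read_network_edges(path: Union[str, Path]) -> list[tuple]:
    """Read back an edge list written by :func:`write_network_edges`."""
    rows = []
    with open(path) as handle:
        header = handle.readline()
        if header and header != _EDGE_HEADER:
            raise ParseError("unexpected edge-list header", 1)
        for line_no, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError("edge list needs 5 columns", line_no)
            source, target, edge_type, sign, score_s = fields
            score = None if score_s == "NA" else float(score_s)
            rows.append((source, target, edge_type, sign, score))
    return rows
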
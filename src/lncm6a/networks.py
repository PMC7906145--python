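"""Cis/trans target inference and ceRNA / coding-non-coding (CNC) network
construction.

Cis-targets are mRNAs within a 10 kbp genomic window of a lncRNA;
trans-targets are mRNAs whose expression profile correlates with the lncRNA
at |Pearson r| >= 0.9 regardless of position. The ceRNA network joins each
screened lncRNA to its top-5 predicted miRNAs and each of those miRNAs to its
top-5 predicted mRNAs. The CNC network links lncRNA-mRNA pairs with
|Pearson r| >= 0.95, the edge sign carrying the correlation sign
(+ "positively regulates", - "negatively regulates").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .model import (
    BindingPrediction,
    ConfigError,
    GenomicInterval,
    TranscriptCatalog,
    TranscriptRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenCriteria",
    "CeRNANetwork",
    "CNCNetwork",
    "find_cis_targets",
    "find_trans_targets",
    "screen_cerna_candidates",
    "build_cerna_network",
    "build_cnc_network",
]


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds for screening ceRNA candidate lncRNAs.

    Defaults follow the screening used for colorectal cancer: methylation
    fold change > 7, expression fold change > 2.5, restricted to
    disease-associated lncRNAs.
    """

    meth_fc_threshold: float = 7.0
    expr_fc_threshold: float = 2.5
    require_disease_flag: bool = True

    def __post_init__(self):
        if not (self.meth_fc_threshold > 0 and self.expr_fc_threshold > 0):
            raise ConfigError("screen thresholds must be > 0")


@dataclass
class CeRNANetwork:
    """Tripartite lncRNA-miRNA-mRNA graph."""

    graph: nx.Graph
    shortfalls: dict  # source id -> number of missing partners (< k available)

    def nodes_by_layer(self, layer: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("layer") == layer
        )

    def validate(self) -> None:
        for u, v in self.graph.edges:
            lu = self.graph.nodes[u]["layer"]
            lv = self.graph.nodes[v]["layer"]
            if {lu, lv} not in ({"lncRNA", "miRNA"}, {"miRNA", "mRNA"}):
                raise ValidationError(f"non-tripartite edge {u}-{v} ({lu}-{lv})")
        for mi in self.nodes_by_layer("miRNA"):
            if not any(
                self.graph.nodes[nb]["layer"] == "lncRNA"
                for nb in self.graph.neighbors(mi)
            ):
                raise ValidationError(f"miRNA {mi} has no lncRNA edge")

    def edge_rows(self):
        for u, v, data in self.graph.edges(data=True):
            lu = self.graph.nodes[u]["layer"]
            if lu != data["edge_type"].split("-")[0]:
                u, v = v, u
            yield (u, v, data["edge_type"], "NA", data.get("score"))


@dataclass
class CNCNetwork:
    """Signed lncRNA-mRNA co-expression graph."""

    graph: nx.Graph
    threshold: float

    def validate(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if abs(data["r"]) < self.threshold:
                raise ValidationError(
                    f"CNC edge {u}-{v} below threshold: r={data['r']}"
                )

    def degree(self, node: str) -> int:
        return self.graph.degree[node] if node in self.graph else 0

    def edge_rows(self):
        for u, v, data in self.graph.edges(data=True):
            if self.graph.nodes[u]["layer"] != "lncRNA":
                u, v = v, u
            yield (u, v, "lncRNA-mRNA", data["sign"], data.get("r"))


def find_cis_targets(
    lncrna: TranscriptRecord,
    catalog: TranscriptCatalog,
    window: int = 10_000,
) -> list[str]:
    """mRNAs within ``window`` bp of the lncRNA's genomic span.

    Strand-agnostic; an mRNA qualifies when its span overlaps
    ``[lncrna.start - window, lncrna.end + window)``, i.e. when the gap
    between the spans is strictly less than ``window`` bp (half-open
    arithmetic: a gap of exactly ``window`` is excluded).
    """
    if window < 0:
        raise ConfigError("cis window must be >= 0")
    query = GenomicInterval(
        lncrna.chrom,
        max(0, lncrna.interval.start - window),
        lncrna.interval.end + window,
    )
    return sorted(
        rec.transcript_id for rec in catalog.overlapping(query, biotype="mRNA")
    )


def _pairwise_r(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        return None
    xm, ym = x[mask], y[mask]
    sx, sy = xm.std(), ym.std()
    if sx == 0 or sy == 0:
        return None
    return float(((xm - xm.mean()) * (ym - ym.mean())).mean() / (sx * sy))


def find_trans_targets(
    lncrna_expr: Mapping[str, float],
    mrna_expr_table: pd.DataFrame,
    threshold: float = 0.9,
    positive_only: bool = False,
) -> list[tuple[str, float]]:
    """mRNAs whose expression correlates with the lncRNA at |r| >= threshold.

    ``lncrna_expr`` maps sample -> FPKM; ``mrna_expr_table`` is indexed by
    mRNA id with sample columns. Infinite/missing values are dropped
    pairwise; at least 3 shared samples are required. The signed r is
    returned; ``positive_only`` restricts to r >= threshold.
    """
    samples = [s for s in mrna_expr_table.columns if s in lncrna_expr]
    if len(samples) < 3:
        raise ValidationError("find_trans_targets needs >= 3 shared samples")
    x = np.asarray([lncrna_expr[s] for s in samples], dtype=float)
    hits = []
    for mrna_id, row in mrna_expr_table[samples].iterrows():
        r = _pairwise_r(x, row.to_numpy(dtype=float))
        if r is None:
            continue
        if (r >= threshold) if positive_only else (abs(r) >= threshold):
            hits.append((str(mrna_id), r))
    return sorted(hits)


def screen_cerna_candidates(
    diff_meth: Mapping[str, float],
    diff_expr: Mapping[str, float],
    disease_flags: Iterable[str],
    criteria: Optional[ScreenCriteria] = None,
) -> pd.DataFrame:
    """Screen lncRNAs for ceRNA analysis.

    ``diff_meth`` / ``diff_expr`` map lncRNA id -> fold-change magnitude
    (may be +inf, which passes any threshold); ``disease_flags`` lists
    disease-associated ids. A lncRNA is retained when it passes the
    methylation screen, the expression screen, or both; the returned frame
    records which criterion fired. Deduplicated and sorted by id.
    """
    criteria = criteria or ScreenCriteria()
    flags = set(disease_flags)
    hits: dict[str, dict] = {}

    def _consider(lnc: str, fc: float, threshold: float, which: str) -> None:
        if fc < 0:
            raise ValidationError(f"negative fold change for {lnc}")
        if criteria.require_disease_flag and lnc not in flags:
            return
        # an infinite fold change passes any threshold, including +inf
        if not (math.isinf(fc) or fc > threshold):
            return
        entry = hits.setdefault(
            lnc, {"lncrna_id": lnc, "meth_fc": math.nan, "expr_fc": math.nan, "criterion": ""}
        )
        entry[f"{which}_fc"] = fc
        entry["criterion"] = (
            "both" if entry["criterion"] and entry["criterion"] != which else which
        )

    for lnc, fc in diff_meth.items():
        _consider(lnc, fc, criteria.meth_fc_threshold, "meth")
    for lnc, fc in diff_expr.items():
        _consider(lnc, fc, criteria.expr_fc_threshold, "expr")
    frame = pd.DataFrame(
        sorted(hits.values(), key=lambda e: e["lncrna_id"]),
        columns=["lncrna_id", "meth_fc", "expr_fc", "criterion"],
    )
    return frame


def _top_k(
    bindings: Sequence[BindingPrediction], source: str, k: int
) -> list[BindingPrediction]:
    mine = [b for b in bindings if b.source_id == source]
    mine.sort(key=lambda b: (-b.score, b.target_id))
    return mine[:k]


def build_cerna_network(
    screened_lncrnas: Iterable[str],
    lnc_mi_bindings: Sequence[BindingPrediction],
    mi_mrna_bindings: Sequence[BindingPrediction],
    k: int = 5,
) -> CeRNANetwork:
    """Assemble the tripartite ceRNA network.

    Per screened lncRNA, its ``k`` highest-scoring miRNAs (ties broken by
    miRNA id ascending); per selected miRNA, its ``k`` highest-scoring mRNAs
    under the same tie rule. Nodes are shared across lncRNAs; sources with
    fewer than ``k`` predictions contribute what they have (shortfall
    recorded).
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    graph = nx.Graph()
    shortfalls: dict[str, int] = {}
    selected_mirnas: list[str] = []
    for lnc in sorted(set(screened_lncrnas)):
        graph.add_node(lnc, layer="lncRNA")
        top = _top_k(lnc_mi_bindings, lnc, k)
        if len(top) < k:
            shortfalls[lnc] = k - len(top)
            logger.info(
                "ceRNA: lncRNA %s has only %d/%d predicted miRNAs", lnc, len(top), k
            )
        for b in top:
            graph.add_node(b.target_id, layer="miRNA")
            graph.add_edge(
                lnc, b.target_id, edge_type="lncRNA-miRNA", score=b.score
            )
            selected_mirnas.append(b.target_id)
    for mi in sorted(set(selected_mirnas)):
        top = _top_k(mi_mrna_bindings, mi, k)
        if len(top) < k:
            shortfalls[mi] = k - len(top)
            logger.info(
                "ceRNA: miRNA %s has only %d/%d predicted mRNAs", mi, len(top), k
            )
        for b in top:
            graph.add_node(b.target_id, layer="mRNA")
            graph.add_edge(mi, b.target_id, edge_type="miRNA-mRNA", score=b.score)
    network = CeRNANetwork(graph=graph, shortfalls=shortfalls)
    network.validate()
    return network


def build_cnc_network(
    lncrna_expr_table: pd.DataFrame,
    mrna_expr_table: pd.DataFrame,
    threshold: float = 0.95,
    positive_only: bool = False,
) -> CNCNetwork:
    """Signed lncRNA-mRNA co-expression network at |Pearson r| >= threshold.

    Both tables are indexed by transcript id with identical sample columns
    (>= 3 required). Rows containing non-finite values or with zero variance
    are excluded (counts logged). Edge sign is the correlation sign.
    """
    samples = [s for s in lncrna_expr_table.columns if s in mrna_expr_table.columns]
    if len(samples) < 3:
        raise ValidationError("build_cnc_network needs >= 3 shared samples")

    def _clean(table: pd.DataFrame, what: str) -> pd.DataFrame:
        values = table[samples].astype(float)
        arr = values.to_numpy()
        finite = np.isfinite(arr).all(axis=1)
        with np.errstate(invalid="ignore"):
            std = np.nanstd(arr, axis=1)
            scale = np.nanmax(np.abs(arr), axis=1)
        # rows constant up to float rounding carry no correlation signal
        varying = std > scale * 1e-12
        keep = finite & varying
        dropped = int((~keep).sum())
        if dropped:
            logger.info("CNC: excluded %d %s rows (non-finite or constant)", dropped, what)
        return values[keep]

    lnc = _clean(lncrna_expr_table, "lncRNA")
    mrna = _clean(mrna_expr_table, "mRNA")
    graph = nx.Graph()
    for t in lnc.index:
        graph.add_node(str(t), layer="lncRNA")
    for t in mrna.index:
        graph.add_node(str(t), layer="mRNA")
    if len(lnc) and len(mrna):
        lz = _standardize(lnc.to_numpy())
        mz = _standardize(mrna.to_numpy())
        corr = lz @ mz.T / lz.shape[1]
        corr = np.clip(corr, -1.0, 1.0)
        ii, jj = np.nonzero(np.abs(corr) >= threshold)
        for i, j in zip(ii, jj):
            r = float(corr[i, j])
            if positive_only and r < 0:
                continue
            graph.add_edge(
                str(lnc.index[i]),
                str(mrna.index[j]),
                r=r,
                sign="+" if r >= 0 else "-",
            )
    network = CNCNetwork(graph=graph, threshold=threshold)
    network.validate()
    return network


def _standardize(matrix: np.ndarray) -> np.ndarray:
    mean = matrix.mean(axis=1, keepdims=True)
    std = matrix.std(axis=1, keepdims=True)
    return (matrix - mean) / std
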
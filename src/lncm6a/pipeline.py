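"""Full-pipeline orchestration: from input files to a reproducible report.

Stages run in a fixed order (annotate peaks -> classify -> differential
summaries -> integration statistics -> targets -> networks); each stage
writes its TSV under the output directory and the run ends with a
``summary.json`` of headline numbers plus a ``manifest.json`` (config hash,
version, seed). Outputs are byte-deterministic for fixed inputs and config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from . import io as lio
from .classify import ClassifyParams, classify_catalog
from .integrate import (
    correlate_levels,
    cumulative_log2fc,
    bin_lengths,
    chromosome_distribution,
    join_methylation_expression,
    mean_fold_change_by_class,
    summarize_regulation,
)
from .model import ConfigError, ValidationError
from .networks import (
    ScreenCriteria,
    build_cerna_network,
    build_cnc_network,
    find_cis_targets,
    find_trans_targets,
)
from .peaks import (
    compare_peak_sets,
    filter_peaks_to_lncrna_exons,
    peaks_per_lncrna_distribution,
)
from .simulate import expression_frame

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Input paths and thresholds for a full run."""

    gtf: Path
    peaks_a: Path
    peaks_b: Path
    diff_peaks: Path
    expression: Path
    outdir: Path
    bindings_lnc_mi: Optional[Path] = None
    bindings_mi_mrna: Optional[Path] = None
    disease_flags: Optional[Path] = None
    gmt: Optional[Path] = None
    condition_a: str = "CRC"
    condition_b: str = "NC"
    peak_dialect: str = "bed6+"
    min_overlap_bp: int = 1
    bidirectional_window: int = 1000
    cis_window: int = 10_000
    trans_threshold: float = 0.9
    cnc_threshold: float = 0.95
    meth_fc_threshold: float = 7.0
    expr_fc_threshold: float = 2.5
    top_k: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("gtf", "peaks_a", "peaks_b", "diff_peaks", "expression", "outdir"):
            setattr(self, name, Path(getattr(self, name)))
        for name in ("bindings_lnc_mi", "bindings_mi_mrna", "disease_flags", "gmt"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        for name in ("min_overlap_bp", "cis_window", "bidirectional_window", "top_k"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    def validate_inputs(self) -> None:
        required = ["gtf", "peaks_a", "peaks_b", "diff_peaks", "expression"]
        optional = ["bindings_lnc_mi", "bindings_mi_mrna", "disease_flags", "gmt"]
        for name in required + optional:
            path = getattr(self, name)
            if path is None:
                continue
            if name in required and not path.exists():
                raise ConfigError(f"input file for {name!r} not found: {path}")
            if name in optional and not path.exists():
                raise ConfigError(f"configured {name!r} not found: {path}")

    def content_hash(self) -> str:
        # outdir is not an input: identical inputs+thresholds hash identically
        payload = {k: str(v) for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()

    @classmethod
    def from_study_dir(cls, study_dir: Union[str, Path], outdir: Union[str, Path],
                       condition_a: str = "CRC", condition_b: str = "NC", **kwargs):
        study_dir = Path(study_dir)
        return cls(
            gtf=study_dir / "annotation.gtf",
            peaks_a=study_dir / f"peaks_{condition_a}.bed",
            peaks_b=study_dir / f"peaks_{condition_b}.bed",
            diff_peaks=study_dir / "diff_peaks.tsv",
            expression=study_dir / "expression.tsv",
            bindings_lnc_mi=study_dir / "bindings_lncrna_mirna.tsv",
            bindings_mi_mrna=study_dir / "bindings_mirna_mrna.tsv",
            disease_flags=study_dir / "disease_flags.tsv",
            outdir=Path(outdir),
            condition_a=condition_a,
            condition_b=condition_b,
            **kwargs,
        )


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, na_rep="NA")


def _annotated_frame(annotated) -> pd.DataFrame:
    rows = []
    for ap in annotated:
        iv = ap.peak.interval
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "name": ap.peak.name,
                "fold_enrichment": ap.peak.fold_enrichment,
                "lncrna_ids": ",".join(ap.lncrna_ids),
                "overlap_bp": ",".join(str(ap.overlap_bp[l]) for l in ap.lncrna_ids),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "fold_enrichment", "lncrna_ids", "overlap_bp"],
    )


def _methylation_levels(annotated, agg: str = "max") -> dict[str, float]:
    levels: dict[str, list[float]] = {}
    for ap in annotated:
        for lnc in ap.overlap_bp:
            levels.setdefault(lnc, []).append(ap.peak.fold_enrichment)
    if agg == "max":
        return {l: max(v) for l, v in levels.items()}
    return {l: sum(v) / len(v) for l, v in levels.items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary dict written to summary.json."""
    config.validate_inputs()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    def stage(name):
        logger.info("stage: %s", name)

    # --- load inputs -------------------------------------------------------
    try:
        stage("load")
        catalog = lio.read_gtf(config.gtf)
        peaks_a = lio.read_peak_table(config.peaks_a, condition=config.condition_a, dialect=config.peak_dialect)
        peaks_b = lio.read_peak_table(config.peaks_b, condition=config.condition_b, dialect=config.peak_dialect)
        diff_peaks = lio.read_peak_table(config.diff_peaks, dialect="diffreps")
        expression = lio.read_expression_table(config.expression)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError("load", exc) from exc

    lnc_expr = [r for r in expression if r.biotype == "lncRNA"]
    mrna_expr = [r for r in expression if r.biotype == "mRNA"]

    # --- peak annotation ---------------------------------------------------
    try:
        stage("annotate")
        annotated_a = filter_peaks_to_lncrna_exons(peaks_a, catalog, config.min_overlap_bp)
        annotated_b = filter_peaks_to_lncrna_exons(peaks_b, catalog, config.min_overlap_bp)
        _write_tsv(_annotated_frame(annotated_a), outdir / "annotated_peaks_a.tsv")
        _write_tsv(_annotated_frame(annotated_b), outdir / "annotated_peaks_b.tsv")
        venn = compare_peak_sets([a.peak for a in annotated_a], [b.peak for b in annotated_b])
        dist_a = peaks_per_lncrna_distribution(annotated_a)
        _write_tsv(
            pd.DataFrame(
                {"peaks": list(dist_a), "fraction": list(dist_a.values())}
            ),
            outdir / "peaks_per_lncrna_a.tsv",
        )
        summary["peaks"] = {
            "n_peaks_a": len(annotated_a),
            "n_peaks_b": len(annotated_b),
            "n_methylated_lncrnas_a": len({l for ap in annotated_a for l in ap.overlap_bp}),
            "venn": {
                "unique_a": venn.unique_a,
                "unique_b": venn.unique_b,
                "shared": venn.shared,
                "shared_fraction": venn.shared_fraction,
            },
            "peaks_per_lncrna_a": {str(k): v for k, v in dist_a.items()},
        }
    except Exception as exc:
        raise StageError("annotate", exc) from exc

    # --- positional classification ----------------------------------------
    try:
        stage("classify")
        params = ClassifyParams(bidirectional_window=config.bidirectional_window)
        assignment, proportions = classify_catalog(catalog, params)
        _write_tsv(
            pd.DataFrame(
                sorted(assignment.items()), columns=["lncrna_id", "class"]
            ).assign(**{"class": lambda f: f["class"].map(lambda c: c.value)}),
            outdir / "positional_classes.tsv",
        )
        summary["classes"] = {c.value: p for c, p in proportions.items()}
    except Exception as exc:
        raise StageError("classify", exc) from exc

    # --- differential summaries -------------------------------------------
    try:
        stage("differential")
        meth_summary = summarize_regulation(diff_peaks)
        diff_lnc_dir: dict[str, str] = {}
        for rec in diff_peaks:
            if rec.lncrna_id:
                diff_lnc_dir.setdefault(rec.lncrna_id, rec.direction)
        lnc_summary = summarize_regulation(list(diff_lnc_dir.values()))
        binning = bin_lengths(diff_lnc_dir, catalog)
        _write_tsv(binning.coarse, outdir / "length_bins_coarse.tsv")
        _write_tsv(binning.fine, outdir / "length_bins_fine.tsv")
        _write_tsv(chromosome_distribution(diff_peaks), outdir / "chromosome_distribution.tsv")
        fc_by_class = mean_fold_change_by_class(diff_peaks, assignment)
        _write_tsv(fc_by_class, outdir / "fold_change_by_class.tsv")
        expr_summary = summarize_regulation(lnc_expr, labels=("up", "down"))
        summary["differential"] = {
            "peaks": dataclasses.asdict(meth_summary),
            "lncrnas": dataclasses.asdict(lnc_summary),
            "expression": dataclasses.asdict(expr_summary),
            "unresolved_lengths": binning.unresolved,
        }
    except Exception as exc:
        raise StageError("differential", exc) from exc

    # --- integration statistics -------------------------------------------
    try:
        stage("integrate")
        level_a = _methylation_levels(annotated_a)
        level_b = _methylation_levels(annotated_b)
        integration: dict = {}
        shared_levels = sorted(set(level_a) & set(level_b))
        if len(shared_levels) >= 3:
            rho, p, n = correlate_levels(level_a, level_b, method="spearman")
            integration["cross_condition_spearman"] = {"rho": rho, "p": p, "n": n}
        de_dir = {
            r.transcript_id: r.regulation for r in lnc_expr if r.regulation != "unchanged"
        }
        join = join_methylation_expression(diff_lnc_dir, de_dir)
        _write_tsv(join, outdir / "methylation_expression_join.tsv", index=True)
        integration["join"] = {
            m: {e: int(join.loc[m, e]) for e in join.columns} for m in join.index
        }
        expr_by_id = {r.transcript_id: r for r in lnc_expr}
        for cond, levels, key in (
            (config.condition_a, level_a, "meth_expr_spearman_a"),
            (config.condition_b, level_b, "meth_expr_spearman_b"),
        ):
            fpkm_means = {}
            for lnc in levels:
                rec = expr_by_id.get(lnc)
                if rec is None:
                    continue
                means = rec.condition_means()
                if cond in means:
                    fpkm_means[lnc] = means[cond]
            if len(set(levels) & set(fpkm_means)) >= 3:
                rho, p, n = correlate_levels(levels, fpkm_means, method="spearman")
                integration[key] = {"rho": rho, "p": p, "n": n}
        m6a_ids = {l for ap in annotated_a + annotated_b for l in ap.overlap_bp}
        if lnc_expr and 0 < len(m6a_ids & {r.transcript_id for r in lnc_expr}) < len(lnc_expr):
            curve = cumulative_log2fc(lnc_expr, m6a_ids)
            integration["cumulative_log2fc"] = {
                "ks_statistic": curve.ks_statistic,
                "n_clamped": curve.n_clamped,
                "n_m6a": int(len(curve.m6a_values)),
                "n_non_m6a": int(len(curve.non_m6a_values)),
            }
        summary["integration"] = integration
    except Exception as exc:
        raise StageError("integrate", exc) from exc

    # --- targets and networks ---------------------------------------------
    try:
        stage("targets")
        meth_fc = {}
        for rec in diff_peaks:
            if rec.lncrna_id:
                prev = meth_fc.get(rec.lncrna_id, 0.0)
                meth_fc[rec.lncrna_id] = max(prev, rec.fold_change)
        expr_fc = {
            r.transcript_id: r.fold_change
            for r in lnc_expr
            if r.regulation != "unchanged"
        }
        flags = (
            set(config.disease_flags.read_text().split())
            if config.disease_flags
            else set(meth_fc) | set(expr_fc)
        )
        criteria = ScreenCriteria(
            meth_fc_threshold=config.meth_fc_threshold,
            expr_fc_threshold=config.expr_fc_threshold,
        )
        screened = screen_frame = None
        from .networks import screen_cerna_candidates

        screen_frame = screen_cerna_candidates(meth_fc, expr_fc, flags, criteria)
        _write_tsv(screen_frame, outdir / "screened_candidates.tsv")
        screened = list(screen_frame["lncrna_id"])
        cis_rows = []
        for lnc in sorted(diff_lnc_dir):
            if lnc in catalog:
                for mrna in find_cis_targets(catalog.get(lnc), catalog, config.cis_window):
                    cis_rows.append({"lncrna_id": lnc, "mrna_id": mrna})
        _write_tsv(pd.DataFrame(cis_rows, columns=["lncrna_id", "mrna_id"]), outdir / "cis_targets.tsv")
        mrna_frame = expression_frame(mrna_expr)
        trans_rows = []
        if len(mrna_frame.columns) >= 3:
            for lnc in screened:
                rec = expr_by_id.get(lnc)
                if rec is None:
                    continue
                for mrna, r in find_trans_targets(rec.fpkm, mrna_frame, config.trans_threshold):
                    trans_rows.append({"lncrna_id": lnc, "mrna_id": mrna, "r": r})
        _write_tsv(
            pd.DataFrame(trans_rows, columns=["lncrna_id", "mrna_id", "r"]),
            outdir / "trans_targets.tsv",
        )
        summary["targets"] = {
            "n_screened": len(screened),
            "n_cis_pairs": len(cis_rows),
            "n_trans_pairs": len(trans_rows),
        }
    except Exception as exc:
        raise StageError("targets", exc) from exc

    try:
        stage("networks")
        networks: dict = {}
        if config.bindings_lnc_mi and config.bindings_mi_mrna and screened:
            lnc_mi = lio.read_binding_table(config.bindings_lnc_mi, layer="lncRNA-miRNA")
            mi_mrna = lio.read_binding_table(config.bindings_mi_mrna, layer="miRNA-mRNA")
            cerna = build_cerna_network(screened, lnc_mi, mi_mrna, k=config.top_k)
            lio.write_network_edges(cerna, outdir / "cerna_edges.tsv")
            networks["cerna"] = {
                "n_lncrna": len(cerna.nodes_by_layer("lncRNA")),
                "n_mirna": len(cerna.nodes_by_layer("miRNA")),
                "n_mrna": len(cerna.nodes_by_layer("mRNA")),
                "n_edges": cerna.graph.number_of_edges(),
            }
        lnc_frame = expression_frame(lnc_expr)
        if len(lnc_frame) and len(mrna_frame) and len(lnc_frame.columns) >= 3:
            cnc = build_cnc_network(lnc_frame, mrna_frame, threshold=config.cnc_threshold)
            lio.write_network_edges(cnc, outdir / "cnc_edges.tsv")
            degrees = {
                n: d
                for n, d in cnc.graph.degree
                if cnc.graph.nodes[n]["layer"] == "lncRNA" and d > 0
            }
            hub = max(sorted(degrees), key=lambda n: degrees[n]) if degrees else None
            networks["cnc"] = {
                "n_edges": cnc.graph.number_of_edges(),
                "hub_lncrna": hub,
                "hub_degree": degrees.get(hub, 0) if hub else 0,
            }
        summary["networks"] = networks
    except Exception as exc:
        raise StageError("networks", exc) from exc

    # --- optional enrichment ----------------------------------------------
    if config.gmt is not None:
        try:
            stage("enrichment")
            from .integrate import enrichment_test

            gene_sets = lio.read_gmt(config.gmt)
            query = sorted(diff_lnc_dir)
            result = enrichment_test(query, gene_sets)
            _write_tsv(result, outdir / "enrichment.tsv")
            summary["enrichment"] = {"n_sets": int(len(result))}
        except Exception as exc:
            raise StageError("enrichment", exc) from exc

    manifest = {
        "config_hash": config.content_hash(),
        "version": __version__,
        "seed": config.seed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
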
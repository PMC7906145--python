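import numpy as np
import pytest

from lncm6a.model import (
    GenomicInterval,
    PeakRecord,
    Strand,
    TranscriptCatalog,
    TranscriptRecord,
)
from lncm6a.simulate import SimConfig, generate_annotation


def make_transcript(tid, chrom, exon_coords, strand="+", biotype="lncRNA", gene=None):
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_coords)
    span = GenomicInterval(chrom, exon_coords[0][0], exon_coords[-1][1], strand)
    return TranscriptRecord(
        transcript_id=tid,
        gene_id=gene or f"g_{tid}",
        interval=span,
        exons=exons,
        biotype=biotype,
    )


def random_catalog(rng, n_mrna=20, n_lncrna=30, chrom_count=3, span=200_000):
    """A dense random catalog (no planted classes) for oracle comparisons."""
    records = []
    for i in range(n_mrna + n_lncrna):
        biotype = "mRNA" if i < n_mrna else "lncRNA"
        chrom = f"chr{rng.integers(1, chrom_count + 1)}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 4))
        start = int(rng.integers(0, span))
        exons = []
        pos = start
        for _ in range(n_exons):
            length = int(rng.integers(50, 600))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(2, 2000))
        records.append(
            make_transcript(f"{biotype}_{i}", chrom, exons, strand, biotype)
        )
    return TranscriptCatalog(records)


def random_peaks(rng, n, chrom_count=3, span=200_000, condition="CRC"):
    peaks = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, chrom_count + 1)}"
        start = int(rng.integers(0, span))
        width = int(rng.integers(20, 300))
        strand = rng.choice(["+", "-", "."])
        peaks.append(
            PeakRecord(
                interval=GenomicInterval(chrom, start, start + width, strand),
                fold_enrichment=float(rng.uniform(1, 20)),
                condition=condition,
                name=f"p{i}",
            )
        )
    return peaks


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        seed=7,
        n_lncrna=60,
        n_mrna=60,
        class_proportions=(1 / 6,) * 6,
        n_peaks_per_condition=(40, 35),
        n_diff_peaks=10,
        n_screen_meth=3,
        n_screen_expr=3,
        n_de_lncrna=8,
        n_trans_pairs=3,
        hub_targets=10,
        n_mirna=60,
        n_binding_mrna=400,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_annotation(small_config)
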
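# lncm6a

Downstream analysis of lncRNA N6-methyladenosine (m6A) modification from
paired MeRIP-seq + RNA-seq studies, as used in tumor vs adjacent-normal
profiling (e.g. colorectal cancer). The package takes the outputs of the
standard upstream tools — a transcript annotation (GTF), per-condition m6A
peak calls, a differential-methylation table, a transcript FPKM matrix, and
scored miRNA binding predictions — and computes everything downstream:

- **Peak annotation** — filter m6A peaks to lncRNA exons (strand-aware,
  ≥1 bp exonic overlap), count peaks per lncRNA, and build the
  cross-condition peak Venn (shared = ≥1 bp overlap under greedy 1-1
  matching by descending overlap).
- **Positional classification** — assign each lncRNA one of six classes
  relative to the mRNA annotation (exon sense-overlapping, intron
  sense-overlapping, natural antisense, intronic antisense, bidirectional,
  intergenic) by a documented priority order in which overlap evidence
  outranks proximity.
- **Differential integration** — hyper/hypomethylation summaries, length
  and chromosome distributions, per-class mean fold changes,
  methylation × expression cross-tabulation, Spearman correlation of
  methylation level (max peak fold enrichment) with FPKM, cumulative
  |log2FC| curves of m6A vs non-m6A lncRNAs with a Kolmogorov–Smirnov D,
  the 2^−ΔΔCt qRT-PCR fold change, and hypergeometric gene-set enrichment
  with Benjamini–Hochberg adjustment.
- **Target inference and networks** — cis-targets (mRNAs within a 10 kbp
  window), trans-targets (|Pearson r| ≥ 0.9 across samples), candidate
  screening (methylation FC > 7 or expression FC > 2.5, restricted to
  disease-flagged lncRNAs), the tripartite ceRNA network (top-5 miRNAs per
  lncRNA, top-5 mRNAs per miRNA), and the signed coding–non-coding (CNC)
  co-expression network at |Pearson r| ≥ 0.95.
- **Synthetic studies** — a generator that plants all of the above
  (positional classes by exact geometry, shared/unique peaks,
  hyper/hypo fold changes, DE labels, a Gaussian-copula
  methylation–expression correlation, exact-correlation trans targets and a
  co-expression hub) and records the ground truth as JSON, so every stage is
  testable without sequencing data.

## Worked example

Simulate a study and run the full pipeline:

```sh
lncm6a run-synthetic --seed 1 --outdir demo
```

or in Python:

```python
from lncm6a.simulate import SimConfig, generate_full_study
from lncm6a.pipeline import PipelineConfig, run_pipeline

generate_full_study(SimConfig(seed=1), "demo/study")
summary = run_pipeline(PipelineConfig.from_study_dir("demo/study", "demo/results"))
print(summary["peaks"]["venn"])
print(summary["networks"])
```

which prints (seed 1):

```
{'unique_a': 123, 'unique_b': 88, 'shared': 127, 'shared_fraction': 0.3757...}
{'cerna': {'n_lncrna': 16, 'n_mirna': 80, 'n_mrna': 400, 'n_edges': 480},
 'cnc': {'n_edges': 67, 'hub_lncrna': 'LNC00497', 'hub_degree': 61}}
```

Reading the numbers: of the 250 + 215 exonic peaks, 127 are shared between
conditions (37.6% of the union — the generator's planted shared fraction);
the 16 screened disease-associated lncRNAs with their disjoint top-5
miRNA/mRNA selections give a 16 + 80 + 400-node ceRNA network; and the
planted co-expression hub is recovered with its 61 CNC partners.
`demo/results/` holds per-stage TSVs (annotated peaks, classes, length bins,
screening provenance, network edge lists importable into Cytoscape) plus
`summary.json` and a run manifest.

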
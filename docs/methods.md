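# Methods

## Data model and coordinates

All genomic features use 0-based half-open coordinates internally. GTF
(1-based closed) and the MACS/diffReps-style tables (1-based) are converted
on read and back-converted on write; BED is passed through. Readers are
total on their dialects: every line is parsed or rejected with its line
number; the only silent-looking exclusion — GTF transcripts whose biotype is
not mapped by the (injectable) biotype rule — is counted and logged. The
default rule maps `lncRNA`, `lincRNA`, `antisense` and
`processed_transcript` to lncRNA and `protein_coding` to mRNA, because
annotation dialects disagree on lncRNA sub-biotypes.

Fold changes printed as `inf`/`-Inf` (a zero denominator in the upstream
caller) are kept as +infinity with the direction carried by the regulation
label. Infinite values sort above all finite ones, pass any screening
threshold, and are excluded from means and correlations (with counts
logged) — no pseudocounts are invented.

## Peak annotation

A peak is assigned to a lncRNA when it overlaps ≥ `min_overlap_bp`
(default 1) of that lncRNA's exons with a compatible strand; unstranded
peaks match both strands, since MeRIP peak callers often emit unstranded
intervals. A peak on exons of several lncRNAs is annotated to all of them,
so lncRNA-level tallies may exceed peak-level tallies (the upstream studies
report both, implying one-to-many assignment).

"Shared" between conditions is deliberately simple: ≥ 1 bp overlap with
compatible strands, resolved to a one-to-one matching greedily by descending
overlap (ties broken by input order, so results are deterministic). The
overlap floor and an optional reciprocal-overlap fraction are exposed as
parameters because peak-set comparison conventions vary between studies.
With this rule `unique_a + shared ≤ |A|`, symmetric in the two sets, and the
shared fraction `shared / (unique_a + unique_b + shared)` is invariant under
swapping the inputs.

## Positional classification

Each lncRNA gets exactly one of six classes by the first rule that fires in
priority order: exon sense-overlapping (≥ 1 bp exon–exon, same strand) >
intron sense-overlapping (span overlap, same strand, zero exon–exon bp) >
natural antisense (≥ 1 bp exon–exon, opposite strand) > intronic antisense
(wholly inside one intron of an opposite-strand mRNA) > bidirectional >
intergenic (nothing fired). Bidirectional means: no span overlap with any
mRNA, an opposite-strand mRNA transcribing away from the lncRNA
(head-to-head), and TSS-to-TSS distance ≤ 1,000 bp (default window).
Overlap evidence outranks proximity evidence; the priority order and window
are parameters. Classification is annotation-positional: all mRNAs are
considered, not only expressed ones. A lncRNA that span-overlaps an mRNA on
the opposite strand without exon–exon overlap and without being intronic
falls through to intergenic — such straddling cases are rare and no
published rule covers them.

The test suite carries an independent brute-force classifier (all rules
against all mRNAs, no interval index) and checks equivalence on random dense
catalogs; this validates the implementation against its own documented
rules, which is the strongest claim possible when the original rule set is
not published.

## Differential and integration statistics

Percentages are rounded half-away-from-zero to one decimal, which
reproduces printed two-category percentage pairs exactly (e.g. 261/396 →
65.9 / 34.1). lncRNA "length" is the mature (summed exonic) length — the
conventional reading of "lncRNA length" — switchable to genomic span.
Length histograms use 1,000 bp bins from 1 bp and 200 bp bins inside
1–1,000 bp, per direction.

The internal differential-methylation caller is a minimal enrichment-ratio
rule for matched peaks (larger/smaller enrichment, hypermethylated when the
case side is larger; unmatched peaks get infinite fold change in their host
condition's direction unless a floor is configured). It exists so synthetic
end-to-end runs are self-contained; real analyses should feed a
diffReps-style table, whose format is accepted as input.

"Methylation level" of a lncRNA in a condition is the maximum fold
enrichment over its peaks (switchable to mean); correlation with expression
uses Spearman's rank by default with the large-sample p approximation, and
pairs with infinite or missing values are dropped (n reported, minimum 3).
The cumulative curves compare |log2FC| between lncRNAs with and without m6A
peaks; infinite |log2FC| (infinite or zero fold change) is clamped to the
maximum finite value + 1 so every lncRNA stays represented, and a
two-sample Kolmogorov–Smirnov D summarizes the separation. Gene-set
enrichment is the upper-tail hypergeometric test P(X ≥ k) against
user-supplied GMT collections with Benjamini–Hochberg adjustment across
sets; replicating any curated annotation database is out of scope.

qRT-PCR fold change is 2^−ΔΔCt with
ΔΔCt = (Ct_target,case − Ct_ref,case) − (Ct_target,ctrl − Ct_ref,ctrl).

## Targets and networks

Cis-targets are mRNAs whose span overlaps the lncRNA span padded by the
window (default 10 kbp) — i.e. gap strictly less than the window under
half-open arithmetic — strand-agnostic. The trans-target rule "correlation
coefficient ≥ 0.9" is read as |Pearson r| ≥ 0.9 on the FPKM profiles (a
p-value threshold of ≥ 0.9 would select non-associations); the signed r is
reported and a positive-only mode is available. Candidate screening keeps
disease-flagged lncRNAs with methylation FC > 7 or expression FC > 2.5;
the disease association is an input flag column, not a literature lookup.
Top-k selection (default 5) breaks score ties by partner id ascending, so
networks are deterministic. CNC edges connect lncRNA–mRNA pairs with
|Pearson r| ≥ 0.95; the edge sign is the correlation sign (positive =
"positively regulates"). Rows with non-finite values or zero variance are
excluded from the correlation matrix with a logged count.

## Synthetic-study generator

The generator is first-class, tested code; its defaults are the study
conditions every test and the acceptance script run under.

*Geometry.* One transcript unit per 500 kbp region, 100 regions per
synthetic chromosome. Every non-intergenic lncRNA is built against its own
anchor mRNA (3 × 500 bp exons, 8 kbp introns) with the exact geometry of its
planted class; intergenic lncRNAs get an empty region. The spacing makes
planted classes exact (no accidental higher-priority rule can fire) and
isolates cis windows. Mature lncRNA lengths are log-normal (median ≈ 700 bp,
clamped to 100–6,000), putting roughly half below 1 kbp as in tumor
profiles.

*Peaks.* Defaults: 250 and 215 peaks per condition with shared fraction
0.375, hosts drawn so 91% / 7% / 2% of methylated lncRNAs carry 1 / 2 / 3
peaks — the proportions reported for these studies. Shared peaks occupy
identical exonic intervals in both conditions; each unique peak gets its own
host, so the Venn is exact by construction. 60 differential peaks are
planted on distinct shared hosts (34.1% hypermethylated in expectation);
fold changes are 1 + log-normal, except a fixed subset of 8 hosts planted
above the FC > 7 screen. These counts are a ~1/15 desk-scale rendition of
the profiled study (whose peak sets number in the thousands); the printed
ratios are kept exactly, the absolute counts scaled.

*Expression.* Log-normal FPKM (meanlog 3, sdlog 1) over 5 + 5 samples, with
per-sample log-scale noise (default sd 0.3). Methylated lncRNAs' baselines
follow a Gaussian copula against their standardized log fold enrichment at
the planted correlation (default 0.5), so the noise-free, no-DE limit gives
Spearman exactly 1. Fifty DE lncRNAs get a planted log2FC (mean 3, sd 0.5,
floored at 1.1; 27% up), including five hypomethylated-and-down lncRNAs so
the methylation × expression join has a planted overlap cell; eight DE
lncRNAs are flagged above the FC > 2.5 screen, giving a deterministic
16-candidate screened set. Trans-target mRNAs (10 pairs at r = 0.95) and one
hub lncRNA with 61 partner mRNAs at |r| = 0.995 are constructed by
orthogonalized noise so the *sample* correlation is exactly the planted
value. DE calling on the generated table is fold-change ≥ 2 only — no
significance test — so noise-free recovery is exact and no upstream caller
is imitated.

*Bindings.* Scores are strictly distinct within each source (unique top-5);
disjoint mode draws partners globally without replacement, which yields the
k / k² node-count law (16 lncRNAs → 80 miRNAs → 400 mRNAs at k = 5).

*What the generator does not emulate:* read-level data, motif (DRACH)
placement, replicate dispersion beyond log-normal noise, batch effects, or
correlated decoys. Passing recovery tests therefore demonstrates that the
pipeline inverts its own generative assumptions exactly — not that it is
robust to real-data pathologies.

*Randomness.* One integer seed; each component derives its generator from
the seed via fixed offsets, so components are reproducible independently and
whole bundles are byte-identical across runs.

## Problem sizes

Tests run the generator at 60–500 lncRNAs; the recovery suites use 20 seeds
at the 500-lncRNA default, and the acceptance script 5 seeds, which keeps
the full run in seconds while the binomial planting bounds stay tight.
Study-scale arithmetic (8,332 / 7,064 peak Venn, 396-peak tallies) is
computed at full published size, since these are cheap interval and counting
operations.

## Known limitations

- The shared-peak rule, classifier windows and tie-breaks are this
  package's own documented conventions; published studies rarely state
  theirs, so cross-study count comparisons are approximate by nature.
- The minimal differential caller ignores coverage and replicate variance;
  it is for synthetic self-consistency only.
- Screening depends on a user-supplied disease-flag list; no disease
  database is bundled.
- CNC networks compute a dense correlation matrix; at very large catalogs
  (≫10⁴ × 10⁴) this should be chunked.
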
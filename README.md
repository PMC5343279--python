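# chipcal

Downstream analysis toolkit for studies of transcription-factor control
of neuronal calcium signalling: ChIP-seq peak characterization
(replicate consensus, genomic annotation, chromatin-context scoring,
E-box cluster enrichment, sliding-window conservation profiling),
ChIP-qPCR enrichment arithmetic, and store-operated calcium entry
(SOCE) trace quantification — plus a ground-truth synthetic-data
generator so the entire pipeline runs and is verified without any
external download.

It is written for the common experimental arc in regulatory
neurogenomics: call binding sites for a basic helix-loop-helix (bHLH)
transcription factor from replicate ChIP-seq experiments, ask where
those sites fall relative to genes and chromatin marks, zoom into a
candidate regulatory element (motif clusters, evolutionary
conservation), validate binding by ChIP-qPCR, and measure the
physiological consequence in calcium-imaging traces.

## What it computes

**Consensus peaks.** Regions covered by ≥1 peak in *every* replicate
set (per-base boolean AND, most-conservative coordinates), scored by
the minimum replicate score. Peak scores use the MACS convention
score = −10·log₁₀(p).

**Midpoint annotation.** Each consensus midpoint is classified with
priority promoter > exonic > intronic > intergenic, where the promoter
is the closed ±1000 bp window around any strand-aware TSS; signed
distances to the nearest TSS feed a binding-preference histogram.

**Chromatin context.** Per-peak mark score = max overlapping segment
value of a histone/CTCF track; per-category means form a heat-map
matrix against a genome-wide baseline Σ(value·length)/genome_size.

**Motifs and conservation.** Forward-strand E-box (CANNTG) scanning
(the pattern is its own reverse complement), background density over
intron sets, cluster enrichment (observed/window)/background — four
E-boxes in 130 bp over a 1/180 bp background ≈ 5.5-fold — and 50 bp
sliding-window profiles of conservation and binding score across a
550 bp span, compared by Spearman rank correlation.

**ChIP-qPCR.** Input-dilution adjustment (−log₂(1/f), i.e. 3.32 cycles
for a 10% aliquot), %input = 100·2^(adjusted input Ct − ChIP Ct), fold
enrichment = target %input / control-antibody %input, and ΔΔCt
relative expression.

**SOCE metrics.** ΔF/F₀ normalization (background-subtracted minimum
set to exactly 1), phase segmentation at the thapsigargin and Ca²⁺
re-addition events, per-wave peak heights above the pre-stimulus
baseline, and trapezoid areas with an early/late split of the SOCE
wave (default 50 s), summarized per condition as median/quartiles and
pairwise median ratios.

## Worked example

The end-to-end demo simulates a dataset (2 × 200 kb genome, 24 genes,
60 planted binding sites, three jittered replicates, seven mark tracks,
a conserved intronic element carrying four E-boxes in 130 bp, qPCR
tables planted at known folds, and 30-cell calcium-trace cohorts per
condition) and runs every stage:

```sh
chipcal demo --outdir run --seed 0
```

Selected outputs from that run and what they mean:

`run/category_summary.tsv` — the consensus peaks (55 of the 60 planted
sites survive the 5% per-replicate dropout) partition cleanly across
genomic categories:

```
category    count  percent
promoter       12    21.82
exonic         13    23.64
intronic       15    27.27
intergenic     15    27.27
```

`run/motif_report.json` — the planted cluster is recovered and its
enrichment over the configured intronic background is
(4/130)/(1/180) = 5.54, "approximately fivefold":

```
"n_eboxes": 4,
"fold_enrichment_vs_configured_background": 5.538461538461538
```

`run/concordance.json` — binding and conservation profiles across the
element co-vary (Spearman ρ = 0.844), the signature of a functional
conserved element.

`run/enrichment.csv` — planted ChIP-qPCR folds are recovered through
the full %input arithmetic (planted 35 and 100 at the target element
in the two developmental stages; 2 at flanking introns; 1 at the
nontarget):

```
amplicon,percent_input_target,percent_input_control,fold,...
Stim1_int1,0.1086,0.0500,2.1712,...
Stim1_int2_E14,4.4509,0.0500,89.0181,...
Stim1_int2_P0,1.5793,0.0500,31.5853,...
Stim1_int3,0.1031,0.0500,2.0625,...
nontarget,0.0504,0.0500,1.0076,...
```

`run/soce_ratios.csv` — the knockdown cohort was planted with a
1.4-fold SOCE increase and the rescue cohort at control level; the
recovered median ratios:

```
metric           numerator  denominator  median_ratio
wave2_peak       knockdown  control      1.37241
wave2_auc_early  knockdown  control      1.37928
wave2_peak       rescue     control      1.03130
```

Rerunning with the same seed reproduces every file byte-for-byte (see
`run/manifest.json` for checksums); each stage is also available as a
subcommand on real data files (`chipcal consensus`, `annotate`,
`context`, `motif`, `conserve`, `qpcr`, `soce`).

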
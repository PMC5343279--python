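# Methods

`chipcal` quantifies three experimental read-outs that together describe
how a basic helix-loop-helix (bHLH) transcription factor regulates a
target gene: genome-wide ChIP-seq binding sites and their chromatin
context, locus-level validation by ChIP-qPCR and motif/conservation
analysis, and the downstream physiology — store-operated calcium entry
(SOCE) — measured by live-cell calcium imaging. Every stage is exercised
end-to-end against a synthetic-data generator with recorded ground
truth.

## Coordinate conventions

All intervals are 0-based half-open (BED-native). The only place 1-based
closed coordinates appear is `GenomicInterval.browser_str()`, which
formats positions the way genome browsers print them. Chromosome names
are matched exactly; there is no `chr` aliasing, so a mismatched genome
build fails loudly rather than returning empty overlaps. Peak scores
follow the MACS convention, score = −10·log10(p); `score_to_pvalue` /
`pvalue_to_score` are exact inverses, and the conventional calling
cutoff p = 1×10⁻⁵ corresponds to score 50.

## Consensus peaks

A consensus peak is a maximal run of bases covered by at least one peak
in *every* replicate set — the per-base boolean AND of replicate
coverages, computed by a sorted two-pointer interval sweep after
merging each replicate (book-ended peaks from one replicate count as a
single covered region, so a within-replicate peak boundary never splits
a consensus region). Design choices where the field admits
alternatives:

* **Coordinates = the intersection**, the most conservative region that
  every replicate supports. A union-style criterion can be emulated by
  merging the inputs first.
* **Score = min over replicates** of that replicate's best overlapping
  peak score. Recomputing p-values from read pileups is out of scope
  (peak files are the input), so the minimum is the conservative
  summary.
* **Overlap threshold** defaults to 1 bp (`min_overlap` is exposed);
  "overlapping" without a stated minimum is the common convention.

Correctness is checked two independent ways: a per-base boolean-AND
numpy oracle on 200 random 100-kb genomes, and `bedtools intersect` on
a random fixture.

## Midpoint annotation

Peak midpoints (floor of (start+end)/2) are classified against
transcript models with priority **promoter > exonic > intronic >
intergenic**. The promoter is the *closed* window ±1000 bp around any
transcript's strand-aware TSS and overrides gene-body status; a base in
any annotated exon is exonic regardless of other overlapping
transcripts' introns. The closed right edge (|d| ≤ 1000 is promoter) is
a choice; the alternative half-open edge moves only peaks landing
exactly on the boundary. Signed TSS distances are positive downstream
and negative upstream relative to gene strand, with |distance| ties
broken toward the lexicographically smaller gene id so results are
deterministic.

## Chromatin context

Each peak receives one score per mark track: by default the **maximum**
value among track segments overlapping it by ≥1 bp (the score of the
strongest called histone/CTCF peak it touches; 0 when none), with a
coverage-weighted mean available via `agg="coverage_mean"`. The
genome-wide baseline is the expected score of a uniformly random base,
Σ(value·length)/genome_size (`mode="segment_mean"` restricts to covered
bases). Empty categories yield NaN cells, never 0 — an absent mean and
a zero mean are different facts.

## E-box scanning and cluster enrichment

The E-box CANNTG is scanned on the forward strand only: the pattern
class is its own reverse complement, so a double-strand scan would
count every site twice. Overlapping matches are counted by default
(`CACATGTG` contains two); a non-overlapping mode is provided since the
choice slightly affects density estimates. `N` never matches.
Background density is pooled hits over pooled length across the
supplied sequences (e.g. all introns); cluster enrichment is the plain
density ratio (observed/window)/background. With the mouse intronic
background of ~1 E-box per 180 bp, four E-boxes in 130 bp give
(4/130)/(1/180) ≈ 5.5-fold.

## Sliding-window profiles

Conservation (PhyloP-style) and binding-score profiles are means of
per-bp values in windows fully inside a span (defaults: 50 bp window,
550 bp span, step 1 → 501 windows), computed by cumulative sums and
verified against the naive O(n·w) moving average to 1e-9. Track inputs
are expanded to per-bp values first; uncovered positions contribute 0
by default (conservation tracks may have gaps), or NaN when the caller
prefers to mask. Profile concordance is the Spearman rank correlation
on an identical window grid. Random exonic/intronic reference profiles
sample features of length ≥ span without replacement, with a random
in-feature offset, under a caller-supplied seed.

## ChIP-qPCR arithmetic

For an input aliquot that is a fraction *f* of the IP chromatin, the
input Ct is adjusted by subtracting log2(1/f) — 3.32 cycles for f=0.10;
log2(10) is kept at full precision internally, 3.32 being display
rounding. Then %input = 100·2^(adjusted input Ct − ChIP Ct), and fold
enrichment is the target antibody's %input divided by the unrelated
control antibody's at the same amplicon. Replicates are aggregated as
the arithmetic mean of %input per antibody before the ratio (a
geometric-mean option exists; at zero noise both agree, and the
aggregation order across technical vs biological replicates is the
caller's choice of how rows are grouped). `relative_expression`
implements ΔΔCt against a housekeeping reference. The whole chain is
invariant to a constant shift applied to every Ct.

## SOCE trace metrics

Traces are normalized as ΔF/F₀ with F₀ = the background-subtracted
minimum of the record, so the normalized floor is exactly 1; a
background ≥ the raw minimum is an error (background is a supplied
per-field scalar — image-derived background estimation is out of
scope). The record splits at the two protocol events into pre
[0, tg), ER-release wave [tg, ca), and SOCE wave [ca, end].

Peak heights are maxima above the **pre-thapsigargin baseline** (mean
ΔF/F₀ of the pre-window; the normalization floor of 1 is available via
`baseline="floor"`). Areas use the trapezoid rule on baseline-subtracted
values clipped at 0 (keeping areas non-negative under noise), with
linear interpolation at window boundaries that fall between samples —
this makes early + late = total exact and reproduces closed-form areas
for rectangular pulses on the 6-s grid. The early SOCE phase defaults
to the first 50 s after Ca²⁺ re-addition. Cohort summaries report
median, quartiles and extrema per condition (box-plot semantics) plus
pairwise median ratios; hypothesis testing (Kruskal–Wallis, ANOVA, t)
is deliberately left to standard statistics routines on the tidy
output.

## Synthetic-data generator

One integer seed feeds named, deterministically derived substreams
(`SeedSequence(seed, spawn_key=…)`), one per artifact, so regenerating
one artifact never perturbs another and identical configs are
byte-identical.

Defaults, chosen once as a desk-scale caricature of the real study
conditions:

| group | default | why |
|---|---|---|
| genome | 2 chromosomes × 200 kb | smallest size leaving room for genes, decoys, and intergenic sites |
| genes | 24 genes, 4 exons × 600 bp, introns 2 kb, gaps 4 kb | exons exceed the 550 bp profile span so exonic reference windows fit in one feature; gap centres sit > 1 kb from every TSS |
| truth sites | 60 × 300 bp, 15 per category | planted at feature centres (TSS, exon 3, intron 2, gap centre) so midpoint categories are unambiguous even after jitter |
| replicates | boundary jitter SD 10 bp, dropout 5%, 15 decoys each | decoys are kept disjoint from truth and from all other replicates' decoys, so a decoy-only consensus is empty by construction |
| motif cluster | 4 E-boxes in 130 bp, background 1/180 bp | the cluster geometry being tested; background density is a configured constant, not re-derived from the toy sequence |
| conservation | baseline mean 0, exons 1, element 2 (SD 0.3, 25 bp tiles) | exons more conserved than introns, the planted element more conserved still |
| qPCR | folds {35, 100, 2, 2, 1}, Ct noise SD 0.2, 6 replicates | strong target-site enrichment at two developmental stages, weak flanking enrichment, a flat nontarget; noise at instrument scale |
| traces | 30 cells/condition, 6 s × 600 s, tg 100 s, ca 400 s, SOCE scale {1.0, 1.4, 1.0}, 10% per-cell amplitude scatter | two-wave protocol with a knockdown-sized SOCE increase and a rescue condition |

Waves are alpha-functions (t/τ)·e^(1−t/τ) — a standard smooth rise/decay
with unit peak; only relative amplitudes and areas are asserted about
them, never absolute shape. The E-box planter rewrites a window to
contain *exactly* n motifs, resampling background bases until a scan of
the window plus 5 bp of flanking context finds only the planted
occurrences.

What the generator does **not** emulate: read-level data (peaks are the
input), realistic base composition or motif clustering statistics
(background sequence is uniform, so its natural E-box density is 1/256
per bp, not the genomic 1/180 — which is why the enrichment arithmetic
takes the background density as a parameter), overlapping transcript
isoforms, irregular sampling or photobleaching in traces, and
cell-to-cell kinetic variability beyond amplitude scatter. Passing
recovery tests therefore demonstrates the *arithmetic* is right under
the stated model, not that the model captures every property of real
cortical-tissue data.

## Problem sizes and numerical notes

The default demo (2×200 kb genome, 60 sites, 90 traces) runs in well
under a minute; consensus-oracle checks use 200 random 100-kb genomes.
Percent rounding in summaries is display-side only. Degenerate inputs
are errors, not silent zeros: empty replicate lists in a consensus call
return an empty result, while an empty Ct group, a background above the
signal floor, an event time outside the record, or overlapping track
segments all raise with a message naming the offending input.

## Known limitations

* Per-region consensus p-values/FDRs are not recomputed from replicate
  p-values; the min-score stand-in is conservative but not a
  probability statement.
* Nearest-gene assignment uses TSS distance only; it is not a curated
  target-gene mapping.
* The qPCR module assumes equal amplification efficiency across
  amplicons (no standard-curve correction).
* `random_region_profiles` requires features at least as long as the
  span; with real annotations most exons are shorter than 550 bp, so
  exonic reference profiles there would need concatenation or a
  shorter span.
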
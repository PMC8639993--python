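# Methods

## Coordinate conventions and interval algebra

All coordinates are 0-based half-open (BED convention); GTF input is
converted on read (1-based inclusive → 0-based half-open). Chromosome
names compare by exact string equality — no "chr" aliasing — and a
validation warning lists chromosomes present in only one of two inputs,
since silent aliasing would zero out every overlap.

Peak sets are merged (gap 0) within each factor before any counting, so
a "site" always means a maximal merged peak and Venn counts are well
defined. Two intervals overlap iff they share ≥ `min_overlap` bp
(default 1, the weakest assumption; exposed as a flag). Strand is
ignored for overlap: a peak occupies a site regardless of orientation.

## Co-occupancy and differential occupancy

`classify_two` counts, for each merged peak set, the peaks overlapping
≥ 1 peak of the other set. The single reported "shared" number is taken
from the first-named factor's side; when the two sides disagree
(many-to-one overlaps) a machine-readable warning is attached rather
than silently printing one of two different numbers. The synthetic
generator plants only one-to-one overlaps, where both sides provably
coincide.

"Lost enrichment" is operationalized as peak-overlap loss: a wild-type
co-occupied site is *retained* iff a knockout peak still overlaps it,
else *lost*; knockout peaks overlapping no wild-type peak of the factor
are *gained*. No quantitative re-scoring of knockout signal is
attempted — differential read-count testing is out of scope, and the
site counts this package reports are peak-comparison counts.

## Annotation

Promoter windows cover `upstream` bp 5′ and `downstream` bp 3′ of the
TSS (defaults 2000 and 500), oriented by gene strand: `[tss − up,
tss + down)` on `+`, and the mirror image `[tss − down + 1,
tss + up + 1)` on `−`, clipped at chromosome bounds. Enhancer windows
are unstranded, centered on the record midpoint ⌊(start + end)/2⌋.

Feature assignment is exclusive with priority promoter > 5′UTR > 3′UTR
> exon > intron > distal. Introns are the gene span (min exon start to
max exon end) minus merged exons; one TSS per gene, taken from the gene
record — transcript-isoform-aware TSS selection is deliberately out of
scope. A site overlapping several promoters is linked to the gene whose
TSS is nearest the site midpoint (ties to the smaller gene_id);
enhancers are linked to the gene with the nearest TSS. These
nearest-TSS rules are the least surprising choice where no rule is
otherwise forced.

The Fig-3b-style category distribution and the promoter window used for
site filtering share the same window parameters by default, but the
window is a parameter everywhere rather than an assumption.

## Coverage and NCIS normalization

`coverage_from_reads` piles each read (optionally 3′-extended to a
fragment length, strand-aware, clipped at chromosome ends) onto
per-base vectors and retains the 5′ start positions; binned counting
assigns reads to fixed-width bins (default 1000 bp, exposed as a flag;
the last partial bin is kept) by 5′ start — deterministic and standard
for count-based normalization. Fragment extension is off by default:
synthetic reads are generated at final fragment length, and fragment
size is a library property, not an analysis parameter.

RPM scaling multiplies by 10⁶ / library size. Normalized tracks come in
two modes, since published figures do not always state which is shown:
`subtract` (max(c − r·b, 0), then RPM-scaled — floored at zero because
enrichment displays are non-negative) and `fold` ((c + p)/(r·b + p),
pseudocount p = 1). Note that the per-base fold ratio is Jensen-biased
above 1 at shallow coverage (E[1/(b+1)] > 1/E[b+1]); it approaches 1
over background only when per-base counts are well above 1.

### The background scaling factor

With bins indexed by total count t\_i = c\_i + b\_i, the cumulative
ratio r(τ) = Σ c\_i / Σ b\_i over bins with t\_i ≤ τ is an unbiased
estimate of the background ratio for any τ below the enrichment range
(conditional on t\_i, c\_i is binomial with success probability
determined solely by the two background rates, so truncating on totals
does not bias the ratio). The estimator therefore wants τ as large as
possible — more reads, less variance — while still excluding enriched
bins, which occupy the top of the total-count ordering.

`ncis_factor` proceeds in two steps:

1. **Bin widening.** While the mean total per bin is < 1, adjacent bin
   pairs are aggregated (doubling the effective width). Sub-unity bins
   carry too little information per threshold step for the scan below.
2. **Threshold scan.** Distinct totals are scanned in increasing order;
   the returned r is r(τ\*) at the smallest τ (from the second distinct
   total up) where at least `min_fraction` (default 0.8) of all bins
   are included and r(τ) ≥ r(τ\_prev). The first non-decrease of the
   cumulative ratio marks the onset of signal bins; the inclusion floor
   keeps that decision out of the noisy low-count head of the scan,
   and is safe because enriched bins are assumed ≤ 5 % of the genome —
   the lower 80 % of the total-count ordering is background-pure. If no
   threshold qualifies, the ratio at the largest total is returned with
   `converged=False` and a warning.

At genome scale the classical first-non-decrease rule works because
even the smallest thresholds aggregate tens of thousands of bins. At
desk scale (a 1 Mb genome, ~10³ bins) the first few thresholds hold
tens of reads, and stopping on a chance non-decrease there yields
10–30 % errors; the inclusion floor restores the intended behavior.
Deterministic throughout: same bins in, same r out, and the estimate is
invariant to bin order (the scan is set-based per distinct total) as
long as no widening occurs — widening aggregates genomically adjacent
bins, which is deliberate.

A hard limit worth knowing: the ratio's sampling sd is ≈
√(1/C + 1/B) for C chip and B control background reads included. A
1 Mb genome at 0.5 control reads per kb-bin holds only ~500 control
reads, capping precision at ~8 % sd — no estimator recovers r within
10 % in 95 % of replicates from such data. The recovery tests therefore
run at background densities of 2–5 reads per kb-bin; the generator's
default (5/kb) is the desk-scale analogue of a ~15 M-read input library
over a mammalian genome.

## Metagene layer

Reference-point mode only (no gene-body scaling): each region
contributes the window [anchor − half\_width, anchor + half\_width)
split into `n_bins` equal bins, bin order reversed for minus-strand
anchors so bin 0 is always 5′ in transcription orientation. The default
geometry — 1 kb each side of the anchor at 50 bins (40-bp bins) — reads
"50 bins" as 50 bins total across the window, matching the bin-count
semantics of the metagene packages this layer emulates; both half-width
and bin count are parameters.

Windows clipped at chromosome ends average over covered positions only
(absent positions excluded, not zero-filled, which would bias edge
promoters); fully uncovered bins are NaN and are excluded per-bin from
column means, with missing rows counted and reported. Heatmap ordering
blocks rows by occupancy group (declared group order) and sorts within
group by descending row-mean of the ordering track, ties preserving
genomic coordinate order. Rendering is a thin optional layer — every
numeric surface is the matrix/profile itself.

Group comparisons take per-region mean signal within a relative window
and apply a two-sample two-tailed Welch t-test (scipy
`ttest_ind(equal_var=False)`), with the degenerate convention t = 0,
p = 1 when both groups are constant with equal means.

## Expression integration

Fold changes are log2((a + p)/(b + p)) with pseudocount 1; direction is
the sign of the fold change with threshold 0 by default (no cutoff is
otherwise forced), with an optional q-value gate (genes above the
cutoff classified "unchanged") for workflows that want a significance
filter. The pipeline never fits a differential-expression model — it
consumes normalized tables.

Box statistics use linear-interpolation quartiles (numpy default,
equivalent to R type 7 used by ggplot); whiskers extend to the most
extreme observation within 1.5 IQR of the hinges, points beyond are
outliers. The six-group partition crosses three occupancy classes with
up/down direction; "unchanged" genes are reported per class and
occupied genes missing from the expression table are listed as
unmatched — conservation over the input gene universe is an invariant,
nothing is silently dropped.

## Synthetic data

Every generator is a pure function of `SyntheticConfig`; independent
generators draw from independent streams derived from the master seed
by fixed labels, so one generator's draw count cannot shift another's
output, and a given seed reproduces byte-identical files.

What it emulates: per-class peak counts and widths (defaults plant the
study conditions: 2060/3108 factor-exclusive peaks, 1128 one-to-one
shared pairs, widths 200–600 bp, ≥ 2 kb between distinct sites, with a
knockout set losing 841 designated shared sites and gaining 9 novel
ones); Poisson background reads with a known chip:control ratio
(default 0.7) plus triangular-kernel enrichment at designated sites
(default 50 extra reads per site — triangular because a cheap bounded
unimodal shape suffices; the shape is not an analysis surface);
non-overlapping gene models with stranded TSSs; log-normal expression
with planted per-group fold changes (baseline median 200 counts, noise
sd 0.25 log2 units around group means).

What it does not emulate: read sequences and sequencing error,
mappability structure, replicate variance, many-to-one peak overlaps,
fragment-length variability. Passing tests therefore demonstrate the
correctness of the counting/normalization machinery under the stated
statistical model, not robustness to real-data artifacts such as
blacklist regions, copy-number variation or antibody efficiency
differences.

Problem sizes used in the test suite: peak plantings at the study's
printed totals (~7400 peaks on 24 Mb); NCIS recovery on 1 Mb genomes
with 25 enriched sites (1 % of bins), 100 seeded replicates per planted
r ∈ {0.5, 1, 2}; oracle-equivalence suites at ≤ 500 intervals / ≤ 50
regions where per-base brute force is exact and fast.

## Known limitations

- Venn counting is reference-side (first-named factor) with an
  asymmetry warning; real data with many-to-one overlaps will show
  shared\_A ≠ shared\_B and requires interpreting both numbers.
- The NCIS inclusion floor assumes enrichment occupies ≤ ~20 % of bins
  by count; datasets with broader enrichment (e.g. some histone marks
  genome-wide) would need a lower floor and would then inherit the
  small-sample instability discussed above.
- Per-base fold enrichment is biased upward at shallow coverage; use
  subtract mode or deeper simulated libraries when absolute fold values
  matter.
- One TSS per gene; no isoform-aware promoter calling.
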
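# cooccupy

Combinatorial transcription-factor co-occupancy, differential binding
upon knockout, and NCIS-normalized metagene profiling for ChIP-seq peak
sets — with a fully ground-truthed synthetic-data module so every stage
is verifiable at desk scale.

## The problem

During neutrophil differentiation, the zinc-finger repressor GFI1
recruits the NuRD remodeling complex (via its ATPase subunit CHD4) to
chromatin in granulocyte–monocyte progenitors (GMPs). Analyzing how two
(or more) factors share genomic sites, what happens to one factor's
occupancy when the other is knocked out, and how chromatin state at
those sites tracks gene expression requires a chain of small, exacting
computations:

- **co-occupancy classification** — merged peak sets compared by
  overlap, yielding Venn counts of sites occupied by factor A, factor B
  or both;
- **differential occupancy** — wild-type co-occupied sites labeled
  *lost* or *retained* in a knockout peak set, plus knockout-specific
  *gained* sites;
- **feature annotation** — sites assigned to promoter / 5′UTR / 3′UTR /
  exon / intron / distal categories, promoters defined as −2 kb…+500 bp
  around the TSS, enhancer windows centered on atlas-record midpoints;
- **NCIS background normalization** — the ChIP:input background scaling
  factor *r* estimated from low-total-count genomic bins, so coverage
  can be compared across libraries as fold enrichment or
  background-subtracted RPM;
- **metagene profiles** — strand-aware binned signal matrices around
  TSSs or enhancer centers, occupancy-sorted heatmaps and mean
  profiles;
- **expression integration** — occupancy classes crossed with the
  direction of expression fold change into six gene groups, compared
  with Welch *t*-tests and Tukey box statistics.

Each stage consumes and emits the field's plain-text formats (BED6,
GTF, bedGraph, TSV, JSON). A synthetic-data module plants peak sets,
Poisson read coverage with a known background ratio, gene models and
expression tables with a machine-readable truth manifest, so that every
operation can be tested against known answers.

## The NCIS estimator

For genome bins *i* with ChIP count *c\_i* and control count *b\_i*,
let *t\_i = c\_i + b\_i* and scan the distinct totals τ in increasing
order. The cumulative ratio

r(τ) = Σ\_{t\_i ≤ τ} c\_i / Σ\_{t\_i ≤ τ} b\_i

is flat at the background ratio *r* while only background bins are
included and rises once enriched bins enter. `ncis_factor` first widens
bins (pairwise aggregation) until the mean total is ≥ 1, then returns
r(τ\*) at the first τ where at least 80 % of bins are included and r(τ)
stops decreasing. See `docs/methods.md` for the reasoning behind the
stopping rule.

## Worked example

`examples/01_cooccupancy_venn.py` plants the study conditions — 3188
GFI1 peaks and 4236 CHD4 peaks with 1128 one-to-one overlapping pairs —
and classifies them:

```
 GFI1_only: 2060
 CHD4_only: 3108
    shared: 1128
```

`examples/02_differential_knockout.py` builds the knockout CHD4 set
(retaining 287 co-occupied sites, adding 9 novel peaks) and calls
differential occupancy:

```
co-occupied sites in WT : 1128
lost CHD4 in knockout   : 841
retained CHD4           : 287
gained (KO-specific)    : 9
```

`examples/03_ncis_metagene.py` simulates reads with a planted
background ratio of 0.7 and recovers it, then profiles fold enrichment
around the planted sites:

```
planted r   : 0.7
estimated r : 0.701  (threshold tau*=12, 865 bins)
fold enrichment at center bin : 20.20
fold enrichment at edge bin   : 1.27
```

The estimate sits within 0.2 % of truth here; the profile peaks at the
planted anchors and decays to ~1 (pure background) in the flanks.
`examples/04_expression_groups.py` shows the six-group occupancy ×
direction partition and a Welch comparison between groups.

## Command line

The same stages are scriptable:

```
cooccupy simulate --config run.yaml --out out/
cooccupy classify --peaks-a out/peaks_A.bed --peaks-b out/peaks_B.bed --out out/
cooccupy diffbind --wt-a out/peaks_A.bed --wt-b out/peaks_B.bed \
                  --ko-b out/peaks_B_ko.bed --out out/
cooccupy metagene --gtf out/genes.gtf --chrom-sizes out/chrom.sizes \
                  --chip-reads out/chip_reads.bed \
                  --control-reads out/control_reads.bed --out out/
cooccupy report --out out/
```

Every artifact is a pure function of config + seed; `report` collates
the stage summaries with config hashes and input checksums.

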
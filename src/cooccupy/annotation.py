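"""Promoter/enhancer anchor regions and genomic feature assignment.

Promoter windows follow the definition used for filtering regulatory
sites: less than 2 kb upstream and less than 500 bp downstream of the
TSS, oriented by gene strand. Enhancer regions are centered on the
midpoint of each enhancer-atlas record (its "Ctr"). Peaks are assigned
to exclusive feature categories with the priority
promoter > 5'UTR > 3'UTR > exon > intron > distal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

from .intervals import (
    GenomicInterval,
    IntervalSet,
    ValidationError,
    merge,
    overlaps,
)


class FeatureCategory(str, Enum):
    PROMOTER = "promoter"
    UTR5 = "utr5"
    UTR3 = "utr3"
    EXON = "exon"
    INTRON = "intron"
    DISTAL = "distal"


#: Higher priority wins when a site overlaps several feature kinds.
FEATURE_PRIORITY: Tuple[FeatureCategory, ...] = (
    FeatureCategory.PROMOTER,
    FeatureCategory.UTR5,
    FeatureCategory.UTR3,
    FeatureCategory.EXON,
    FeatureCategory.INTRON,
)


@dataclass
class GeneModel:
    """One gene: a single TSS, a strand and merged exon structure."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: List[GenomicInterval] = field(default_factory=list)
    utr5: List[GenomicInterval] = field(default_factory=list)
    utr3: List[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        self.exons = sorted(self.exons, key=GenomicInterval.sort_key)

    @property
    def span(self) -> Optional[GenomicInterval]:
        """Gene span = [min exon start, max exon end), or None without exons."""
        if not self.exons:
            return None
        return GenomicInterval(self.chrom, self.exons[0].start,
                               max(e.end for e in self.exons),
                               self.gene_id, None, self.strand)

    def introns(self) -> List[GenomicInterval]:
        """Gene span minus merged exons."""
        if len(self.exons) < 2:
            return []
        merged_ex = merge(IntervalSet(self.exons)).intervals
        out = []
        for a, b in zip(merged_ex, merged_ex[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start,
                                           self.gene_id, None, self.strand))
        return out


@dataclass
class AnchoredRegion:
    """A window with a reference anchor (TSS or enhancer center)."""

    interval: GenomicInterval
    anchor: int
    anchor_kind: str  # "tss" | "enhancer_center"
    strand: str = "."
    linked_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.anchor < self.interval.end):
            raise ValidationError(
                f"anchor {self.anchor} outside [{self.interval.start}, {self.interval.end})"
            )


def promoter_windows(
    genes: Sequence[GeneModel],
    upstream: int = 2000,
    downstream: int = 500,
    genome: Optional[Dict[str, int]] = None,
) -> List[AnchoredRegion]:
    """One promoter window per gene, oriented by strand, anchored at the TSS.

    On the + strand the window is ``[tss - upstream, tss + downstream)``;
    on the - strand it is the mirror image ``[tss - downstream + 1,
    tss + upstream + 1)``, so both cover ``upstream`` bp 5' and
    ``downstream`` bp 3' of the start base in transcription orientation.
    Windows are clipped at chromosome bounds when a genome is supplied.
    """
    if upstream < 0 or downstream < 0:
        raise ValidationError("upstream/downstream must be >= 0")
    out: List[AnchoredRegion] = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - upstream, g.tss + downstream
        else:
            start, end = g.tss - downstream + 1, g.tss + upstream + 1
        start = max(0, start)
        if genome is not None and g.chrom in genome:
            end = min(end, genome[g.chrom])
        iv = GenomicInterval(g.chrom, start, end, g.gene_id, None, g.strand)
        out.append(AnchoredRegion(iv, g.tss, "tss", g.strand, g.gene_id))
    return out


def enhancer_regions(enhancers: IntervalSet, half_width: int = 1000) -> List[AnchoredRegion]:
    """Fixed-width unstranded windows centered on each enhancer midpoint."""
    if len(enhancers) == 0:
        raise ValidationError("enhancer set is empty")
    out = []
    for e in enhancers:
        anchor = e.midpoint
        iv = GenomicInterval(e.chrom, max(0, anchor - half_width), anchor + half_width,
                             e.name, None, ".")
        out.append(AnchoredRegion(iv, anchor, "enhancer_center", ".", None))
    return out


def _feature_intervals(
    genes: Sequence[GeneModel],
    promoters: Sequence[AnchoredRegion],
) -> Dict[FeatureCategory, List[GenomicInterval]]:
    feats: Dict[FeatureCategory, List[GenomicInterval]] = {
        FeatureCategory.PROMOTER: [p.interval for p in promoters],
        FeatureCategory.UTR5: [],
        FeatureCategory.UTR3: [],
        FeatureCategory.EXON: [],
        FeatureCategory.INTRON: [],
    }
    for g in genes:
        feats[FeatureCategory.UTR5].extend(g.utr5)
        feats[FeatureCategory.UTR3].extend(g.utr3)
        feats[FeatureCategory.EXON].extend(g.exons)
        feats[FeatureCategory.INTRON].extend(g.introns())
    return feats


def assign_feature(
    site: GenomicInterval,
    genes: Sequence[GeneModel],
    promoters: Sequence[AnchoredRegion],
    _index: Optional[Dict[FeatureCategory, IntervalSet]] = None,
) -> FeatureCategory:
    """Exclusive feature category of the highest-priority overlapping feature."""
    if _index is None:
        _index = {
            cat: IntervalSet(ivs)
            for cat, ivs in _feature_intervals(genes, promoters).items()
        }
    for cat in FEATURE_PRIORITY:
        if _index[cat].overlapping(site):
            return cat
    return FeatureCategory.DISTAL


def feature_distribution(
    sites: IntervalSet,
    genes: Sequence[GeneModel],
    promoters: Sequence[AnchoredRegion],
) -> Dict[FeatureCategory, float]:
    """Percent of sites in each exclusive feature category (sums to 100)."""
    if len(sites) == 0:
        raise ValidationError("feature_distribution requires a non-empty site set")
    index = {cat: IntervalSet(ivs)
             for cat, ivs in _feature_intervals(genes, promoters).items()}
    counts = {cat: 0 for cat in FeatureCategory}
    for site in sites:
        counts[assign_feature(site, genes, promoters, _index=index)] += 1
    n = len(sites)
    return {cat: 100.0 * c / n for cat, c in counts.items()}


def nearest_promoter_gene(
    site: GenomicInterval,
    promoters: Sequence[AnchoredRegion],
    min_overlap: int = 1,
) -> Optional[str]:
    """Gene whose promoter overlaps the site, nearest TSS to the site midpoint.

    Ties break to the lexicographically smaller gene_id; None when no
    promoter overlaps.
    """
    mid = site.midpoint
    hits = [
        p for p in promoters
        if overlaps(site, p.interval, min_overlap)
    ]
    if not hits:
        return None
    return min(hits, key=lambda p: (abs(p.anchor - mid), p.linked_gene or ""))\
        .linked_gene


def nearest_tss_gene(anchor_chrom: str, anchor: int, genes: Sequence[GeneModel]) -> Optional[str]:
    """Gene with the TSS nearest to a position (enhancer-to-gene linking)."""
    same = [g for g in genes if g.chrom == anchor_chrom]
    if not same:
        return None
    return min(same, key=lambda g: (abs(g.tss - anchor), g.gene_id)).gene_id


# -- GTF input ----------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')

_FEATURE_MAP = {
    "exon": "exons",
    "five_prime_utr": "utr5",
    "three_prime_utr": "utr3",
}


def read_gtf(path) -> List[GeneModel]:
    """Read gene models from GTF 2.2 (features gene/exon/five_prime_utr/three_prime_utr).

    GTF 1-based inclusive coordinates are converted to 0-based half-open
    on read. The TSS is taken from the gene record (start base on +,
    end base on -); one TSS per gene.
    """
    genes: Dict[str, GeneModel] = {}
    pending: Dict[str, Dict[str, List[GenomicInterval]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValidationError(f"{path}:{lineno}: expected 9 GTF fields")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = fields[:9]
            start, end = int(start1) - 1, int(end1)
            attrs_map = dict(_GTF_ATTR.findall(attrs))
            gene_id = attrs_map.get("gene_id")
            if gene_id is None:
                raise ValidationError(f"{path}:{lineno}: missing gene_id attribute")
            if feature == "gene":
                tss = start if strand == "+" else end - 1
                genes[gene_id] = GeneModel(gene_id, chrom, strand, tss)
            elif feature in _FEATURE_MAP:
                iv = GenomicInterval(chrom, start, end, gene_id, None, strand)
                pending.setdefault(gene_id, {}).setdefault(_FEATURE_MAP[feature], []).append(iv)
    for gene_id, featmap in pending.items():
        g = genes.get(gene_id)
        if g is None:
            continue
        for attr, ivs in featmap.items():
            getattr(g, attr).extend(sorted(ivs, key=GenomicInterval.sort_key))
    return [genes[k] for k in sorted(genes)]


def write_gtf(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GTF 2.2 (gene + exon + UTR records)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id)):
            span = g.span
            if span is None:
                span = GenomicInterval(g.chrom, g.tss, g.tss + 1, g.gene_id, None, g.strand)
            else:
                # gene record must encode the TSS at its strand-appropriate end
                span = GenomicInterval(g.chrom, min(span.start, g.tss),
                                       max(span.end, g.tss + 1),
                                       g.gene_id, None, g.strand)
            rows = [("gene", span)]
            rows += [("exon", e) for e in g.exons]
            rows += [("five_prime_utr", u) for u in g.utr5]
            rows += [("three_prime_utr", u) for u in g.utr3]
            for feature, iv in rows:
                fh.write(
                    f"{g.chrom}\tcooccupy\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t"
                    f'{g.strand}\t.\tgene_id "{g.gene_id}";\n'
                )
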
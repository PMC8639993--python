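"""Synthetic genomes, peak sets, reads and expression with planted truth.

Every generator is a pure function of a :class:`SyntheticConfig`: the
same seed reproduces byte-identical outputs. Independent generators
draw from independent pseudo-random streams derived from the master
seed by fixed labels, so changing how many numbers one generator draws
cannot shift another's output.

The default configuration plants the study conditions the analysis is
exercised under: two factors with 2060 / 3108 A-only / B-only peaks and
1128 one-to-one shared sites (totals 3188 and 4236), a knockout set
losing the factor at 841 designated shared sites, retaining 287 and
gaining 9 novel sites; Poisson read coverage with a known ChIP:input
background scaling factor; and expression tables with planted per-group
fold-change directions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import GeneModel
from .intervals import GenomicInterval, IntervalSet

# fixed stream labels: generator name -> sub-seed component
_STREAMS = {
    "genes": 11,
    "peaks": 13,
    "ko": 17,
    "reads": 19,
    "expression": 23,
}


class GenerationError(ValueError):
    pass


@dataclass
class PeakConfig:
    a_only: int = 2060
    b_only: int = 3108
    shared: int = 1128
    width_min: int = 200
    width_max: int = 600
    gap: int = 2000  # minimum bp between distinct planted sites


@dataclass
class KoConfig:
    lost: int = 841
    gained: int = 9


@dataclass
class CoverageConfig:
    lam: float = 5.0          # background control reads per bin (~15M-read
                              # input library over a mammalian genome at 1 kb)
    r_true: float = 0.7       # chip background / control background
    bin_width: int = 1000
    enrich_amplitude: float = 50.0  # mean extra chip reads per enriched site
    enrich_halfwidth: int = 300     # triangular placement half-width (bp)
    fragment_length: int = 200


@dataclass
class ExpressionConfig:
    base_mean: float = 200.0  # baseline normalized counts (lognormal median)
    base_sigma: float = 1.0   # lognormal sigma of baselines
    noise_sd: float = 0.25    # per-gene sd around the planted log2fc
    group_lfc: Dict[str, float] = field(default_factory=dict)


@dataclass
class GeneConfig:
    n_genes: int = 60
    spacing: int = 20000      # distance between consecutive TSSs
    span_min: int = 2000
    span_max: int = 8000
    strand_mode: str = "alternate"  # alternate | random | plus


@dataclass
class SyntheticConfig:
    seed: int = 0
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"synth1": 12_000_000, "synth2": 12_000_000})
    genes: GeneConfig = field(default_factory=GeneConfig)
    peaks: PeakConfig = field(default_factory=PeakConfig)
    ko: KoConfig = field(default_factory=KoConfig)
    coverage: CoverageConfig = field(default_factory=CoverageConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2 ** 31), _STREAMS[stream]])


@dataclass
class TruthManifest:
    """Machine-readable ground truth for every planted object."""

    site_class: Dict[str, str] = field(default_factory=dict)       # site id -> a_only|b_only|shared
    differential: Dict[str, str] = field(default_factory=dict)     # shared site id -> lost|retained
    gained_sites: List[str] = field(default_factory=list)
    r_true: Optional[float] = None
    gene_direction: Dict[str, str] = field(default_factory=dict)   # gene id -> up|down|unchanged
    gene_group: Dict[str, str] = field(default_factory=dict)       # gene id -> occupancy class

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def make_genome(cfg: SyntheticConfig) -> Dict[str, int]:
    """Chromosome-size map; deterministic (lengths come from the config)."""
    for chrom, length in cfg.chrom_lengths.items():
        if length <= 0:
            raise GenerationError(f"chrom {chrom!r} length must be > 0")
    return dict(cfg.chrom_lengths)


def make_gene_models(cfg: SyntheticConfig, genome: Dict[str, int]) -> List[GeneModel]:
    """Non-overlapping gene models with stranded TSSs and exon structure."""
    gcfg = cfg.genes
    rng = cfg.rng("genes")
    chroms = sorted(genome)
    genes: List[GeneModel] = []
    chrom_i, pos = 0, gcfg.spacing
    for k in range(gcfg.n_genes):
        span_len = int(rng.integers(gcfg.span_min, gcfg.span_max + 1))
        while chrom_i < len(chroms) and pos + span_len + gcfg.spacing > genome[chroms[chrom_i]]:
            chrom_i += 1
            pos = gcfg.spacing
        if chrom_i >= len(chroms):
            raise GenerationError(
                f"genome too small for {gcfg.n_genes} genes at spacing {gcfg.spacing}")
        chrom = chroms[chrom_i]
        if gcfg.strand_mode == "alternate":
            strand = "+" if k % 2 == 0 else "-"
        elif gcfg.strand_mode == "plus":
            strand = "+"
        else:
            strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene{k:04d}"
        start, end = pos, pos + span_len
        n_exons = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(np.arange(start + 200, end - 200, 100),
                                  size=2 * (n_exons - 1), replace=False))
        bounds = [start] + [int(c) for c in cuts] + [end]
        exons = [GenomicInterval(chrom, bounds[2 * i], bounds[2 * i + 1],
                                 gene_id, None, strand)
                 for i in range(n_exons)]
        tss = start if strand == "+" else end - 1
        # 100 bp terminal UTRs, oriented by strand
        utr_head = GenomicInterval(chrom, start, min(start + 100, exons[0].end),
                                   gene_id, None, strand)
        utr_tail = GenomicInterval(chrom, max(end - 100, exons[-1].start), end,
                                   gene_id, None, strand)
        utr5, utr3 = (utr_head, utr_tail) if strand == "+" else (utr_tail, utr_head)
        genes.append(GeneModel(gene_id, chrom, strand, tss, exons,
                               [utr5], [utr3]))
        pos = end + gcfg.spacing
    return genes


def plant_peaks(
    cfg: SyntheticConfig, genome: Dict[str, int],
) -> Tuple[IntervalSet, IntervalSet, TruthManifest, Dict[str, int]]:
    """Plant A-only, B-only and one-to-one shared peaks with known labels.

    Returns (set_a, set_b, truth, next_free) where ``next_free`` maps
    chrom -> first unoccupied position (used to place knockout-gained
    peaks clear of every wild-type peak).
    """
    pcfg = cfg.peaks
    rng = cfg.rng("peaks")
    classes = (["a_only"] * pcfg.a_only + ["b_only"] * pcfg.b_only
               + ["shared"] * pcfg.shared)
    rng.shuffle(classes)
    chroms = sorted(genome)
    set_a: List[GenomicInterval] = []
    set_b: List[GenomicInterval] = []
    truth = TruthManifest()
    chrom_i, pos = 0, pcfg.gap
    counters = {"a_only": 0, "b_only": 0, "shared": 0}
    max_extent = pcfg.width_max + pcfg.width_max // 2 + pcfg.width_max
    for cls in classes:
        while chrom_i < len(chroms) and pos + max_extent + pcfg.gap > genome[chroms[chrom_i]]:
            chrom_i += 1
            pos = pcfg.gap
        if chrom_i >= len(chroms):
            raise GenerationError("genome too small for requested peak counts and gap")
        chrom = chroms[chrom_i]
        site_id = f"{cls}_{counters[cls]:05d}"
        counters[cls] += 1
        wa = int(rng.integers(pcfg.width_min, pcfg.width_max + 1))
        if cls == "a_only":
            set_a.append(GenomicInterval(chrom, pos, pos + wa, site_id))
            extent_end = pos + wa
        elif cls == "b_only":
            set_b.append(GenomicInterval(chrom, pos, pos + wa, site_id))
            extent_end = pos + wa
        else:  # shared: B shifted by half the A width -> overlap >= ceil(wa/2) bp
            wb = int(rng.integers(pcfg.width_min, pcfg.width_max + 1))
            shift = wa // 2
            set_a.append(GenomicInterval(chrom, pos, pos + wa, site_id))
            set_b.append(GenomicInterval(chrom, pos + shift, pos + shift + wb, site_id))
            extent_end = max(pos + wa, pos + shift + wb)
        truth.site_class[site_id] = cls
        pos = extent_end + pcfg.gap
    next_free = {c: pcfg.gap for c in chroms}
    for c in chroms[:chrom_i + 1]:
        next_free[c] = pos if c == chroms[chrom_i] else genome[c]
    return (IntervalSet(set_a, genome=genome, merged=True),
            IntervalSet(set_b, genome=genome, merged=True),
            truth, next_free)


def plant_ko(
    cfg: SyntheticConfig,
    set_b: IntervalSet,
    truth: TruthManifest,
    next_free: Dict[str, int],
    genome: Dict[str, int],
) -> Tuple[IntervalSet, TruthManifest]:
    """Knockout peak set: B minus peaks at designated lost shared sites,
    plus novel gained peaks placed >= gap from every wild-type peak."""
    kcfg, pcfg = cfg.ko, cfg.peaks
    rng = cfg.rng("ko")
    shared_ids = sorted(i for i, c in truth.site_class.items() if c == "shared")
    if kcfg.lost > len(shared_ids):
        raise GenerationError("requested lost count exceeds planted shared sites")
    lost_ids = set(rng.choice(shared_ids, size=kcfg.lost, replace=False).tolist())
    for sid in shared_ids:
        truth.differential[sid] = "lost" if sid in lost_ids else "retained"
    ko: List[GenomicInterval] = [iv for iv in set_b if iv.name not in lost_ids]
    chroms = sorted(genome)
    chrom_i = 0
    for g in range(kcfg.gained):
        w = int(rng.integers(pcfg.width_min, pcfg.width_max + 1))
        while chrom_i < len(chroms) and \
                next_free[chroms[chrom_i]] + w + pcfg.gap > genome[chroms[chrom_i]]:
            chrom_i += 1
        if chrom_i >= len(chroms):
            raise GenerationError("no free space for gained peaks")
        chrom = chroms[chrom_i]
        pos = next_free[chrom]
        site_id = f"gained_{g:03d}"
        ko.append(GenomicInterval(chrom, pos, pos + w, site_id))
        truth.gained_sites.append(site_id)
        next_free[chrom] = pos + w + pcfg.gap
    return IntervalSet(ko, genome=genome, merged=True), truth


def simulate_reads(
    cfg: SyntheticConfig,
    genome: Dict[str, int],
    enriched_sites: IntervalSet,
) -> Tuple[IntervalSet, IntervalSet, float]:
    """Simulate ChIP and control reads with a known background ratio.

    Control read 5' starts are Poisson(lam) per bin, uniform within the
    bin; the ChIP background is Poisson(r_true * lam); each enriched
    site additionally receives Poisson(enrich_amplitude) reads placed
    with a triangular density centered on the site midpoint. All reads
    have the configured fragment length on the + strand.
    """
    ccfg = cfg.coverage
    if ccfg.lam <= 0 or ccfg.r_true <= 0:
        raise GenerationError("lam and r_true must be > 0")
    rng = cfg.rng("reads")
    fl = ccfg.fragment_length
    chip: List[GenomicInterval] = []
    control: List[GenomicInterval] = []

    def background(rate: float, out: List[GenomicInterval], tag: str) -> None:
        for chrom in sorted(genome):
            clen = genome[chrom]
            n_bins = (clen + ccfg.bin_width - 1) // ccfg.bin_width
            counts = rng.poisson(rate, size=n_bins)
            for b in np.flatnonzero(counts):
                lo = b * ccfg.bin_width
                hi = min(clen, lo + ccfg.bin_width)
                for s in rng.integers(lo, hi, size=counts[b]):
                    start = int(min(s, clen - fl))
                    out.append(GenomicInterval(chrom, start, start + fl,
                                               f"{tag}"))

    background(ccfg.lam, control, "ctl")
    background(ccfg.r_true * ccfg.lam, chip, "bg")
    for site in enriched_sites:
        clen = genome[site.chrom]
        n_extra = rng.poisson(ccfg.enrich_amplitude)
        if n_extra == 0:
            continue
        centers = rng.triangular(-ccfg.enrich_halfwidth, 0, ccfg.enrich_halfwidth,
                                 size=n_extra) + site.midpoint
        for c in centers:
            start = int(np.clip(round(c - fl / 2), 0, clen - fl))
            chip.append(GenomicInterval(site.chrom, start, start + fl, "enr"))
    return (IntervalSet(chip, genome=genome), IntervalSet(control, genome=genome),
            ccfg.r_true)


def plant_expression(
    cfg: SyntheticConfig,
    gene_groups: Dict[str, Sequence[str]],
    conditions: Tuple[str, str] = ("ko", "wt"),
) -> Tuple[Dict[str, Dict[str, float]], TruthManifest]:
    """Per-gene expression values realizing per-group planted fold changes.

    Baselines are lognormal; the first condition's value is the baseline
    scaled by 2^(group lfc + N(0, noise_sd)). Truth records each gene's
    group and intended direction (sign of the group mean lfc).
    """
    ecfg = cfg.expression
    rng = cfg.rng("expression")
    seen: set = set()
    for genes in gene_groups.values():
        for g in genes:
            if g in seen:
                raise GenerationError(f"gene {g!r} appears in more than one group")
            seen.add(g)
    table: Dict[str, Dict[str, float]] = {}
    truth = TruthManifest()
    cond_a, cond_b = conditions
    for group in sorted(gene_groups):
        lfc = ecfg.group_lfc.get(group, 0.0)
        direction = "up" if lfc > 0 else ("down" if lfc < 0 else "unchanged")
        for gene_id in sorted(gene_groups[group]):
            base = float(ecfg.base_mean * rng.lognormal(0.0, ecfg.base_sigma))
            eff = lfc + rng.normal(0.0, ecfg.noise_sd)
            table[gene_id] = {cond_b: base, cond_a: base * 2.0 ** eff}
            truth.gene_group[gene_id] = group
            truth.gene_direction[gene_id] = direction
    return table, truth
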
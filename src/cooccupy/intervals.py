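"""Genomic interval model, BED I/O and overlap algebra.

Coordinates are 0-based half-open throughout (BED convention). Every other
module builds on :class:`GenomicInterval` and :class:`IntervalSet`; peak
sets, promoter windows, enhancer regions and simulated reads are all
interval sets, so overlap semantics are defined in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised for malformed BED input; message names the offending line."""


class ValidationError(ValueError):
    """Raised when an interval or interval set violates its invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded 0-based half-open interval ``[start, end)`` on ``chrom``.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded). ``score`` is
    an optional real carried through BED round-trips.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two intervals; 0 when on different chroms."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_overlap: int = 1) -> bool:
    """True iff ``a`` and ``b`` share at least ``min_overlap`` bp.

    Strand is ignored: a peak on either strand occupies the site.
    """
    if min_overlap < 1:
        raise ValidationError("min_overlap must be >= 1")
    return overlap_length(a, b) >= min_overlap


class IntervalSet:
    """An ordered collection of intervals, sorted by (chrom, start, end).

    ``merged`` records that same-chrom overlaps have been unioned; several
    operations (occupancy classification in particular) require merged
    inputs so that a "site" is an unambiguous unit.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: Optional[Dict[str, int]] = None,
        merged: bool = False,
    ) -> None:
        self.intervals: List[GenomicInterval] = sorted(intervals, key=GenomicInterval.sort_key)
        self.genome = dict(genome) if genome is not None else None
        self.merged = merged
        if self.genome is not None:
            for iv in self.intervals:
                if iv.chrom not in self.genome:
                    raise ValidationError(f"chrom {iv.chrom!r} not in genome")
                if iv.end > self.genome[iv.chrom]:
                    raise ValidationError(
                        f"interval [{iv.start}, {iv.end}) exceeds {iv.chrom} "
                        f"length {self.genome[iv.chrom]}"
                    )
        if merged:
            for prev, cur in zip(self.intervals, self.intervals[1:]):
                if cur.chrom == prev.chrom and cur.start < prev.end:
                    raise ValidationError("merged set contains overlapping intervals")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, merged={self.merged})"

    def chroms(self) -> List[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def by_chrom(self) -> Dict[str, List[GenomicInterval]]:
        out: Dict[str, List[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    # -- overlap queries ------------------------------------------------

    def build_trees(self) -> Dict[str, IntervalTree]:
        trees: Dict[str, IntervalTree] = {}
        for chrom, ivs in self.by_chrom().items():
            trees[chrom] = IntervalTree.from_tuples((iv.start, iv.end, iv) for iv in ivs)
        return trees

    def overlapping(
        self, query: GenomicInterval, min_overlap: int = 1,
        _trees: Optional[Dict[str, IntervalTree]] = None,
    ) -> List[GenomicInterval]:
        """All intervals in the set overlapping ``query`` by >= min_overlap bp."""
        if min_overlap < 1:
            raise ValidationError("min_overlap must be >= 1")
        trees = _trees if _trees is not None else self.build_trees()
        tree = trees.get(query.chrom)
        if tree is None:
            return []
        hits = [
            node.data
            for node in tree.overlap(query.start, query.end)
            if min(query.end, node.end) - max(query.start, node.begin) >= min_overlap
        ]
        return sorted(hits, key=GenomicInterval.sort_key)

    def overlap_flags(self, other: "IntervalSet", min_overlap: int = 1) -> List[bool]:
        """Per-interval flag: does interval i overlap anything in ``other``?"""
        trees = other.build_trees()
        return [
            bool(self_iv is not None and other.overlapping(self_iv, min_overlap, _trees=trees))
            for self_iv in self.intervals
        ]


def merge(s: IntervalSet, gap: int = 0) -> IntervalSet:
    """Union overlapping (or within ``gap`` bp) same-chrom intervals.

    Interval names are joined with ``,`` when peaks fuse; scores are
    dropped (a merged site has no single peak score). Total covered bp is
    unchanged for ``gap=0``.
    """
    if gap < 0:
        raise ValidationError("gap must be >= 0")
    out: List[GenomicInterval] = []
    for chrom, ivs in s.by_chrom().items():
        cur_start, cur_end = ivs[0].start, ivs[0].end
        cur_names = [ivs[0].name]
        cur_strand = ivs[0].strand
        for iv in ivs[1:]:
            if iv.start <= cur_end + gap:
                cur_end = max(cur_end, iv.end)
                cur_names.append(iv.name)
                if iv.strand != cur_strand:
                    cur_strand = "."
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end,
                                           ",".join(cur_names), None, cur_strand))
                cur_start, cur_end = iv.start, iv.end
                cur_names = [iv.name]
                cur_strand = iv.strand
        out.append(GenomicInterval(chrom, cur_start, cur_end,
                                   ",".join(cur_names), None, cur_strand))
    return IntervalSet(out, genome=s.genome, merged=True)


# -- BED I/O ------------------------------------------------------------


def read_bed(path, genome: Optional[Dict[str, int]] = None) -> IntervalSet:
    """Read BED3/BED6 into a sorted, unmerged :class:`IntervalSet`.

    Strand is taken from column 6 when present, else unstranded. Raises
    :class:`BedParseError` naming the line number on malformed input and
    :class:`ValidationError` when a coordinate violates the invariants or
    exceeds the supplied genome.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else "."
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in STRANDS:
                raise BedParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if start < 0 or start >= end:
                raise ValidationError(f"{path}:{lineno}: require 0 <= start < end")
            intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
    return IntervalSet(intervals, genome=genome)


def write_bed(s: IntervalSet, path) -> None:
    """Write tab-separated BED6; ``read_bed(write_bed(s)) == s``."""
    with open(path, "w") as fh:
        for iv in s.intervals:
            score = "0" if iv.score is None else format(iv.score, "g")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


def read_chrom_sizes(path) -> Dict[str, int]:
    """Read a two-column chrom-sizes TSV into a name -> length map."""
    genome: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            genome[parts[0]] = int(parts[1])
    return genome


def write_chrom_sizes(genome: Dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f"{chrom}\t{genome[chrom]}\n")


def shared_chrom_warning(a: IntervalSet, b: IntervalSet) -> Optional[str]:
    """Chrom names present in only one of two inputs, or None.

    Chromosome comparison is exact string equality; a name mismatch (e.g.
    "chr1" vs "1") silently yields zero overlaps, so it is surfaced here.
    """
    only_a = set(a.chroms()) - set(b.chroms())
    only_b = set(b.chroms()) - set(a.chroms())
    if not only_a and not only_b:
        return None
    return (f"chroms only in first input: {sorted(only_a)}; "
            f"only in second: {sorted(only_b)}")
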
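"""Combinatorial co-occupancy classification and differential occupancy.

Two-set classification reproduces a Venn diagram over merged peak sets:
a peak of factor A is "shared" when it overlaps at least one peak of
factor B. The counts are reported from both sides; with one-to-one
overlaps the two shared counts coincide and a single number can be
printed, otherwise an asymmetry warning is attached.

Differential occupancy compares a factor's wild-type and knockout peak
sets at the wild-type co-occupied sites: a site retains the factor iff a
knockout peak still overlaps it, else it is lost; knockout peaks that
overlap no wild-type peak at all are gained. Loss of enrichment is thus
operationalized as peak-overlap loss, not quantitative re-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

from .intervals import GenomicInterval, IntervalSet, ValidationError, merge


@dataclass
class OccupancyTable:
    """Per-site combinatorial factor labels over a merged site universe."""

    sites: IntervalSet
    labels: List[FrozenSet[str]]
    factor_names: List[str]
    counts: Dict[str, int] = field(default_factory=dict)
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sites):
            raise ValidationError("one label per site required")
        for lab in self.labels:
            if not lab or not lab <= set(self.factor_names):
                raise ValidationError(f"label {set(lab)} not a non-empty subset of factors")

    def combination_counts(self) -> Dict[FrozenSet[str], int]:
        out: Dict[FrozenSet[str], int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out

    def sites_with_label(self, label: FrozenSet[str]) -> IntervalSet:
        ivs = [iv for iv, lab in zip(self.sites, self.labels) if lab == label]
        return IntervalSet(ivs, genome=self.sites.genome, merged=self.sites.merged)


@dataclass(frozen=True)
class DifferentialCall:
    site: GenomicInterval
    call: str  # "lost" | "retained" | "gained"


def _require_merged(s: IntervalSet, what: str) -> None:
    if not s.merged:
        raise ValidationError(f"{what} must be merged within itself (call merge() first)")


def classify_two(
    set_a: IntervalSet,
    set_b: IntervalSet,
    min_overlap: int = 1,
    name_a: str = "A",
    name_b: str = "B",
) -> OccupancyTable:
    """Two-factor Venn classification of merged peak sets.

    ``counts`` holds A_only, B_only, shared_A (A peaks overlapping >=1 B
    peak), shared_B, and ``shared`` = shared_A. A warning is attached
    whenever shared_A != shared_B (many-to-one overlaps), since a single
    Venn number is then ambiguous.
    """
    _require_merged(set_a, "first peak set")
    _require_merged(set_b, "second peak set")
    flags_a = set_a.overlap_flags(set_b, min_overlap)
    flags_b = set_b.overlap_flags(set_a, min_overlap)
    shared_a = sum(flags_a)
    shared_b = sum(flags_b)
    counts = {
        f"{name_a}_only": len(set_a) - shared_a,
        f"{name_b}_only": len(set_b) - shared_b,
        f"shared_{name_a}": shared_a,
        f"shared_{name_b}": shared_b,
        "shared": shared_a,
    }
    warning = None
    if shared_a != shared_b:
        warning = (f"asymmetric overlap: {shared_a} {name_a} peaks overlap "
                   f"{name_b} but {shared_b} {name_b} peaks overlap {name_a}")
    sites: List[GenomicInterval] = []
    labels: List[FrozenSet[str]] = []
    for iv, hit in zip(set_a, flags_a):
        sites.append(iv)
        labels.append(frozenset({name_a, name_b}) if hit else frozenset({name_a}))
    for iv, hit in zip(set_b, flags_b):
        if not hit:  # shared sites are represented once, from A's side
            sites.append(iv)
            labels.append(frozenset({name_b}))
    order = sorted(range(len(sites)), key=lambda i: sites[i].sort_key())
    # each universe site is a maximal merged unit of its own factor set;
    # with min_overlap > 1 a B-only peak may still touch an A site by a
    # sub-threshold overlap, so the flag is set without re-validation
    universe = IntervalSet([sites[i] for i in order])
    universe.merged = True
    table = OccupancyTable(
        sites=universe,
        labels=[labels[i] for i in order],
        factor_names=[name_a, name_b],
        counts=counts,
        warning=warning,
    )
    return table


def classify_multi(
    sets: Dict[str, IntervalSet],
    min_overlap: int = 1,
) -> OccupancyTable:
    """Label each site of the merged union with the factors that occupy it.

    The site universe is the merged union of all input peak sets; every
    universe site is labeled with the subset of factors having >=1 peak
    overlapping it by >= min_overlap bp.
    """
    names = list(sets)
    if not names:
        raise ValidationError("classify_multi needs at least one named set")
    if len(set(names)) != len(names):
        raise ValidationError("duplicate factor names")
    for name, s in sets.items():
        _require_merged(s, f"peak set {name!r}")
    union = merge(IntervalSet([iv for s in sets.values() for iv in s]))
    trees = {name: s.build_trees() for name, s in sets.items()}
    labels: List[FrozenSet[str]] = []
    for site in union:
        present = frozenset(
            name for name, s in sets.items()
            if s.overlapping(site, min_overlap, _trees=trees[name])
        )
        labels.append(present)
    counts: Dict[str, int] = {}
    for lab in labels:
        key = "+".join(sorted(lab))
        counts[key] = counts.get(key, 0) + 1
    return OccupancyTable(sites=union, labels=labels, factor_names=names, counts=counts)


def differential(
    wt_shared: IntervalSet,
    wt_factor: IntervalSet,
    ko_factor: IntervalSet,
    min_overlap: int = 1,
) -> Tuple[List[DifferentialCall], Dict[str, int]]:
    """Lost / retained / gained calls for a factor upon knockout.

    lost + retained partition ``wt_shared``; gained sites are knockout
    peaks overlapping no wild-type peak of the factor.
    """
    for s, what in ((wt_shared, "wt_shared"), (wt_factor, "wt_factor"),
                    (ko_factor, "ko_factor")):
        _require_merged(s, what)
    calls: List[DifferentialCall] = []
    retained_flags = wt_shared.overlap_flags(ko_factor, min_overlap)
    for iv, kept in zip(wt_shared, retained_flags):
        calls.append(DifferentialCall(iv, "retained" if kept else "lost"))
    gained_flags = ko_factor.overlap_flags(wt_factor, min_overlap)
    for iv, in_wt in zip(ko_factor, gained_flags):
        if not in_wt:
            calls.append(DifferentialCall(iv, "gained"))
    counts = {
        "lost": sum(1 for c in calls if c.call == "lost"),
        "retained": sum(1 for c in calls if c.call == "retained"),
        "gained": sum(1 for c in calls if c.call == "gained"),
    }
    return calls, counts
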
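"""Per-base coverage tracks, RPM scaling and NCIS background normalization.

The NCIS estimator recovers the scaling factor ``r`` by which a ChIP
library's *background* exceeds (or trails) its input control. The genome
is tiled into fixed-width bins; bins are added in order of increasing
total count (ChIP + control), and the ratio of cumulative ChIP to
cumulative control counts is tracked. In background-only bins the ratio
is flat at ``r``; as enriched bins enter, it starts rising. The estimate
is the ratio at the first threshold where most bins are already included
and the ratio stops decreasing — i.e. just before signal bins begin to
inflate it.

Normalized tracks come in two modes: background subtraction
``max(chip - r * control, 0)`` followed by RPM scaling, and fold
enrichment ``(chip + p) / (r * control + p)`` with pseudocount ``p``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .intervals import IntervalSet, ValidationError


class EstimationError(ValueError):
    pass


@dataclass
class CoverageTrack:
    """Per-chrom coverage vectors with library size and unit bookkeeping.

    ``read_starts`` (per-chrom sorted 5' start positions) is populated
    when the track is built from reads; the NCIS binning requires it.
    """

    data: Dict[str, np.ndarray]
    library_size: int
    units: str = "raw"  # raw | rpm | normalized
    read_starts: Optional[Dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        for chrom, vec in self.data.items():
            if np.any(vec < 0):
                raise ValidationError(f"negative coverage on {chrom}")

    @property
    def genome(self) -> Dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self.data[chrom][start:end]

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))


@dataclass
class BinnedCounts:
    """Per-bin ChIP and control read-start counts at a fixed bin width."""

    w: int
    chip: np.ndarray
    control: np.ndarray

    def __post_init__(self) -> None:
        if self.chip.shape != self.control.shape:
            raise ValidationError("chip and control bin vectors differ in length")

    @property
    def totals(self) -> np.ndarray:
        return self.chip + self.control


@dataclass
class NormalizationFactor:
    """NCIS background scaling factor of ChIP relative to control."""

    r: float
    w: int
    threshold: float  # chosen total-count cutoff tau*
    n_bins_used: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValidationError("r must be > 0")


def coverage_from_reads(
    reads: IntervalSet,
    genome: Dict[str, int],
    extend_to: Optional[int] = None,
) -> CoverageTrack:
    """Pile reads into per-base coverage; library size = number of reads.

    With ``extend_to``, each read is extended to that fragment length in
    its 3' direction (strand-aware) before piling; intervals are clipped
    at chromosome ends. The 5' start positions are retained for binned
    counting.
    """
    data = {c: np.zeros(n, dtype=float) for c, n in genome.items()}
    starts: Dict[str, List[int]] = {c: [] for c in genome}
    for r in reads:
        if r.chrom not in genome:
            raise ValidationError(f"read chrom {r.chrom!r} not in genome")
        start, end = r.start, r.end
        if extend_to is not None:
            if extend_to < len(r):
                raise ValidationError("extend_to must be >= read length")
            if r.strand == "-":
                start = end - extend_to
            else:
                end = start + extend_to
        start = max(0, start)
        end = min(end, genome[r.chrom])
        if start >= end:
            raise ValidationError(f"read at [{r.start}, {r.end}) on {r.chrom} "
                                  "cannot be clipped into the chromosome")
        data[r.chrom][start:end] += 1.0
        # 5' position in sequencing orientation
        starts[r.chrom].append(r.end - 1 if r.strand == "-" else r.start)
    read_starts = {c: np.sort(np.asarray(v, dtype=int)) for c, v in starts.items()}
    return CoverageTrack(data, library_size=len(reads), units="raw",
                         read_starts=read_starts)


def rpm_scale(track: CoverageTrack) -> CoverageTrack:
    """Scale a raw track to reads per million mapped reads."""
    if track.units != "raw":
        raise ValidationError(f"rpm_scale expects raw units, got {track.units}")
    if track.library_size <= 0:
        raise ValidationError("library_size must be > 0")
    factor = 1e6 / track.library_size
    return CoverageTrack({c: v * factor for c, v in track.data.items()},
                         track.library_size, units="rpm",
                         read_starts=track.read_starts)


def bin_counts(chip: CoverageTrack, control: CoverageTrack, w: int = 1000) -> BinnedCounts:
    """Tile the genome into ``w``-bp bins and count read 5' starts per bin.

    The last partial bin on each chromosome is kept. Both tracks must be
    raw, on the same genome, and carry read start positions.
    """
    if chip.units != "raw" or control.units != "raw":
        raise ValidationError("bin_counts expects raw tracks")
    if chip.genome != control.genome:
        raise ValidationError("chip and control genomes differ")
    if chip.read_starts is None or control.read_starts is None:
        raise ValidationError("bin_counts requires tracks built from reads "
                              "(read start positions unavailable)")
    chip_bins: List[np.ndarray] = []
    ctrl_bins: List[np.ndarray] = []
    for chrom in sorted(chip.genome):
        n = chip.genome[chrom]
        n_bins = (n + w - 1) // w
        edges = np.arange(1, n_bins + 1) * w
        chip_bins.append(np.bincount(
            np.searchsorted(edges, chip.read_starts[chrom], side="right"),
            minlength=n_bins)[:n_bins])
        ctrl_bins.append(np.bincount(
            np.searchsorted(edges, control.read_starts[chrom], side="right"),
            minlength=n_bins)[:n_bins])
    return BinnedCounts(w, np.concatenate(chip_bins).astype(float),
                        np.concatenate(ctrl_bins).astype(float))


def _widen_bins(bins: BinnedCounts) -> BinnedCounts:
    """Aggregate adjacent bin pairs, doubling the effective bin width."""
    def pair(v: np.ndarray) -> np.ndarray:
        if len(v) % 2:
            v = np.concatenate((v, [0.0]))
        return v.reshape(-1, 2).sum(axis=1)
    return BinnedCounts(bins.w * 2, pair(bins.chip), pair(bins.control))


def ncis_factor(bins: BinnedCounts, min_fraction: float = 0.8) -> NormalizationFactor:
    """Estimate the ChIP:control background scaling factor from binned counts.

    Bins are first widened (adjacent pairs aggregated, doubling the bin
    width) until the mean total count per bin is at least 1, so that the
    low-count thresholds are informative. Distinct bin totals are then
    scanned in increasing order; at each threshold tau_k the ratio
    r_k = sum(chip) / sum(control) over bins with total <= tau_k is
    computed (thresholds with zero control sum are skipped). The
    returned r is r_k at the smallest k >= 2 where at least
    ``min_fraction`` of all bins are included and r_k >= r_{k-1} — the
    first non-decrease of the cumulative ratio marks the onset of
    enriched bins, and the inclusion floor keeps the decision out of
    the noisy low-count head of the scan (enriched bins occupy the top
    of the total-count ordering, so the lower half is background).
    When no threshold qualifies, the ratio at the largest threshold is
    returned with ``converged=False`` and a warning.
    """
    if float(bins.control.sum()) <= 0:
        raise EstimationError("all-zero control: cannot estimate background ratio")
    while bins.totals.mean() < 1.0 and len(bins.totals) > 2:
        bins = _widen_bins(bins)
    totals = bins.totals
    n_total = len(totals)
    order = np.argsort(totals, kind="stable")
    t_sorted = totals[order]
    c_cum = np.cumsum(bins.chip[order])
    b_cum = np.cumsum(bins.control[order])
    t_cum = np.cumsum(t_sorted)
    # index of the last bin at each distinct total
    distinct_idx = np.flatnonzero(np.diff(t_sorted, append=np.inf) != 0)
    ratios: List[Tuple[float, float, int]] = []  # (tau, r_k, n_bins)
    for i in distinct_idx:
        if b_cum[i] <= 0:
            continue
        ratios.append((float(t_sorted[i]), float(c_cum[i] / b_cum[i]), int(i + 1)))
    if not ratios:
        raise EstimationError("no threshold with nonzero control counts")
    chosen = None
    for k in range(1, len(ratios)):
        tau, r_k, n = ratios[k]
        if n >= min_fraction * n_total and r_k >= ratios[k - 1][1]:
            chosen = (tau, r_k, n)
            break
    converged = chosen is not None
    if chosen is None:
        chosen = ratios[-1]
        warnings.warn("NCIS stopping rule never satisfied; returning the ratio "
                      "at the largest bin total", RuntimeWarning)
    tau, r, n = chosen
    if r <= 0:
        raise EstimationError("estimated background ratio is zero "
                              "(no chip reads in low-count bins)")
    return NormalizationFactor(r=r, w=bins.w, threshold=tau, n_bins_used=n,
                               converged=converged)


def normalize_track(
    chip: CoverageTrack,
    control: CoverageTrack,
    nf: NormalizationFactor,
    mode: str = "subtract",
    pseudocount: float = 1.0,
) -> CoverageTrack:
    """Input-normalize a ChIP track by its control using an NCIS factor.

    subtract: ``max(chip - r*control, 0)`` then RPM-scaled by the ChIP
    library. fold: ``(chip + p) / (r*control + p)``.
    """
    if chip.units != "raw" or control.units != "raw":
        raise ValidationError("normalize_track expects raw tracks")
    if chip.genome != control.genome:
        raise ValidationError("chip and control genomes differ")
    if mode == "subtract":
        data = {c: np.maximum(chip.data[c] - nf.r * control.data[c], 0.0)
                * (1e6 / chip.library_size)
                for c in chip.data}
    elif mode == "fold":
        if pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0 in fold mode")
        data = {c: (chip.data[c] + pseudocount)
                / (nf.r * control.data[c] + pseudocount)
                for c in chip.data}
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return CoverageTrack(data, chip.library_size, units="normalized")


# -- bedGraph I/O -------------------------------------------------------


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write coverage as 4-column bedGraph (0-based half-open, runs collapsed)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            vec = track.data[chrom]
            if len(vec) == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path, genome: Dict[str, int], library_size: int,
                  units: str = "raw") -> CoverageTrack:
    """Read 4-column bedGraph into a dense per-base track."""
    data = {c: np.zeros(n, dtype=float) for c, n in genome.items()}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 bedGraph fields")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in data:
                raise ValidationError(f"{path}:{lineno}: chrom {chrom!r} not in genome")
            data[chrom][start:end] = value
    return CoverageTrack(data, library_size=library_size, units=units)
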
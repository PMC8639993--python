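"""Anchor-relative binned signal matrices, mean profiles and heatmap ordering.

Reference-point mode only: every region contributes a fixed window
``[anchor - half_width, anchor + half_width)`` split into equal bins,
with bin order reversed for minus-strand anchors so that bin 0 is always
5' in transcription orientation. Windows clipped at chromosome ends
contribute means over the covered positions only; bins with no covered
position are missing (NaN) and are excluded from column means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .annotation import AnchoredRegion
from .coverage import CoverageTrack, NormalizationFactor, normalize_track
from .intervals import ValidationError


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class ProfileSpec:
    """Window geometry for anchor-relative profiles.

    half_width bp on each side of the anchor, split into n_bins equal
    bins of 2*half_width/n_bins bp; the default emulates 1 kb on each
    side of the TSS/enhancer center at 50 bins (40-bp bins).
    """

    half_width: int = 1000
    n_bins: int = 50
    strand_aware: bool = True

    def __post_init__(self) -> None:
        if self.n_bins < 2 or self.n_bins % 2 != 0:
            raise ValidationError("n_bins must be even and >= 2")
        if (2 * self.half_width) % self.n_bins != 0:
            raise ValidationError("bin width must be integral: 2*half_width % n_bins == 0")

    @property
    def bin_width(self) -> int:
        return 2 * self.half_width // self.n_bins

    def bin_midpoints(self) -> np.ndarray:
        """Relative bin midpoints in bp; negative = upstream of the anchor."""
        edges = np.arange(self.n_bins + 1) * self.bin_width - self.half_width
        return (edges[:-1] + edges[1:]) / 2.0


@dataclass
class HeatmapMatrix:
    """Region x bin mean-signal matrix with per-row region metadata."""

    regions: List[AnchoredRegion]
    midpoints: np.ndarray
    values: np.ndarray  # shape (n_regions, n_bins), NaN = missing
    groups: Optional[List[str]] = None
    sort_key: Optional[str] = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.regions), len(self.midpoints)):
            raise ValidationError("matrix shape does not match regions x bins")
        if self.groups is not None and len(self.groups) != len(self.regions):
            raise ValidationError("one group label per row required")

    @property
    def n_missing_rows(self) -> int:
        return int(np.all(np.isnan(self.values), axis=1).sum())

    def subset(self, row_idx: Sequence[int]) -> "HeatmapMatrix":
        idx = list(row_idx)
        return HeatmapMatrix(
            regions=[self.regions[i] for i in idx],
            midpoints=self.midpoints,
            values=self.values[idx],
            groups=None if self.groups is None else [self.groups[i] for i in idx],
            sort_key=self.sort_key,
        )


@dataclass
class MetageneProfile:
    """Column-mean profile over a heatmap matrix."""

    midpoints: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_regions: int
    units: str = "raw"
    r: Optional[float] = None


def binned_matrix(
    regions: Sequence[AnchoredRegion],
    track: CoverageTrack,
    spec: ProfileSpec = ProfileSpec(),
) -> HeatmapMatrix:
    """Mean coverage per bin around each region's anchor.

    Bins falling partly outside the chromosome average over the covered
    positions only; fully uncovered bins are NaN. For minus-strand
    anchors (when strand_aware) the bin order is reversed.
    """
    n_bins, bw, hw = spec.n_bins, spec.bin_width, spec.half_width
    values = np.full((len(regions), n_bins), np.nan)
    for i, region in enumerate(regions):
        chrom = region.interval.chrom
        if chrom not in track.data:
            continue
        clen = len(track.data[chrom])
        win_start = region.anchor - hw
        for j in range(n_bins):
            b0 = max(0, win_start + j * bw)
            b1 = min(clen, win_start + (j + 1) * bw)
            if b1 > b0:
                values[i, j] = float(track.data[chrom][b0:b1].mean())
        if spec.strand_aware and region.strand == "-":
            values[i] = values[i, ::-1]
    return HeatmapMatrix(regions=list(regions), midpoints=spec.bin_midpoints(),
                         values=values)


def profile_mean(matrix: HeatmapMatrix, units: str = "raw",
                 r: Optional[float] = None) -> MetageneProfile:
    """Per-bin arithmetic mean across rows, ignoring missing values per bin."""
    if len(matrix.regions) == 0:
        raise EstimationError("profile of an empty matrix")
    if np.all(np.isnan(matrix.values)):
        raise EstimationError("all rows missing: no covered positions")
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(matrix.values, axis=0)
        sd = np.nanstd(matrix.values, axis=0, ddof=1) if len(matrix.regions) > 1 \
            else np.zeros_like(mean)
    return MetageneProfile(midpoints=matrix.midpoints, mean=mean, sd=sd,
                           n_regions=len(matrix.regions), units=units, r=r)


def sort_heatmap(
    matrix: HeatmapMatrix,
    order_values: np.ndarray,
    groups: Sequence[str],
    group_order: Sequence[str],
    sort_key: str = "",
) -> HeatmapMatrix:
    """Block rows by occupancy group, descending row-mean of the ordering track.

    ``order_values`` is the row x bin matrix of the track used for
    ordering (often the matrix itself). Ties preserve genomic coordinate
    order (stable sort on the already coordinate-sorted rows).
    """
    if len(groups) != len(matrix.regions):
        raise ValidationError("one group label per row required")
    unknown = set(groups) - set(group_order)
    if unknown:
        raise ValidationError(f"unknown group labels: {sorted(unknown)}")
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        row_means = np.nanmean(order_values, axis=1)
    row_means = np.where(np.isnan(row_means), -np.inf, row_means)  # missing rows sink
    group_rank = {g: k for k, g in enumerate(group_order)}
    coord = [(r.interval.chrom, r.interval.start, r.interval.end)
             for r in matrix.regions]
    idx = sorted(range(len(groups)),
                 key=lambda i: (group_rank[groups[i]], -row_means[i], coord[i]))
    out = matrix.subset(idx)
    out.groups = [groups[i] for i in idx]
    out.sort_key = sort_key
    return out


def aggregate_fold(
    regions: Sequence[AnchoredRegion],
    chip: CoverageTrack,
    control: CoverageTrack,
    nf: NormalizationFactor,
    spec: ProfileSpec = ProfileSpec(half_width=2000, n_bins=50),
    pseudocount: float = 1.0,
) -> MetageneProfile:
    """Mean fold-enrichment profile over regions (aggregation plot).

    The ChIP track is fold-normalized against the NCIS-scaled control
    and averaged per bin across all anchors.
    """
    norm = normalize_track(chip, control, nf, mode="fold", pseudocount=pseudocount)
    matrix = binned_matrix(regions, norm, spec)
    return profile_mean(matrix, units="fold", r=nf.r)


def group_region_test(
    matrix_a: HeatmapMatrix,
    matrix_b: HeatmapMatrix,
    window: Tuple[float, float],
) -> Tuple[float, float, float]:
    """Welch two-sample t-test on per-region mean signal within a window.

    ``window`` is a (lo, hi) range of relative positions in bp; bins
    whose midpoints fall inside [lo, hi] are averaged per region, and
    the two groups of per-region means are compared with a two-tailed
    Welch t-test. Returns (t, df, p). When both groups are constant with
    equal means, (0, df, 1) by convention.
    """
    lo, hi = window
    def region_means(m: HeatmapMatrix) -> np.ndarray:
        cols = (m.midpoints >= lo) & (m.midpoints <= hi)
        if not cols.any():
            raise ValidationError("window selects no bins")
        vals = np.nanmean(m.values[:, cols], axis=1)
        return vals[~np.isnan(vals)]
    a, b = region_means(matrix_a), region_means(matrix_b)
    return welch_t(a, b)


def welch_t(a: np.ndarray, b: np.ndarray) -> Tuple[float, float, float]:
    """Two-tailed Welch t-test; degenerate zero-variance equal-mean case -> p=1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 regions")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), \
            float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    df = getattr(res, "df", None)
    if df is None:  # older scipy: recompute Welch-Satterthwaite
        sa, sb = va / len(a), vb / len(b)
        df = (sa + sb) ** 2 / (sa ** 2 / (len(a) - 1) + sb ** 2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)
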
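"""Shared fixtures and brute-force oracles.

The oracles here are deliberately naive (per-base position sets,
O(n*m) pairwise loops) and independent of the library's interval
algebra; they define what the fast implementations must agree with.
"""

from __future__ import annotations

from typing import Dict, List, Set, Tuple

import numpy as np
import pytest

from cooccupy import GenomicInterval, IntervalSet


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def random_intervals(
    rng: np.random.Generator,
    n: int,
    chroms: Tuple[str, ...] = ("c1", "c2"),
    max_pos: int = 10_000,
    max_len: int = 300,
    stranded: bool = True,
) -> List[GenomicInterval]:
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        strand = ["+", "-", "."][int(rng.integers(3))] if stranded else "."
        out.append(GenomicInterval(chrom, start, start + length, f"iv{i}",
                                   float(rng.integers(0, 100)), strand))
    return out


# -- per-base oracles ---------------------------------------------------


def covered_positions(intervals) -> Set[Tuple[str, int]]:
    """The set of (chrom, position) pairs covered by any interval."""
    pos: Set[Tuple[str, int]] = set()
    for iv in intervals:
        for p in range(iv.start, iv.end):
            pos.add((iv.chrom, p))
    return pos


def brute_overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap length by explicit per-base set intersection."""
    return len(covered_positions([a]) & covered_positions([b]))


def brute_any_overlap(iv: GenomicInterval, others, min_overlap: int = 1) -> bool:
    return any(brute_overlap_len(iv, o) >= min_overlap for o in others)
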
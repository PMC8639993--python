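"""Expression integration: fold-change direction, box statistics and the
occupancy-by-direction gene partition.

The six-group partition crosses three promoter occupancy classes (factor
B alone, A+B together, factor A alone — e.g. CHD4 / GFI1+CHD4 / GFI1)
with the direction of expression change (up / down) for the linked
genes. Genes whose fold change is classified "unchanged" are reported
separately, never silently dropped; so are occupied genes missing from
the expression table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import ValidationError
from .metagene import welch_t


@dataclass
class ExpressionRecord:
    """Per-gene expression with a log2 fold change for a stated contrast."""

    gene_id: str
    values: Dict[str, float] = field(default_factory=dict)
    log2fc: Optional[float] = None
    qvalue: Optional[float] = None


@dataclass
class BoxStats:
    """Tukey box-and-whisker statistics.

    Hinges are the 25th/75th linear-interpolation percentiles; whiskers
    extend to the most extreme observation within 1.5 IQR of the hinges;
    points beyond the whiskers are outliers.
    """

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: List[float]
    n: int


def log2_fold_change(a: float, b: float, pseudocount: float = 1.0) -> float:
    """log2((a + p) / (b + p)) with pseudocount p > 0."""
    if a < 0 or b < 0:
        raise ValidationError("expression means must be >= 0")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    return float(np.log2((a + pseudocount) / (b + pseudocount)))


def direction_classify(log2fc: float, threshold: float = 0.0) -> str:
    """'up' if log2fc > threshold, 'down' if < -threshold, else 'unchanged'."""
    if log2fc > threshold:
        return "up"
    if log2fc < -threshold:
        return "down"
    return "unchanged"


def box_stats(values: Sequence[float]) -> BoxStats:
    """Boxplot statistics with whiskers at 1.5 IQR, clipped to the data."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("box_stats requires at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    return BoxStats(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=sorted(float(v) for v in arr[(arr < lo_fence) | (arr > hi_fence)]),
        n=int(arr.size),
    )


def group_fc_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-tailed Welch t-test p-value between two fold-change samples."""
    _t, _df, p = welch_t(np.asarray(group_a), np.asarray(group_b))
    return p


def six_group_partition(
    gene_occupancy: Dict[str, str],
    expression: Dict[str, ExpressionRecord],
    threshold: float = 0.0,
    qvalue_cutoff: Optional[float] = None,
) -> Dict[Tuple[str, str], List[str]]:
    """Cross occupancy classes with expression direction.

    ``gene_occupancy`` maps gene_id -> occupancy class label (e.g.
    "CHD4", "GFI1+CHD4", "GFI1" for promoter-linked genes). Returns a
    map from (class, direction) to sorted gene lists, where direction is
    "up"/"down" for the six primary groups plus "unchanged" per class;
    occupied genes absent from the expression table appear under
    (class, "unmatched"). With ``qvalue_cutoff``, genes whose q-value
    exceeds the cutoff are classified "unchanged" regardless of sign.
    """
    out: Dict[Tuple[str, str], List[str]] = {}
    for gene_id, cls in sorted(gene_occupancy.items()):
        rec = expression.get(gene_id)
        if rec is None or rec.log2fc is None:
            key = (cls, "unmatched")
        else:
            if qvalue_cutoff is not None and (rec.qvalue is None
                                              or rec.qvalue > qvalue_cutoff):
                direction = "unchanged"
            else:
                direction = direction_classify(rec.log2fc, threshold)
            key = (cls, direction)
        out.setdefault(key, []).append(gene_id)
    return out


# -- expression table I/O ----------------------------------------------


def read_expression_tsv(
    path,
    condition_a: Optional[Sequence[str]] = None,
    condition_b: Optional[Sequence[str]] = None,
    pseudocount: float = 1.0,
) -> Dict[str, ExpressionRecord]:
    """Read a gene x sample TSV into expression records.

    The first column is the gene id. When a precomputed ``log2fc``
    column is present it is used; otherwise the fold change is computed
    from the means of the ``condition_a`` vs ``condition_b`` sample
    columns. An optional ``qvalue`` column is carried through.
    """
    df = pd.read_csv(path, sep="\t")
    gene_col = df.columns[0]
    records: Dict[str, ExpressionRecord] = {}
    for _, row in df.iterrows():
        gene_id = str(row[gene_col])
        values = {c: float(row[c]) for c in df.columns[1:]
                  if c not in ("log2fc", "qvalue")}
        if "log2fc" in df.columns:
            lfc = float(row["log2fc"])
        elif condition_a and condition_b:
            lfc = log2_fold_change(
                float(np.mean([row[c] for c in condition_a])),
                float(np.mean([row[c] for c in condition_b])),
                pseudocount,
            )
        else:
            lfc = None
        q = float(row["qvalue"]) if "qvalue" in df.columns else None
        records[gene_id] = ExpressionRecord(gene_id, values, lfc, q)
    return records


def write_expression_tsv(records: Dict[str, ExpressionRecord], path) -> None:
    sample_cols: List[str] = []
    for rec in records.values():
        for c in rec.values:
            if c not in sample_cols:
                sample_cols.append(c)
    with open(path, "w") as fh:
        header = ["gene_id"] + sample_cols + ["log2fc"]
        fh.write("\t".join(header) + "\n")
        for gene_id in sorted(records):
            rec = records[gene_id]
            row = [gene_id] + [format(rec.values.get(c, 0.0), ".6g") for c in sample_cols]
            row.append("" if rec.log2fc is None else format(rec.log2fc, ".6g"))
            fh.write("\t".join(row) + "\n")
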
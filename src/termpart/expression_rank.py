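"""Diurnal expression ranking from an FPKM matrix.

Genes are ranked by their unweighted arithmetic mean FPKM across all
timepoints of a diurnal (24 h) RNA-seq series; rank 1 is the most highly
expressed gene.  Tied means share the minimum rank of the tied block.
The ranking feeds terminator-candidate selection ("highly expressed"
means rank at or above a cutoff, with named exceptions such as genes
induced only under special conditions).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "load_fpkm",
    "rank_expression",
    "rank_filter",
    "utr_length_by_rank",
    "TopRankLengthResult",
]


def load_fpkm(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Load a genes x timepoints FPKM matrix from a delimited text file.

    The first column holds gene ids; the header row holds timepoint
    labels.  Raises ``ValueError`` on duplicate gene ids (naming them),
    non-numeric cells (with row/column coordinates) or negative values.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene id(s): {', '.join(map(str, dupes))}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        col = bad.loc[gene].idxmax()
        raise ValueError(
            f"non-numeric FPKM value {df.loc[gene, col]!r} at gene {gene!r}, "
            f"timepoint {col!r}"
        )
    if numeric.isna().any().any():
        gene = numeric.isna().any(axis=1).idxmax()
        raise ValueError(f"missing FPKM value(s), first at gene {gene!r}")
    if (numeric < 0).any().any():
        gene = (numeric < 0).any(axis=1).idxmax()
        raise ValueError(f"negative FPKM value(s), first at gene {gene!r}")
    return numeric


def rank_expression(
    matrix: pd.DataFrame,
    average_replicates: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Rank genes by descending mean FPKM over all timepoints.

    Returns a DataFrame indexed by gene id with columns ``mean_fpkm``,
    ``sd_fpkm`` (sample SD over timepoints; 0 for a single column) and
    ``rank`` (1 = highest mean, ties get the minimum rank of the block).

    ``average_replicates`` optionally maps a timepoint label to the
    replicate columns to average before the mean is taken; by default
    every column counts once.
    """
    if matrix.shape[1] < 1:
        raise ValueError("expression matrix needs at least one timepoint")
    if average_replicates:
        matrix = pd.DataFrame(
            {tp: matrix[list(cols)].mean(axis=1) for tp, cols in average_replicates.items()}
        )
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1).fillna(0.0) if matrix.shape[1] > 1 else pd.Series(
        0.0, index=matrix.index
    )
    rank = mean.rank(method="min", ascending=False).astype(int)
    return pd.DataFrame({"mean_fpkm": mean, "sd_fpkm": sd, "rank": rank})


def rank_filter(
    rank_table: pd.DataFrame,
    max_rank: int,
    exceptions: Iterable[str] = (),
) -> set[str]:
    """Genes with rank <= ``max_rank``, plus ``exceptions`` regardless of
    rank (if present in the table)."""
    if max_rank < 0:
        raise ValueError("max_rank must be >= 0")
    exceptions = set(exceptions)
    passing = set(rank_table.index[rank_table["rank"] <= max_rank])
    return passing | (exceptions & set(rank_table.index))


@dataclass
class TopRankLengthResult:
    """Count of top-ranked genes with a feature length above a threshold."""

    count: int
    top_n: int
    threshold: int
    missing_length: list[str]


def utr_length_by_rank(
    rank_table: pd.DataFrame,
    lengths: Iterable[tuple[str, int]],
    top_n: int,
    threshold: int,
    subset: Iterable[str] | None = None,
) -> TopRankLengthResult:
    """Among the ``top_n`` best-ranked genes, count 3'UTRs longer than
    ``threshold`` bp.

    ``subset`` optionally restricts the ranking first (e.g. to nuclear
    genes).  Top-``n`` genes without a length entry are listed in
    ``missing_length``, not silently dropped.
    """
    table = rank_table
    if subset is not None:
        table = table.loc[table.index.intersection(set(subset))]
    if top_n > len(table):
        raise ValueError(f"top_n={top_n} exceeds {len(table)} ranked genes")
    top = table.sort_values(["rank", "mean_fpkm"], ascending=[True, False]).head(top_n)
    length_map = dict(lengths)
    missing = [g for g in top.index if g not in length_map]
    count = int(
        np.sum([length_map[g] > threshold for g in top.index if g in length_map])
    )
    return TopRankLengthResult(
        count=count, top_n=top_n, threshold=threshold, missing_length=missing
    )
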
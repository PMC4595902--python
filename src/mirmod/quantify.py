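"""Plain-count quantification, size-factor normalization and comparisons.

Counts are per (mature miRNA, sample) sums of read depth times multimap
weight: templated and modified reads both count.  Normalization is the
median-of-ratios size-factor estimator (each sample's factor is the median,
over miRNAs with all-positive counts, of its count divided by the row
geometric mean); dispersion estimation and hypothesis testing are out of
scope.  Fold changes use a configurable pseudo-count (default 1.0).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd


def plain_counts(
    attributions: Iterable[tuple[str, str, float]],
    samples: Sequence[str],
    matures: Sequence[str],
) -> pd.DataFrame:
    """Build the mature x sample count matrix from (mature, sample, depth) triples.

    ``first_hit`` multimapping yields integer-valued cells, ``fractional``
    may yield fractions; unmapped reads contribute nothing.
    """
    counts = pd.DataFrame(0.0, index=sorted(matures), columns=list(samples))
    for mature_id, sample_id, depth in attributions:
        counts.loc[mature_id, sample_id] += depth
    return counts


def size_factors(counts: pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios size factors (one positive factor per sample).

    Each sample's factor is the median, over miRNAs with all-positive
    counts, of its count divided by the row geometric mean; factors are then
    rescaled to geometric mean 1, which leaves every between-sample ratio
    unchanged and makes normalization idempotent.  Requires at least two
    samples and at least one miRNA with positive counts in every sample;
    otherwise raises with a hint to pass a ``pseudocount``.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factor estimation needs at least 2 samples")
    c = counts.astype(float)
    if pseudocount:
        c = c + pseudocount
    pos = c[(c > 0).all(axis=1)]
    if pos.empty:
        raise ValueError(
            "no miRNA has positive counts in every sample; "
            "pass pseudocount > 0 to fall back to pseudo-counted ratios"
        )
    logc = np.log(pos)
    log_ratios = logc.sub(logc.mean(axis=1), axis=0)
    log_factors = log_ratios.median(axis=0)
    return np.exp(log_factors - log_factors.mean()).rename("size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    if factors is None:
        factors = size_factors(counts)
    return counts.div(factors, axis=1)


def _check_samples(matrix: pd.DataFrame, group: Sequence[str]) -> None:
    unknown = [s for s in group if s not in matrix.columns]
    if unknown:
        raise KeyError(f"unknown sample(s): {unknown}")
    if not group:
        raise ValueError("empty sample group")


def top_expressed(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n: int = 10,
) -> pd.DataFrame:
    """Top-n miRNAs by mean normalized count over both groups, side by side.

    Ties in the overall mean break lexicographically by mature ID.
    """
    if n not in (10, 20, 50):
        raise ValueError("n must be one of 10, 20, 50")
    _check_samples(matrix, group_a)
    _check_samples(matrix, group_b)
    union = list(dict.fromkeys([*group_a, *group_b]))
    table = pd.DataFrame(
        {
            "mean_overall": matrix[union].mean(axis=1),
            "mean_a": matrix[list(group_a)].mean(axis=1),
            "mean_b": matrix[list(group_b)].mean(axis=1),
        }
    )
    table = table.sort_values(
        by=["mean_overall"], ascending=False, kind="mergesort"
    )
    # stable sort on the (already lexicographic) index, then by mean, keeps
    # lexicographic order within ties
    table = table.sort_index(kind="mergesort").sort_values(
        by="mean_overall", ascending=False, kind="mergesort"
    )
    return table.head(n)


def pairwise_table(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudo: float = 1.0,
) -> pd.DataFrame:
    """Per-miRNA group means and log2 fold change (the scatterplot's table).

    lfc = log2((mean_a + pseudo) / (mean_b + pseudo)); sorted by |lfc|
    descending, ties lexicographic.  Groups must be disjoint.
    """
    _check_samples(matrix, group_a)
    _check_samples(matrix, group_b)
    if set(group_a) & set(group_b):
        raise ValueError(f"overlapping groups: {sorted(set(group_a) & set(group_b))}")
    mean_a = matrix[list(group_a)].mean(axis=1)
    mean_b = matrix[list(group_b)].mean(axis=1)
    lfc = np.log2((mean_a + pseudo) / (mean_b + pseudo))
    table = pd.DataFrame({"mean_a": mean_a, "mean_b": mean_b, "log2fc": lfc})
    table = table.sort_index(kind="mergesort")
    return table.iloc[np.argsort(-table["log2fc"].abs().to_numpy(), kind="stable")]


def total_counts(counts: pd.DataFrame) -> pd.Series:
    """Per-sample total counts (the QC totals table)."""
    return counts.sum(axis=0).rename("total_counts")
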
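"""Rank aggregation of score matrices and ingestion of external results.

A :class:`InteractionRanking` turns a score matrix into per-miRNA ranks
(1 = strongest predicted target) according to the matrix's ordering
convention.  Borda aggregation averages ranks across methods; the top-k
variant first replaces ranks beyond k by the maximal rank (the number of
mRNAs), so that only agreement inside the top-k lists counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ExpressionDataset,
    MirankError,
    Ordering,
    ScoreMatrix,
    check_name_sets,
)

__all__ = ["InteractionRanking", "to_ranking", "borda", "borda_topk",
           "read_external_result", "write_ranking"]


class InteractionRanking:
    """Per-miRNA ranking of mRNAs derived from a score matrix.

    ``ranks.loc[mRNA, miRNA]`` is the 1-based rank of the mRNA under that
    miRNA (ties share the mean rank); ``scores`` holds the originating
    scores.  Within a miRNA every mRNA appears exactly once.
    """

    def __init__(self, ranks: pd.DataFrame, scores: pd.DataFrame,
                 method_label: str) -> None:
        self.ranks = ranks
        self.scores = scores
        self.method_label = method_label

    @property
    def mrna_names(self) -> list[str]:
        return [str(i) for i in self.ranks.index]

    @property
    def mirna_names(self) -> list[str]:
        return [str(c) for c in self.ranks.columns]

    @property
    def n_mrna(self) -> int:
        return self.ranks.shape[0]

    def ordered_targets(self, mirna: str) -> list[tuple[str, float, float]]:
        """(mRNA, score, rank) triples sorted by rank, then mRNA name."""
        col = self.ranks[mirna]
        order = sorted(col.index, key=lambda g: (col[g], str(g)))
        return [(str(g), float(self.scores.loc[g, mirna]), float(col[g]))
                for g in order]


def to_ranking(sm: ScoreMatrix) -> InteractionRanking:
    """Rank mRNAs per miRNA according to the matrix's ordering convention."""
    vals = sm.values.to_numpy(dtype=float)
    if sm.ordering in (Ordering.ASC_SIGNED, Ordering.ASC_RANK):
        keyed = vals
    elif sm.ordering is Ordering.DESC_VALUE:
        keyed = -vals
    else:  # pragma: no cover - enum is closed
        raise MirankError(f"unknown ordering {sm.ordering}")
    ranks = np.apply_along_axis(
        lambda c: stats.rankdata(c, method="average"), 0, keyed)
    rank_df = pd.DataFrame(ranks, index=sm.values.index,
                           columns=sm.values.columns)
    return InteractionRanking(rank_df, sm.values.copy(), sm.method_label)


def _check_rankings(rankings: list[InteractionRanking]) -> None:
    if len(rankings) < 2:
        raise MirankError("Borda aggregation needs at least 2 rankings")
    first = rankings[0]
    for r in rankings[1:]:
        check_name_sets(first.mrna_names, first.mirna_names,
                        r.mrna_names, r.mirna_names)


def borda(rankings: list[InteractionRanking]) -> ScoreMatrix:
    """Average rank across methods (classic Borda aggregation)."""
    _check_rankings(rankings)
    base = rankings[0].ranks
    total = base.copy()
    for r in rankings[1:]:
        total = total + r.ranks.reindex(index=base.index, columns=base.columns)
    mean = total / len(rankings)
    label = "Borda(" + ",".join(r.method_label for r in rankings) + ")"
    return ScoreMatrix(mean, label, Ordering.ASC_RANK)


def borda_topk(rankings: list[InteractionRanking], k: int) -> ScoreMatrix:
    """Borda aggregation of truncated rankings.

    Per method and miRNA, ranks strictly greater than ``k`` are replaced
    by the maximal rank — the number of mRNAs in the dataset — before
    averaging, so only genes inside a method's top-k list retain their
    rank.  A gene exactly at rank k is kept.
    """
    if k < 1:
        raise MirankError("k must be >= 1")
    _check_rankings(rankings)
    base = rankings[0].ranks
    n_mrna = base.shape[0]
    total = None
    for r in rankings:
        ranks = r.ranks.reindex(index=base.index, columns=base.columns)
        truncated = ranks.where(ranks <= k, float(n_mrna))
        total = truncated if total is None else total + truncated
    mean = total / len(rankings)
    label = (f"BordaTopk{k}(" +
             ",".join(r.method_label for r in rankings) + ")")
    return ScoreMatrix(mean, label, Ordering.ASC_RANK)


def read_external_result(
    ds: ExpressionDataset,
    path,
    ordering: Ordering,
    method_label: str | None = None,
    allow_unknown: bool = False,
) -> ScoreMatrix:
    """Read an externally computed score matrix and align it to a dataset.

    The CSV has mRNA rows (first column = names) and miRNA columns in any
    order.  Rows/columns are reindexed to the dataset's order; pairs
    missing from the file become 0 with a warning; feature names unknown
    to the dataset raise an error unless ``allow_unknown`` (then they are
    dropped with a warning).
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    mrnas, mirnas = ds.mrna_names, ds.mirna_names
    unknown_rows = [g for g in df.index if g not in set(mrnas)]
    unknown_cols = [m for m in df.columns if m not in set(mirnas)]
    if (unknown_rows or unknown_cols) and not allow_unknown:
        raise MirankError(
            f"external result has unknown feature names: rows={unknown_rows} "
            f"columns={unknown_cols}"
        )
    if unknown_rows or unknown_cols:
        warnings.warn(
            f"external result: dropping unknown rows={unknown_rows} "
            f"columns={unknown_cols}"
        )
        df = df.drop(index=unknown_rows, columns=unknown_cols)
    aligned = df.reindex(index=mrnas, columns=mirnas)
    missing = int(aligned.isna().to_numpy().sum())
    if missing:
        warnings.warn(
            f"external result: {missing} missing pairs filled with 0")
        aligned = aligned.fillna(0.0)
    label = method_label or "External"
    return ScoreMatrix(aligned.astype(float), label, ordering)


def write_ranking(ranking: InteractionRanking, path, k: int | None = None
                  ) -> None:
    """Long-format CSV export ``miRNA,mRNA,score,rank`` (top-k slice)."""
    rows = []
    for mirna in ranking.mirna_names:
        triples = ranking.ordered_targets(mirna)
        if k is not None:
            triples = triples[:k]
        rows.extend((mirna, g, s, r) for g, s, r in triples)
    pd.DataFrame(rows, columns=["miRNA", "mRNA", "score", "rank"]).to_csv(
        path, index=False, lineterminator="\n"
    )
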
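"""Core containers shared across the toolkit.

The central objects are an expression dataset with matched miRNA ("cause")
and mRNA ("effect") columns, a score matrix produced by a prediction
method, and the two kinds of ground truth used to validate predictions:
experimentally confirmed interaction pairs and miRNA perturbation
(transfection) log2 fold-changes.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Ordering",
    "ExpressionDataset",
    "ScoreMatrix",
    "GroundTruth",
    "PerturbationTable",
    "DeResult",
    "MirankError",
    "OverlappingRangesError",
    "NonNumericCellError",
    "MissingValuesError",
]


class MirankError(ValueError):
    """Base class for toolkit-specific input errors."""


class OverlappingRangesError(MirankError):
    """Cause and effect column ranges overlap."""


class NonNumericCellError(MirankError):
    """A CSV cell is neither numeric nor a recognised missing-value token."""


class MissingValuesError(MirankError):
    """Operation requires complete data but missing values are present."""


class Ordering(enum.Enum):
    """How a score matrix orders predictions from strongest to weakest.

    miRNAs predominantly down-regulate their targets, so sign-carrying
    methods (correlation, regression coefficients, causal effects) rank
    the most negative scores first (``ASC_SIGNED``).  Non-negative
    dependence measures rank the largest values first (``DESC_VALUE``),
    and aggregated rank matrices rank the smallest mean rank first
    (``ASC_RANK``).
    """

    ASC_SIGNED = "asc_signed"
    DESC_VALUE = "desc_value"
    ASC_RANK = "asc_rank"


@dataclass
class ExpressionDataset:
    """Samples x features expression matrix with matched miRNA/mRNA columns.

    Parameters
    ----------
    data
        DataFrame of shape (n_samples, n_features); the index holds sample
        identifiers and the columns hold feature names.  Values are assumed
        to be on a log2 scale.
    cause_idx
        0-based column positions of the miRNAs (regulators).
    effect_idx
        0-based column positions of the mRNAs (potential targets).
    """

    data: pd.DataFrame
    cause_idx: list[int]
    effect_idx: list[int]

    def __post_init__(self) -> None:
        self.cause_idx = list(self.cause_idx)
        self.effect_idx = list(self.effect_idx)
        if not self.cause_idx or not self.effect_idx:
            raise MirankError("need at least one miRNA and one mRNA column")
        if set(self.cause_idx) & set(self.effect_idx):
            raise OverlappingRangesError(
                "cause and effect column ranges overlap"
            )
        ncol = self.data.shape[1]
        for i in self.cause_idx + self.effect_idx:
            if not (0 <= i < ncol):
                raise MirankError(f"column index {i} outside 0..{ncol - 1}")
        if self.data.shape[0] < 3:
            raise MirankError("expression dataset needs at least 3 samples")
        names = list(self.data.columns)
        if len(set(names)) != len(names):
            raise MirankError("duplicate feature names in dataset")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def mirna_names(self) -> list[str]:
        cols = self.data.columns
        return [str(cols[i]) for i in self.cause_idx]

    @property
    def mrna_names(self) -> list[str]:
        cols = self.data.columns
        return [str(cols[i]) for i in self.effect_idx]

    def cause_matrix(self) -> np.ndarray:
        """(n_samples, n_mirna) float array of miRNA expressions."""
        return self.data.iloc[:, self.cause_idx].to_numpy(dtype=float)

    def effect_matrix(self) -> np.ndarray:
        """(n_samples, n_mrna) float array of mRNA expressions."""
        return self.data.iloc[:, self.effect_idx].to_numpy(dtype=float)

    def has_missing(self) -> bool:
        return bool(self.data.isna().to_numpy().any())

    def with_data(self, data: pd.DataFrame) -> "ExpressionDataset":
        """New dataset with the same column roles but replaced values."""
        return ExpressionDataset(data, list(self.cause_idx), list(self.effect_idx))


@dataclass
class ScoreMatrix:
    """mRNAs x miRNAs matrix of prediction scores.

    ``values.loc[mRNA, miRNA]`` is the score of the prediction that the
    mRNA is a target of the miRNA; ``ordering`` states how scores map to
    ranking strength and is set exactly once by the producing method.
    """

    values: pd.DataFrame
    method_label: str
    ordering: Ordering

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = int((~np.isfinite(arr)).sum())
            warnings.warn(
                f"{self.method_label}: {bad} non-finite scores replaced by 0"
            )
            self.values = self.values.where(
                pd.DataFrame(np.isfinite(arr), index=self.values.index,
                             columns=self.values.columns),
                0.0,
            )

    @property
    def mrna_names(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def mirna_names(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_mrna(self) -> int:
        return self.values.shape[0]

    @property
    def n_mirna(self) -> int:
        return self.values.shape[1]


@dataclass
class GroundTruth:
    """Set of experimentally confirmed (miRNA, mRNA) interaction pairs."""

    pairs: set[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pairs = set(self.pairs)
        for m, g in self.pairs:
            if not m or not g:
                raise MirankError("ground-truth names must be non-empty")

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PerturbationTable:
    """miRNA transfection/knockdown log2 fold-changes per gene.

    ``records`` maps (miRNA, gene) -> LFC.  Duplicate (miRNA, gene) rows
    keep the first occurrence (with a warning).
    """

    records: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, rows: Iterable[tuple[str, str, float]]
    ) -> "PerturbationTable":
        records: dict[tuple[str, str], float] = {}
        dup = 0
        for mirna, gene, lfc in rows:
            lfc = float(lfc)
            if not np.isfinite(lfc):
                raise MirankError(
                    f"non-finite LFC for ({mirna}, {gene})"
                )
            key = (str(mirna), str(gene))
            if key in records:
                dup += 1
                continue
            records[key] = lfc
        if dup:
            warnings.warn(
                f"perturbation table: {dup} duplicate (miRNA, gene) rows "
                "dropped (first kept)"
            )
        return cls(records)

    def derive_truth(self, lfc_threshold: float = 1.0) -> GroundTruth:
        """Pairs whose |LFC| strictly exceeds the threshold."""
        if lfc_threshold <= 0:
            raise MirankError("lfc_threshold must be positive")
        pairs = {
            k for k, v in self.records.items() if abs(v) > lfc_threshold
        }
        return GroundTruth(pairs, provenance="perturbation")

    def mirnas(self) -> set[str]:
        return {m for m, _ in self.records}

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class DeResult:
    """Differential-expression result for one feature set.

    ``table`` has one row per feature with columns ``statistic`` (moderated
    t), ``p_value``, ``adj_p_value`` (Benjamini-Hochberg) and ``selected``.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float

    @property
    def selected_features(self) -> list[str]:
        return [str(i) for i in self.table.index[self.table["selected"]]]


def check_name_sets(
    a_rows: Sequence[str], a_cols: Sequence[str],
    b_rows: Sequence[str], b_cols: Sequence[str],
) -> None:
    """Raise when two score matrices are not over identical name sets."""
    if set(a_rows) != set(b_rows) or set(a_cols) != set(b_cols):
        raise MirankError("score matrices cover different feature name sets")
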
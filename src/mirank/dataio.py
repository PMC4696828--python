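"""Reading/writing the toolkit's file formats and expression pre-processing.

File formats
------------
* Expression CSV: header row of feature names, one row per sample.  An
  optional first column of sample identifiers is auto-detected when its
  header is ``Sample`` (case-insensitive) or the column is non-numeric.
  Column ranges given by users are 1-based inclusive, mirroring the
  convention of R-style calls such as ``cause=1:35, effect=36:1189``;
  internally everything is 0-based.
* Ground-truth CSV: header ``miRNA,mRNA``.
* Perturbation CSV: header ``miRNA,gene,lfc`` (log2 fold-change).

Pre-processing
--------------
``standardise`` (z-score per feature), ``impute_normalise`` (KNN
imputation followed by quantile normalisation) and ``diff_exp``
(empirical-Bayes moderated t-test with Benjamini-Hochberg adjustment).
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    DeResult,
    ExpressionDataset,
    GroundTruth,
    MirankError,
    MissingValuesError,
    NonNumericCellError,
    OverlappingRangesError,
    PerturbationTable,
    ScoreMatrix,
    Ordering,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_ground_truth",
    "write_ground_truth",
    "read_perturbation",
    "write_perturbation",
    "write_score_matrix",
    "read_score_matrix",
    "standardise",
    "impute_normalise",
    "diff_exp",
    "bh_adjust",
]

#: Missing-value tokens recognised in CSV cells (case-insensitive).
MISSING_TOKENS = {"", "na", "nan"}


def _parse_cell(text: str, row: int, col: str) -> float:
    t = text.strip()
    if t.lower() in MISSING_TOKENS:
        return np.nan
    try:
        return float(t)
    except ValueError:
        raise NonNumericCellError(
            f"non-numeric cell {text!r} at data row {row + 1}, column {col!r}"
        ) from None


def _range_to_idx(rng: tuple[int, int], ncol: int, what: str) -> list[int]:
    lo, hi = int(rng[0]), int(rng[1])
    if lo < 1 or hi > ncol or lo > hi:
        raise MirankError(
            f"{what} range {lo}:{hi} outside 1:{ncol} or empty"
        )
    return list(range(lo - 1, hi))


def read_expression(
    path: str | Path,
    cause_range: tuple[int, int],
    effect_range: tuple[int, int],
) -> ExpressionDataset:
    """Read a matched miRNA+mRNA expression CSV.

    ``cause_range`` and ``effect_range`` are 1-based inclusive column
    ranges over the feature columns (after any sample-ID column has been
    stripped); they must not overlap.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows or len(rows) < 2:
        raise MirankError(f"{path}: need a header row and at least one sample")
    header = [h.strip() for h in rows[0]]
    body = rows[1:]

    # sample-ID column detection: header "Sample" or non-numeric first column
    def _is_missing_or_number(t: str) -> bool:
        if t.strip().lower() in MISSING_TOKENS:
            return True
        try:
            float(t)
            return True
        except ValueError:
            return False

    has_ids = header[0].lower() == "sample" or not all(
        _is_missing_or_number(r[0]) for r in body if r
    )
    if has_ids:
        sample_ids = [r[0] for r in body]
        header = header[1:]
        body = [r[1:] for r in body]
    else:
        sample_ids = [f"S{i + 1}" for i in range(len(body))]

    ncol = len(header)
    cause_idx = _range_to_idx(cause_range, ncol, "cause")
    effect_idx = _range_to_idx(effect_range, ncol, "effect")
    if set(cause_idx) & set(effect_idx):
        raise OverlappingRangesError(
            f"cause range {cause_range} overlaps effect range {effect_range}"
        )

    matrix = np.empty((len(body), ncol))
    for i, row in enumerate(body):
        if len(row) != ncol:
            raise MirankError(
                f"{path}: data row {i + 1} has {len(row)} cells, expected {ncol}"
            )
        for j, cell in enumerate(row):
            matrix[i, j] = _parse_cell(cell, i, header[j])

    data = pd.DataFrame(matrix, index=sample_ids, columns=header)
    return ExpressionDataset(data, cause_idx, effect_idx)


def write_expression(ds: ExpressionDataset, path: str | Path) -> None:
    """Write an expression CSV with a leading ``Sample`` ID column."""
    out = ds.data.copy()
    out.insert(0, "Sample", ds.sample_ids)
    out.to_csv(path, index=False, lineterminator="\n")


def read_ground_truth(path: str | Path, provenance: str = "") -> GroundTruth:
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip() for c in df.columns]
    if len(cols) < 2:
        raise MirankError(f"{path}: ground truth needs miRNA,mRNA columns")
    pairs = {
        (str(m).strip(), str(g).strip())
        for m, g in zip(df.iloc[:, 0], df.iloc[:, 1])
    }
    return GroundTruth(pairs, provenance=provenance or str(path))


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = sorted(truth.pairs)
    pd.DataFrame(rows, columns=["miRNA", "mRNA"]).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_perturbation(path: str | Path) -> PerturbationTable:
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise MirankError(f"{path}: perturbation needs miRNA,gene,lfc columns")
    return PerturbationTable.from_records(
        (str(r.iloc[0]).strip(), str(r.iloc[1]).strip(), float(r.iloc[2]))
        for _, r in df.iterrows()
    )


def write_perturbation(pert: PerturbationTable, path: str | Path) -> None:
    rows = [(m, g, lfc) for (m, g), lfc in sorted(pert.records.items())]
    pd.DataFrame(rows, columns=["miRNA", "gene", "lfc"]).to_csv(
        path, index=False, lineterminator="\n"
    )


def write_score_matrix(sm: ScoreMatrix, path: str | Path) -> None:
    """Score CSV (first column mRNA names) plus a JSON sidecar with the
    method label and ordering convention."""
    import json

    path = Path(path)
    out = sm.values.copy()
    out.index.name = "mRNA"
    out.to_csv(path, lineterminator="\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"method_label": sm.method_label, "ordering": sm.ordering.value},
            indent=2,
        )
        + "\n"
    )


def read_score_matrix(path: str | Path) -> ScoreMatrix:
    """Read a score CSV written by :func:`write_score_matrix`."""
    import json

    path = Path(path)
    values = pd.read_csv(path, index_col=0)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label = meta.get("method_label", path.stem)
        ordering = Ordering(meta.get("ordering", "desc_value"))
    else:
        label, ordering = path.stem, Ordering.DESC_VALUE
    return ScoreMatrix(values, label, ordering)


# ---------------------------------------------------------------------------
# pre-processing


def standardise(ds: ExpressionDataset) -> ExpressionDataset:
    """Z-score each feature column (mean 0, unbiased sd 1).

    Zero-variance columns become all-zero and are reported via a warning;
    they carry no ranking information and downstream scorers treat them as
    degenerate.
    """
    if ds.has_missing():
        raise MissingValuesError("standardise requires complete data")
    arr = ds.data.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    flat = sd == 0
    safe_sd = np.where(flat, 1.0, sd)
    out = (arr - mean) / safe_sd
    out[:, flat] = 0.0
    if flat.any():
        names = [ds.feature_names[i] for i in np.flatnonzero(flat)]
        warnings.warn(f"zero-variance features set to 0: {names}")
    return ds.with_data(
        pd.DataFrame(out, index=ds.data.index, columns=ds.data.columns)
    )


def impute_normalise(
    ds: ExpressionDataset, k_neighbors: int = 10
) -> ExpressionDataset:
    """KNN imputation followed by quantile normalisation across samples.

    Features missing in more than half the samples are dropped (warning).
    Each remaining missing cell is replaced by the mean of that feature
    over the ``k_neighbors`` samples nearest in Euclidean distance over
    the complete features (features observed in every sample); when no
    complete feature exists the feature median is used.  Quantile
    normalisation then maps every sample's empirical distribution onto
    the mean order-statistic distribution; tied values receive the mean
    of the quantile values they span.
    """
    if k_neighbors < 1:
        raise MirankError("k_neighbors must be >= 1")
    data = ds.data.copy()
    n = data.shape[0]

    frac_missing = data.isna().mean(axis=0)
    if (frac_missing >= 1.0).any():
        bad = list(data.columns[frac_missing >= 1.0])
        raise MirankError(f"features entirely missing: {bad}")
    drop = frac_missing > 0.5
    if drop.any():
        dropped = list(data.columns[drop])
        warnings.warn(f"features >50% missing dropped: {dropped}")
        keep_pos = np.flatnonzero(~drop.to_numpy())
        pos_map = {old: new for new, old in enumerate(keep_pos)}
        cause_idx = [pos_map[i] for i in ds.cause_idx if i in pos_map]
        effect_idx = [pos_map[i] for i in ds.effect_idx if i in pos_map]
        data = data.loc[:, ~drop]
        if not cause_idx or not effect_idx:
            raise MirankError("dropping missing-heavy features emptied a role")
    else:
        cause_idx, effect_idx = list(ds.cause_idx), list(ds.effect_idx)

    arr = data.to_numpy(dtype=float)
    missing = np.isnan(arr)
    if missing.any():
        complete_cols = ~missing.any(axis=0)
        for j in np.flatnonzero(missing.any(axis=0)):
            observed = ~missing[:, j]
            col_median = float(np.median(arr[observed, j]))
            for i in np.flatnonzero(missing[:, j]):
                if complete_cols.any():
                    diffs = arr[:, complete_cols] - arr[i, complete_cols]
                    dist = np.sqrt((diffs**2).sum(axis=1))
                    cand = np.flatnonzero(observed)
                    order = cand[np.argsort(dist[cand], kind="stable")]
                    nearest = order[: min(k_neighbors, len(order))]
                    arr[i, j] = float(arr[nearest, j].mean())
                else:
                    arr[i, j] = col_median

    arr = _quantile_normalise(arr)
    out = pd.DataFrame(arr, index=data.index, columns=data.columns)
    return ExpressionDataset(out, cause_idx, effect_idx)


def _quantile_normalise(arr: np.ndarray) -> np.ndarray:
    """Map each row (sample) to the mean order-statistic distribution."""
    n, p = arr.shape
    sorted_rows = np.sort(arr, axis=1)
    reference = sorted_rows.mean(axis=0)  # mean k-th order statistic
    out = np.empty_like(arr)
    for i in range(n):
        row = arr[i]
        order = np.argsort(row, kind="stable")
        assigned = np.empty(p)
        assigned[order] = reference
        # tied values share the mean of the reference values they span
        _, inv = np.unique(row, return_inverse=True)
        sums = np.bincount(inv, weights=assigned)
        counts = np.bincount(inv)
        out[i] = (sums / counts)[inv]
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def _moment_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior for gene variances.

    Under the hierarchical model s_g^2 ~ s0^2 * F(d, d0), matching the
    first two moments of the observed {s_g^2} gives d0 and s0^2.  When
    the observed variances are under-dispersed relative to any finite
    d0 the prior degrees of freedom are infinite and the posterior
    variance is the mean observed variance.
    """
    m = float(np.mean(s2))
    v = float(np.var(s2, ddof=1)) if len(s2) > 1 else 0.0
    if m <= 0:
        return np.inf, max(m, 0.0)
    z = v / (m * m)
    # z = 2 (d + d0 - 2) / (d (d0 - 4))  =>  solve for d0
    denom = z * d - 2
    if denom <= 0:
        return np.inf, m
    d0 = (2 * d - 4 + 4 * z * d) / denom
    if d0 <= 4:  # moments undefined below 4 df; fall back to heavy tails
        d0 = 4.0 + 1e-6
    s0_sq = m * (d0 - 2) / d0
    return d0, s0_sq


def diff_exp(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    select: dict,
    method: str = "moderated",
) -> DeResult:
    """Per-feature differential expression between two sample groups.

    Both groups are samples x features with identical feature columns.
    The default test is a moderated t-statistic with empirical-Bayes
    variance shrinkage: the pooled within-group variance s_g^2 (d_g
    degrees of freedom) is shrunk toward a prior (d0, s0^2) estimated by
    method of moments, giving

        s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)
        t~_g   = (mean_a - mean_b) / (s~_g sqrt(1/n_a + 1/n_b))

    with two-sided p-values from a t distribution on d0 + d_g df.
    ``method="welch"`` uses a plain Welch t-test instead.

    ``select`` is either ``{"top_n": N}`` (N smallest raw p-values, ties
    broken by feature order) or ``{"max_adj_p": q}`` (BH-adjusted p <= q).
    """
    if list(group_a.columns) != list(group_b.columns):
        raise MirankError("diff_exp groups must share an identical feature set")
    n_a, n_b = group_a.shape[0], group_b.shape[0]
    if n_a < 2 or n_b < 2:
        raise MirankError("each group needs at least 2 samples")

    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    delta = mean_a - mean_b

    if method == "welch":
        stat, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
        d0, s0_sq = np.nan, np.nan
    elif method == "moderated":
        d_g = n_a + n_b - 2
        ss = ((a - mean_a) ** 2).sum(axis=0) + ((b - mean_b) ** 2).sum(axis=0)
        s2 = ss / d_g
        d0, s0_sq = _moment_prior(s2, d_g)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df = np.inf
        else:
            s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
            df = d0 + d_g
        se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
        p = 2 * stats.t.sf(np.abs(stat), df)
    else:
        raise MirankError(f"unknown diff_exp method {method!r}")

    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    adj = bh_adjust(p)

    selected = np.zeros(len(p), dtype=bool)
    if "top_n" in select:
        top_n = int(select["top_n"])
        if top_n < 0 or top_n > len(p):
            raise MirankError(f"top_n {top_n} outside 0..{len(p)}")
        order = np.argsort(p, kind="stable")  # ties: original column order
        selected[order[:top_n]] = True
    elif "max_adj_p" in select:
        selected = adj <= float(select["max_adj_p"])
    else:
        raise MirankError("select must contain 'top_n' or 'max_adj_p'")

    table = pd.DataFrame(
        {
            "statistic": stat,
            "p_value": p,
            "adj_p_value": adj,
            "selected": selected,
        },
        index=group_a.columns,
    )
    return DeResult(table=table, d0=float(d0), s0_sq=float(s0_sq))
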
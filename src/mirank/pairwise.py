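"""Per-pair association scorers between each miRNA and each mRNA.

Every scorer fills an mRNAs x miRNAs :class:`~mirank.datatypes.ScoreMatrix`
from an :class:`~mirank.datatypes.ExpressionDataset`.  Sign-carrying
measures (Pearson, Spearman, Kendall) use the ``ASC_SIGNED`` ordering —
miRNAs predominantly down-regulate targets, so the most negative
associations rank first.  Non-negative dependence measures (distance
correlation, Hoeffding's D, RDC, mutual information, pseudo-knockout
Z-score) use ``DESC_VALUE``.

Undefined scores (e.g. a zero-variance feature) are stored as 0 with a
warning rather than aborting the whole matrix: a batch scoring run over
thousands of pairs should degrade gracefully.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionDataset, MirankError, Ordering, ScoreMatrix

__all__ = [
    "pearson",
    "spearman",
    "kendall",
    "dcov",
    "hoeffding",
    "rdc",
    "mutual_information",
    "zscore",
    "distance_correlation",
    "hoeffding_d",
    "rdc_pair",
    "PAIRWISE_METHODS",
]


def _check(ds: ExpressionDataset, min_samples: int, label: str) -> None:
    if ds.has_missing():
        raise MirankError(f"{label}: dataset contains missing values")
    if ds.n_samples < min_samples:
        raise MirankError(
            f"{label}: needs >= {min_samples} samples, got {ds.n_samples}"
        )


def _matrix(ds: ExpressionDataset, values: np.ndarray, label: str,
            ordering: Ordering) -> ScoreMatrix:
    df = pd.DataFrame(values, index=ds.mrna_names, columns=ds.mirna_names)
    return ScoreMatrix(df, label, ordering)


def _zero_variance_warn(arr: np.ndarray, names: list[str], label: str
                        ) -> np.ndarray:
    flat = arr.std(axis=0, ddof=1) == 0
    if flat.any():
        bad = [names[i] for i in np.flatnonzero(flat)]
        warnings.warn(f"{label}: zero-variance features scored 0: {bad}")
    return flat


# ---------------------------------------------------------------------------
# linear / rank correlations


def _pearson_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(y-features x x-features) matrix of Pearson correlations."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = x.std(axis=0, ddof=1)
    sy = y.std(axis=0, ddof=1)
    n = x.shape[0]
    cov = yc.T @ xc / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.outer(np.where(sy == 0, 1, sy), np.where(sx == 0, 1, sx))
    r[sy == 0, :] = 0.0
    r[:, sx == 0] = 0.0
    return np.clip(r, -1.0, 1.0)


def pearson(ds: ExpressionDataset) -> ScoreMatrix:
    """Pearson correlation of every mRNA with every miRNA."""
    _check(ds, 3, "pearson")
    x, y = ds.cause_matrix(), ds.effect_matrix()
    _zero_variance_warn(np.hstack([x, y]), ds.mirna_names + ds.mrna_names,
                        "pearson")
    return _matrix(ds, _pearson_matrix(x, y), "Pearson", Ordering.ASC_SIGNED)


def spearman(ds: ExpressionDataset) -> ScoreMatrix:
    """Spearman rank correlation (Pearson on mid-ranks)."""
    _check(ds, 3, "spearman")
    x, y = ds.cause_matrix(), ds.effect_matrix()
    _zero_variance_warn(np.hstack([x, y]), ds.mirna_names + ds.mrna_names,
                        "spearman")
    rx = np.apply_along_axis(stats.rankdata, 0, x)
    ry = np.apply_along_axis(stats.rankdata, 0, y)
    return _matrix(ds, _pearson_matrix(rx, ry), "Spearman",
                   Ordering.ASC_SIGNED)


def kendall(ds: ExpressionDataset) -> ScoreMatrix:
    """Kendall's tau-b (tie-corrected) per pair."""
    _check(ds, 3, "kendall")
    x, y = ds.cause_matrix(), ds.effect_matrix()
    flat_x = x.std(axis=0, ddof=1) == 0
    flat_y = y.std(axis=0, ddof=1) == 0
    if flat_x.any() or flat_y.any():
        warnings.warn("kendall: zero-variance features scored 0")
    out = np.zeros((y.shape[1], x.shape[1]))
    for j in range(x.shape[1]):
        if flat_x[j]:
            continue
        for i in range(y.shape[1]):
            if flat_y[i]:
                continue
            tau = stats.kendalltau(x[:, j], y[:, i]).statistic
            out[i, j] = 0.0 if np.isnan(tau) else tau
    return _matrix(ds, out, "Kendall", Ordering.ASC_SIGNED)


# ---------------------------------------------------------------------------
# distance correlation


def _centred_distances(v: np.ndarray) -> np.ndarray:
    """Double-centred pairwise absolute-difference matrix of a vector."""
    d = np.abs(v[:, None] - v[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) \
        + d.mean()


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation (biased V-statistic form), in [0, 1]."""
    a = _centred_distances(np.asarray(x, dtype=float))
    b = _centred_distances(np.asarray(y, dtype=float))
    dcov2 = (a * b).mean()
    dvx = (a * a).mean()
    dvy = (b * b).mean()
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvx * dvy)))


def dcov(ds: ExpressionDataset) -> ScoreMatrix:
    """Distance correlation per pair; detects non-linear dependence."""
    _check(ds, 4, "dcov")
    x, y = ds.cause_matrix(), ds.effect_matrix()
    # cache the centred distance matrix of every miRNA; stream over mRNAs
    a_list = [_centred_distances(x[:, j]) for j in range(x.shape[1])]
    dvx = np.array([(a * a).mean() for a in a_list])
    if (dvx <= 0).any():
        warnings.warn("dcov: constant miRNA scored 0")
    out = np.zeros((y.shape[1], x.shape[1]))
    for i in range(y.shape[1]):
        b = _centred_distances(y[:, i])
        dvy = (b * b).mean()
        if dvy <= 0:
            warnings.warn(f"dcov: constant mRNA {ds.mrna_names[i]!r} scored 0")
            continue
        for j in range(x.shape[1]):
            if dvx[j] <= 0:
                continue
            dcov2 = (a_list[j] * b).mean()
            out[i, j] = np.sqrt(max(dcov2, 0.0) / np.sqrt(dvx[j] * dvy))
    return _matrix(ds, out, "Dcov", Ordering.DESC_VALUE)


# ---------------------------------------------------------------------------
# Hoeffding's D


def hoeffding_d(x: np.ndarray, y: np.ndarray) -> float:
    """Hoeffding's D statistic for one pair (classical tie convention).

    Uses mid-ranks R, S of x and y and the bivariate rank
    Q_i = 1 + #{j : x_j < x_i and y_j < y_i} with ties in one coordinate
    counted 1/2 and ties in both counted 1/4.  Requires n >= 5.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 5:
        raise MirankError("Hoeffding's D requires at least 5 samples")
    r = stats.rankdata(x)
    s = stats.rankdata(y)
    lx = (x[None, :] < x[:, None]).astype(float)
    ex = (x[None, :] == x[:, None]).astype(float)
    ly = (y[None, :] < y[:, None]).astype(float)
    ey = (y[None, :] == y[:, None]).astype(float)
    both_less = lx * ly
    one_tie = lx * ey + ex * ly
    both_tie = ex * ey
    np.fill_diagonal(both_tie, 0.0)
    q = 1.0 + both_less.sum(axis=1) + 0.5 * one_tie.sum(axis=1) \
        + 0.25 * both_tie.sum(axis=1)
    d1 = np.sum((q - 1) * (q - 2))
    d2 = np.sum((r - 1) * (r - 2) * (s - 1) * (s - 2))
    d3 = np.sum((r - 2) * (s - 2) * (q - 1))
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return float(30.0 * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3)
                 / denom)


def hoeffding(ds: ExpressionDataset) -> ScoreMatrix:
    """Hoeffding's D dependence measure per pair."""
    _check(ds, 5, "hoeffding")
    x, y = ds.cause_matrix(), ds.effect_matrix()
    out = np.zeros((y.shape[1], x.shape[1]))
    for j in range(x.shape[1]):
        for i in range(y.shape[1]):
            out[i, j] = hoeffding_d(x[:, j], y[:, i])
    return _matrix(ds, out, "Hoeffding", Ordering.DESC_VALUE)


# ---------------------------------------------------------------------------
# randomised dependence coefficient


def _copula(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v) / len(v)


def rdc_pair(
    x: np.ndarray,
    y: np.ndarray,
    n_features: int = 20,
    scale: float = 1.0 / 6.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Randomised dependence coefficient for one pair.

    Each variable is mapped to its empirical copula, augmented with an
    intercept and projected through ``n_features`` random sinusoidal
    features sin(w.u + b) with w entries drawn Normal(0, scale^2) and
    b ~ Uniform(0, 2*pi); the score is the largest canonical correlation
    between the two feature blocks, clipped to [0, 1].
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(x)
    u = np.column_stack([_copula(np.asarray(x, dtype=float)), np.ones(n)])
    v = np.column_stack([_copula(np.asarray(y, dtype=float)), np.ones(n)])
    wx = rng.normal(0.0, scale, size=(2, n_features))
    bx = rng.uniform(0.0, 2 * np.pi, size=n_features)
    wy = rng.normal(0.0, scale, size=(2, n_features))
    by = rng.uniform(0.0, 2 * np.pi, size=n_features)
    fx = np.sin(u @ wx + bx)
    fy = np.sin(v @ wy + by)
    return _max_canonical_correlation(fx, fy)


def _max_canonical_correlation(fx: np.ndarray, fy: np.ndarray) -> float:
    fx = fx - fx.mean(axis=0)
    fy = fy - fy.mean(axis=0)
    n = fx.shape[0]
    cxx = fx.T @ fx / n
    cyy = fy.T @ fy / n
    cxy = fx.T @ fy / n
    eps = 1e-8
    # the sinusoidal features are typically near-collinear, so the block
    # covariances are routinely singular; ridge-regularise before solving
    cxx = cxx + eps * np.eye(cxx.shape[0])
    cyy = cyy + eps * np.eye(cyy.shape[0])
    m = np.linalg.solve(cxx, cxy) @ np.linalg.solve(cyy, cxy.T)
    eig = np.linalg.eigvals(m)
    lam = float(np.max(eig.real))
    return float(np.sqrt(np.clip(lam, 0.0, 1.0)))


def rdc(
    ds: ExpressionDataset,
    n_features: int = 20,
    scale: float = 1.0 / 6.0,
    seed: int = 0,
) -> ScoreMatrix:
    """Randomised dependence coefficient per pair.

    The random projections for pair (miRNA j, mRNA i) are drawn from a
    generator seeded deterministically from (seed, j, i), so the matrix
    is reproducible and invariant to sample-row permutations (copula
    ranks are permutation-equivariant and seeds do not depend on rows).
    """
    _check(ds, 10, "rdc")
    x, y = ds.cause_matrix(), ds.effect_matrix()
    out = np.zeros((y.shape[1], x.shape[1]))
    for j in range(x.shape[1]):
        for i in range(y.shape[1]):
            rng = np.random.default_rng(np.random.SeedSequence([seed, j, i]))
            out[i, j] = rdc_pair(x[:, j], y[:, i], n_features, scale, rng)
    return _matrix(ds, out, "RDC", Ordering.DESC_VALUE)


# ---------------------------------------------------------------------------
# mutual information


def _equal_frequency_bins(v: np.ndarray, bins: int) -> np.ndarray:
    """Assign each value to one of ``bins`` equal-frequency bins.

    Ordinal ranks split ties deterministically by sample order, keeping
    bin occupancies as equal as possible.
    """
    n = len(v)
    ranks = stats.rankdata(v, method="ordinal") - 1  # 0..n-1
    return (ranks * bins) // n


def mutual_information(
    ds: ExpressionDataset, bins: int | str = "auto"
) -> ScoreMatrix:
    """Plug-in mutual information (bits) on equal-frequency bins.

    ``bins="auto"`` uses ceil(n^(1/3)) bins.
    """
    _check(ds, 10, "mutual_information")
    n = ds.n_samples
    if bins == "auto":
        nbins = int(np.ceil(n ** (1.0 / 3.0)))
    else:
        nbins = int(bins)
    if nbins < 2:
        raise MirankError("mutual_information needs at least 2 bins")
    x, y = ds.cause_matrix(), ds.effect_matrix()
    bx = np.stack([_equal_frequency_bins(x[:, j], nbins)
                   for j in range(x.shape[1])])
    by = np.stack([_equal_frequency_bins(y[:, i], nbins)
                   for i in range(y.shape[1])])
    out = np.zeros((y.shape[1], x.shape[1]))
    for j in range(x.shape[1]):
        for i in range(y.shape[1]):
            out[i, j] = _plugin_mi(bx[j], by[i], nbins)
    return _matrix(ds, out, "MI", Ordering.DESC_VALUE)


def _plugin_mi(a: np.ndarray, b: np.ndarray, nbins: int) -> float:
    n = len(a)
    joint = np.zeros((nbins, nbins))
    np.add.at(joint, (a, b), 1.0)
    joint /= n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    mi = np.sum(joint[nz] * np.log2(joint[nz] /
                                    (np.outer(pa, pb)[nz])))
    return float(max(mi, 0.0))


# ---------------------------------------------------------------------------
# pseudo-knockout Z-score


def zscore(ds: ExpressionDataset) -> ScoreMatrix:
    """Pseudo-knockout Z-score.

    The sample in which a miRNA attains its minimum expression is treated
    as a stand-in for a knockout of that miRNA (first occurrence on
    ties); the score of an mRNA is the absolute deviation of its
    expression in that sample from its mean, in units of its unbiased
    standard deviation.  Knockdown of a repressor may move targets either
    way, so the absolute deviation captures both signs.
    """
    _check(ds, 3, "zscore")
    x, y = ds.cause_matrix(), ds.effect_matrix()
    s_star = np.argmin(x, axis=0)  # first minimum per miRNA
    mean_y = y.mean(axis=0)
    sd_y = y.std(axis=0, ddof=1)
    flat = sd_y == 0
    if flat.any():
        warnings.warn("zscore: constant mRNAs scored 0")
    safe_sd = np.where(flat, 1.0, sd_y)
    dev = np.abs(y[s_star, :] - mean_y[None, :]) / safe_sd[None, :]
    dev[:, flat] = 0.0
    return _matrix(ds, dev.T, "Zscore", Ordering.DESC_VALUE)


#: name -> callable registry for the CLI and pipelines
PAIRWISE_METHODS = {
    "pearson": pearson,
    "spearman": spearman,
    "kendall": kendall,
    "dcov": dcov,
    "hoeffding": hoeffding,
    "rdc": rdc,
    "mi": mutual_information,
    "zscore": zscore,
}
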
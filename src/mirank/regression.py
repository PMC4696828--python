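"""Penalised-regression scoring: Lasso and elastic net.

Each mRNA is regressed on all miRNAs simultaneously; the (standardised)
coefficient of a miRNA is its association score with that mRNA.  The
objective for response y and predictor matrix X (n samples) is

    min_{b0, b}  (1/2n) ||y - b0 - X b||^2
                 + lambda [ l1_ratio ||b||_1 + (1 - l1_ratio)/2 ||b||_2^2 ]

so ``l1_ratio = 1`` is the Lasso.  Because coefficients are used only for
ranking, predictors are standardised internally and coefficients are
reported on the standardised scale, making scores comparable across
miRNAs.  The most negative coefficients rank first (down-regulation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, enet_path

from .datatypes import ExpressionDataset, MirankError, Ordering, ScoreMatrix

__all__ = ["penalized_scores", "lasso", "elastic_net", "cv_folds"]


def _standardise_columns(arr: np.ndarray) -> np.ndarray:
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (arr - mean) / sd


def cv_folds(n: int, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic k-fold split: sample position mod k after a seeded shuffle."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[perm] = np.arange(n) % folds
    out = []
    for f in range(folds):
        test = np.flatnonzero(assignment == f)
        train = np.flatnonzero(assignment != f)
        out.append((train, test))
    return out


def _lambda_grid(x: np.ndarray, y: np.ndarray, l1_ratio: float,
                 n_lambdas: int = 50, eps: float = 1e-3) -> np.ndarray:
    """Log-spaced grid from the smallest all-zero lambda downwards."""
    n = x.shape[0]
    lam_max = np.max(np.abs(x.T @ (y - y.mean(axis=0)))) / (n * max(l1_ratio, 1e-3))
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * eps, n_lambdas)


def _fit_one(x: np.ndarray, y: np.ndarray, lam: float, l1_ratio: float
             ) -> np.ndarray:
    if lam == 0:
        xc = np.column_stack([np.ones(len(y)), x])
        beta, *_ = np.linalg.lstsq(xc, y, rcond=None)
        return beta[1:]
    model = ElasticNet(alpha=lam, l1_ratio=l1_ratio, fit_intercept=True,
                       max_iter=20000, tol=1e-8)
    model.fit(x, y)
    return model.coef_


def penalized_scores(
    ds: ExpressionDataset,
    l1_ratio: float = 0.5,
    lambda_rule: dict | None = None,
    seed: int = 0,
    n_lambdas: int = 50,
    label: str | None = None,
) -> ScoreMatrix:
    """Elastic-net coefficients of every mRNA on all miRNAs.

    ``lambda_rule`` is ``{"fixed": lam}`` or ``{"cv": k}`` (k-fold
    cross-validated minimum mean squared error over a log-spaced grid,
    with a deterministic seeded fold assignment).  Default: 5-fold CV.
    """
    if ds.has_missing():
        raise MirankError("penalized_scores: dataset contains missing values")
    if ds.n_samples < 10:
        raise MirankError("penalized_scores needs >= 10 samples")
    if not (0 < l1_ratio <= 1):
        raise MirankError("l1_ratio must lie in (0, 1]")
    if lambda_rule is None:
        lambda_rule = {"cv": 5}

    x = _standardise_columns(ds.cause_matrix())
    ymat = ds.effect_matrix()
    n_mrna = ymat.shape[1]
    out = np.zeros((n_mrna, x.shape[1]))

    if "fixed" in lambda_rule:
        lam = float(lambda_rule["fixed"])
        if lam < 0:
            raise MirankError("lambda must be non-negative")
        for i in range(n_mrna):
            out[i] = _fit_one(x, ymat[:, i], lam, l1_ratio)
    elif "cv" in lambda_rule:
        folds = int(lambda_rule["cv"])
        if folds < 2:
            raise MirankError("cv folds must be >= 2")
        splits = cv_folds(ds.n_samples, folds, seed)
        grid = _lambda_grid(x, ymat, l1_ratio, n_lambdas)
        for i in range(n_mrna):
            y = ymat[:, i]
            mse = np.zeros(len(grid))
            for train, test in splits:
                xm = x[train].mean(axis=0)
                ym = y[train].mean()
                _, coefs, _ = enet_path(
                    x[train] - xm, y[train] - ym,
                    alphas=grid, l1_ratio=l1_ratio, tol=1e-6,
                )
                pred = (x[test] - xm) @ coefs + ym  # (n_test, n_alphas)
                mse += ((pred - y[test][:, None]) ** 2).sum(axis=0)
            lam_best = grid[int(np.argmin(mse))]
            out[i] = _fit_one(x, y, lam_best, l1_ratio)
    else:
        raise MirankError("lambda_rule must contain 'fixed' or 'cv'")

    name = label or ("Lasso" if l1_ratio == 1 else "Elastic")
    df = pd.DataFrame(out, index=ds.mrna_names, columns=ds.mirna_names)
    return ScoreMatrix(df, name, Ordering.ASC_SIGNED)


def lasso(ds: ExpressionDataset, lambda_rule: dict | None = None,
          seed: int = 0) -> ScoreMatrix:
    """Lasso scoring (``l1_ratio = 1``)."""
    return penalized_scores(ds, l1_ratio=1.0, lambda_rule=lambda_rule,
                            seed=seed, label="Lasso")


def elastic_net(ds: ExpressionDataset, l1_ratio: float = 0.5,
                lambda_rule: dict | None = None, seed: int = 0) -> ScoreMatrix:
    """Elastic-net scoring (default ``l1_ratio = 0.5``)."""
    return penalized_scores(ds, l1_ratio=l1_ratio, lambda_rule=lambda_rule,
                            seed=seed, label="Elastic")
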
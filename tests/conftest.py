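from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirank.datatypes import ExpressionDataset


def make_dataset(
    x: np.ndarray,
    y: np.ndarray,
    mirna_names: list[str] | None = None,
    mrna_names: list[str] | None = None,
) -> ExpressionDataset:
    """Build a dataset from miRNA (n x c) and mRNA (n x e) arrays."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1 and y.shape[0] != 1:
        x = x.T
    if y.shape[0] == 1 and y.shape[1] > 1 and x.shape[0] != 1:
        y = y.T
    c, e = x.shape[1], y.shape[1]
    mirna_names = mirna_names or [f"miR-{j + 1}" for j in range(c)]
    mrna_names = mrna_names or [f"G{i + 1}" for i in range(e)]
    df = pd.DataFrame(np.hstack([x, y]), columns=mirna_names + mrna_names)
    return ExpressionDataset(df, list(range(c)), list(range(c, c + e)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset(rng) -> ExpressionDataset:
    """5 miRNAs, 8 mRNAs, 40 samples of independent Gaussian noise."""
    return make_dataset(
        rng.standard_normal((40, 5)), rng.standard_normal((40, 8)))
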
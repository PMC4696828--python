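"""Synthetic matched miRNA+mRNA expression data with planted regulation.

The generator emulates the shape of real matched-profile studies so the
whole pipeline (scoring, aggregation, masking, validation) runs without
any downloads: miRNA expressions are iid standard Normal; a sampled edge
set of miRNA -> mRNA regulations (at most ``regulator_cap`` regulators
per mRNA) drives regulated mRNAs through a linear model with negative
coefficients — miRNAs predominantly down-regulate their targets — plus
Gaussian noise, with an optional fraction of monotone-decreasing cubic
(variance-matched) links for testing non-linear detectors.  A matching
confirmed-interaction ground truth (the planted edges) and a
perturbation table (over-expression log2 fold-changes) are produced.

Defaults mirror the benchmark conditions used throughout the test suite:
300 samples, 20 miRNAs, 500 mRNAs, 100 edges with effect sizes in
[-1.0, -0.6] and unit noise — a signal-to-noise regime where pairwise
correlation is clearly detectable but not trivial.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionDataset,
    GroundTruth,
    MirankError,
    PerturbationTable,
)

__all__ = ["SynthConfig", "generate", "write_synthetic"]


@dataclass
class SynthConfig:
    """Study-design parameters of the synthetic generator.

    ``beta_range`` is (lo, hi) with lo <= hi < 0: regulation strengths on
    the standardised log2-expression scale.  ``delta`` is the simulated
    over-expression shift (in miRNA standard deviations) used to derive
    perturbation log2 fold-changes.
    """

    n_samples: int = 300
    n_mirna: int = 20
    n_mrna: int = 500
    n_edges: int = 100
    beta_range: tuple[float, float] = (-1.0, -0.6)
    noise_sd: float = 1.0
    nonlinear_fraction: float = 0.0
    regulator_cap: int = 3
    delta: float = 2.0
    allow_positive: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.beta_range
        if not self.allow_positive and not (lo <= hi < 0):
            raise MirankError("beta_range must satisfy lo <= hi < 0")
        if self.noise_sd <= 0:
            raise MirankError("noise_sd must be positive")
        if not (0 <= self.nonlinear_fraction <= 1):
            raise MirankError("nonlinear_fraction must lie in [0, 1]")
        if self.n_edges > self.n_mirna * self.n_mrna:
            raise MirankError("more edges than miRNA x mRNA pairs")
        if self.n_edges > self.regulator_cap * self.n_mrna:
            raise MirankError(
                "edge count infeasible under the per-mRNA regulator cap")


def _sample_edges(cfg: SynthConfig, rng: np.random.Generator
                  ) -> list[tuple[int, int]]:
    """Sample edges uniformly without replacement under the regulator cap."""
    edges: set[tuple[int, int]] = set()
    reg_count = np.zeros(cfg.n_mrna, dtype=int)
    attempts = 0
    while len(edges) < cfg.n_edges:
        attempts += 1
        if attempts > 1000 * cfg.n_edges + 1000:
            raise MirankError("could not place edges under the regulator cap")
        j = int(rng.integers(cfg.n_mirna))
        i = int(rng.integers(cfg.n_mrna))
        if (j, i) in edges or reg_count[i] >= cfg.regulator_cap:
            continue
        edges.add((j, i))
        reg_count[i] += 1
    return sorted(edges)


def generate(
    cfg: SynthConfig,
) -> tuple[ExpressionDataset, GroundTruth, PerturbationTable]:
    """Generate a dataset, its planted ground truth and a perturbation table.

    Perturbation LFCs emulate a miRNA inhibition assay: removing a
    repressor de-represses its targets, so each planted edge records
    lfc = -beta * delta + Normal(0, 0.1) (positive for the default
    negative betas), and an equal number of random non-edges records
    lfc ~ Normal(0, 0.3).  With |beta| >= 0.6 and delta = 2 the edge
    LFCs clear the conventional |LFC| > 1 target threshold.
    """
    rng = np.random.default_rng(cfg.seed)
    mirna_names = [f"miR-{j + 1}" for j in range(cfg.n_mirna)]
    mrna_names = [f"GENE{i + 1}" for i in range(cfg.n_mrna)]

    x = rng.standard_normal((cfg.n_samples, cfg.n_mirna))

    edges = _sample_edges(cfg, rng)
    lo, hi = cfg.beta_range
    betas = {e: float(rng.uniform(lo, hi)) for e in edges}

    regulators: dict[int, list[int]] = {}
    for j, i in edges:
        regulators.setdefault(i, []).append(j)

    regulated = sorted(regulators)
    n_nonlinear = int(round(cfg.nonlinear_fraction * len(regulated)))
    nonlinear_set = set(
        rng.choice(regulated, size=n_nonlinear, replace=False).tolist()
    ) if n_nonlinear else set()

    y = np.empty((cfg.n_samples, cfg.n_mrna))
    for i in range(cfg.n_mrna):
        if i not in regulators:
            y[:, i] = rng.standard_normal(cfg.n_samples)
            continue
        eta = np.zeros(cfg.n_samples)
        for j in regulators[i]:
            eta += betas[(j, i)] * x[:, j]
        if i in nonlinear_set:
            # monotone-decreasing cubic link, rescaled to match the
            # linear predictor's spread so signal-to-noise is preserved
            cube = eta**3
            sd_c = cube.std()
            if sd_c > 0:
                eta = cube * (eta.std() / sd_c)
        y[:, i] = eta + rng.normal(0.0, cfg.noise_sd, cfg.n_samples)

    data = pd.DataFrame(
        np.hstack([x, y]),
        index=[f"S{s + 1}" for s in range(cfg.n_samples)],
        columns=mirna_names + mrna_names,
    )
    ds = ExpressionDataset(
        data,
        cause_idx=list(range(cfg.n_mirna)),
        effect_idx=list(range(cfg.n_mirna, cfg.n_mirna + cfg.n_mrna)),
    )

    truth = GroundTruth(
        {(mirna_names[j], mrna_names[i]) for j, i in edges},
        provenance="synthetic planted edges",
    )

    # inhibition of miRNA j by delta sd de-represses each target by
    # -beta * delta; non-edges get small off-target noise
    records: list[tuple[str, str, float]] = []
    for j, i in edges:
        lfc = -betas[(j, i)] * cfg.delta + rng.normal(0.0, 0.1)
        records.append((mirna_names[j], mrna_names[i], lfc))
    non_edges_needed = len(edges)
    edge_set = set(edges)
    placed = 0
    guard = 0
    seen: set[tuple[int, int]] = set()
    while placed < non_edges_needed:
        guard += 1
        if guard > 1000 * non_edges_needed + 1000:
            break
        j = int(rng.integers(cfg.n_mirna))
        i = int(rng.integers(cfg.n_mrna))
        if (j, i) in edge_set or (j, i) in seen:
            continue
        seen.add((j, i))
        records.append(
            (mirna_names[j], mrna_names[i], float(rng.normal(0.0, 0.3))))
        placed += 1
    pert = PerturbationTable.from_records(records)

    return ds, truth, pert


def write_synthetic(cfg: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the three CSVs plus a manifest JSON."""
    from . import dataio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds, truth, pert = generate(cfg)
    paths = {
        "expression": outdir / "expression.csv",
        "ground_truth": outdir / "ground_truth.csv",
        "perturbation": outdir / "perturbation.csv",
        "manifest": outdir / "manifest.json",
    }
    dataio.write_expression(ds, paths["expression"])
    dataio.write_ground_truth(truth, paths["ground_truth"])
    dataio.write_perturbation(pert, paths["perturbation"])
    manifest = asdict(cfg)
    manifest["beta_range"] = list(cfg.beta_range)
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
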
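"""Validation of predicted rankings against ground truths, and method
comparison by ranking scores.

Two kinds of ground truth are supported: experimentally confirmed
(miRNA, mRNA) interaction pairs, and miRNA perturbation (transfection)
experiments, where a gene counts as a target of a miRNA when the
absolute log2 fold-change strictly exceeds a threshold (default 1.0).

Method comparison follows a Borda-style ranking-score procedure: keep
only the miRNAs for which every method predicted at least one confirmed
target in its top-k list; per retained miRNA, rank the methods by
confirmed count (descending, ties = mean rank) and award M - rank + 1
points; a method's ranking score is its point total over the retained
miRNAs.  Higher is better.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GroundTruth, MirankError, PerturbationTable
from .ensemble import InteractionRanking

__all__ = [
    "ValidationReport",
    "extract_topk",
    "validate_confirmed",
    "validate_perturbation",
    "validate_all",
    "compare_methods",
]


@dataclass
class ValidationReport:
    """Top-k validation result for one method and one ground-truth type."""

    method_label: str
    ground_truth_type: str
    k: int
    per_mirna: dict[str, dict] = field(default_factory=dict)
    uncovered_mirnas: list[str] = field(default_factory=list)

    @property
    def total_confirmed(self) -> int:
        return sum(d["confirmed_count"] for d in self.per_mirna.values())

    def confirmed_counts(self) -> dict[str, int]:
        return {m: d["confirmed_count"] for m, d in self.per_mirna.items()}

    def to_dict(self) -> dict:
        return {
            "method": self.method_label,
            "ground_truth": self.ground_truth_type,
            "k": self.k,
            "total_confirmed": self.total_confirmed,
            "uncovered_mirnas": list(self.uncovered_mirnas),
            "per_mirna": self.per_mirna,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def extract_topk(
    ranking: InteractionRanking, k: int
) -> list[tuple[str, str, float]]:
    """The k best-ranked (miRNA, mRNA, score) triples per miRNA.

    Ties at the k boundary break by mRNA name (lexicographically smaller
    included), so the output always has length k x n_miRNA.
    """
    if not (1 <= k <= ranking.n_mrna):
        raise MirankError(f"k={k} outside 1..{ranking.n_mrna}")
    out: list[tuple[str, str, float]] = []
    for mirna in ranking.mirna_names:
        for g, score, _rank in ranking.ordered_targets(mirna)[:k]:
            out.append((mirna, g, score))
    return out


def validate_confirmed(
    ranking: InteractionRanking, k: int, truth: GroundTruth,
) -> ValidationReport:
    """Count confirmed pairs in each miRNA's top-k predictions."""
    report = ValidationReport(
        method_label=ranking.method_label,
        ground_truth_type=truth.provenance or "confirmed",
        k=k,
    )
    top = extract_topk(ranking, k)
    by_mirna: dict[str, list[str]] = {m: [] for m in ranking.mirna_names}
    for mirna, g, _ in top:
        by_mirna[mirna].append(g)
    for mirna, genes in by_mirna.items():
        confirmed = sorted(g for g in genes if (mirna, g) in truth.pairs)
        report.per_mirna[mirna] = {
            "predicted": genes,
            "confirmed": confirmed,
            "confirmed_count": len(confirmed),
        }
    return report


def validate_perturbation(
    ranking: InteractionRanking,
    k: int,
    pert: PerturbationTable,
    lfc_threshold: float = 1.0,
) -> ValidationReport:
    """Validate against perturbation-derived targets (|LFC| > threshold).

    The inequality is strict: a gene at exactly the threshold is not a
    target.  miRNAs absent from the perturbation table contribute zero
    confirmed counts and are listed as uncovered.
    """
    truth = pert.derive_truth(lfc_threshold)
    report = validate_confirmed(ranking, k, truth)
    report.ground_truth_type = "perturbation"
    covered = pert.mirnas()
    report.uncovered_mirnas = sorted(
        m for m in ranking.mirna_names if m not in covered)
    return report


def validate_all(
    ranking: InteractionRanking,
    k: int,
    truth: GroundTruth | None = None,
    pert: PerturbationTable | None = None,
    lfc_threshold: float = 1.0,
) -> dict[str, ValidationReport]:
    """Validate one ranking against every available ground-truth type."""
    if truth is None and pert is None:
        raise MirankError("need a confirmed ground truth or a perturbation table")
    out: dict[str, ValidationReport] = {}
    if truth is not None:
        out["confirmed"] = validate_confirmed(ranking, k, truth)
    if pert is not None:
        out["perturbation"] = validate_perturbation(
            ranking, k, pert, lfc_threshold)
    return out


def compare_methods(
    reports_by_method: dict[str, ValidationReport],
) -> dict:
    """Borda-style ranking scores for a set of methods, one truth type.

    All reports must share the miRNA set and k.  Only miRNAs with at
    least one confirmed target under every method are retained; per
    retained miRNA methods are ranked by confirmed count (descending,
    mean-rank ties) and scored M - rank + 1; scores are summed over the
    retained miRNAs.
    """
    if not reports_by_method:
        raise MirankError("no reports supplied")
    methods = sorted(reports_by_method)
    first = reports_by_method[methods[0]]
    mirnas = sorted(first.per_mirna)
    for m in methods[1:]:
        rep = reports_by_method[m]
        if sorted(rep.per_mirna) != mirnas or rep.k != first.k:
            raise MirankError("reports must share the miRNA set and k")

    counts = pd.DataFrame(
        {m: reports_by_method[m].confirmed_counts() for m in methods}
    ).loc[mirnas, methods]
    retained = [mi for mi in mirnas if (counts.loc[mi] >= 1).all()]

    n_methods = len(methods)
    scores = {m: 0.0 for m in methods}
    for mi in retained:
        # rank 1 = highest confirmed count; ties share the mean rank
        ranks = stats.rankdata(-counts.loc[mi].to_numpy(), method="average")
        for m, r in zip(methods, ranks):
            scores[m] += n_methods - r + 1
    return {
        "scores": scores,
        "retained_mirnas": retained,
        "k": first.k,
        "notice": None if retained else
        "no miRNA has a confirmed target under every method",
    }
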
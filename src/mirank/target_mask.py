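"""Restricting score matrices to sequence-supported miRNA-mRNA pairs.

Expression-based predictions can be intersected with sequence-based
target information (e.g. TargetScan exports or CLIP-derived pair lists):
pairs without binding support are assigned the ordering-specific null
score, so they can never enter a top-k list ahead of a supported pair
with a real score.  The mask is applied after scoring (filtering the
predictions), not before (it does not alter the regressions).
"""

from __future__ import annotations

from .datatypes import GroundTruth, MirankError, Ordering, ScoreMatrix

__all__ = ["apply_target_mask", "null_score"]


def null_score(ordering: Ordering, n_mrna: int) -> float:
    """Worst-possible score under an ordering convention.

    For signed orderings the null is 0, which places unsupported pairs
    behind every negative (down-regulation) score; for magnitude
    orderings 0 is the weakest dependence; for rank matrices the null is
    the maximal rank (the number of mRNAs).
    """
    if ordering is Ordering.ASC_RANK:
        return float(n_mrna)
    return 0.0


def apply_target_mask(
    sm: ScoreMatrix,
    binding: GroundTruth,
    mode: str = "null",
) -> ScoreMatrix:
    """Null out (or drop) pairs unsupported by sequence target information.

    ``binding`` holds (miRNA, mRNA) pairs in the same name space as the
    matrix.  ``mode="null"`` replaces unsupported scores by the
    ordering-specific null value; ``mode="drop"`` additionally marks them
    by the null value — rankings built from a dropped matrix via the
    ensemble module place them last (identical effect, kept for API
    symmetry with tools that remove rows).
    """
    if len(binding) == 0:
        raise MirankError("empty binding list would mask every pair")
    if mode not in ("null", "drop"):
        raise MirankError(f"unknown mask mode {mode!r}")
    out = sm.values.copy()
    null = null_score(sm.ordering, sm.n_mrna)
    supported = binding.pairs
    for mirna in out.columns:
        col_support = {g for m, g in supported if m == str(mirna)}
        unsupported = [g for g in out.index if str(g) not in col_support]
        out.loc[unsupported, mirna] = null
    return ScoreMatrix(out, sm.method_label + "+mask", sm.ordering)
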
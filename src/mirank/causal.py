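"""Causal-effect scoring via PC-stable structure learning and IDA.

The pipeline learns a completed partially directed acyclic graph (CPDAG)
over all features — the Markov-equivalence-class representation returned
by the PC algorithm — using the order-independent "stable" variant with
Gaussian (Fisher-z partial correlation) conditional-independence tests.
For a given miRNA x and mRNA y, IDA (intervention calculus when the DAG
is absent) enumerates the valid parent sets of x that are consistent
with some DAG in the equivalence class and, for each, estimates the
causal effect of x on y as the coefficient of x in the least-squares
regression of y on {x} union parents.  The multiset of effects is
summarised by its minimum-absolute-value element (sign preserved), a
conservative lower bound on the magnitude of the effect.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionDataset, MirankError, Ordering, ScoreMatrix

__all__ = ["Cpdag", "CiTestConfig", "pc_stable", "ida_effects", "ida_scores",
           "fisher_z_pvalue", "write_cpdag"]


@dataclass
class CiTestConfig:
    """Gaussian conditional-independence test settings.

    ``alpha`` is the significance level of the Fisher-z test (default
    0.01); ``max_cond_size`` caps the conditioning-set size (None =
    unlimited) — PC is exponential in conditioning size, so a small cap
    keeps thousand-feature datasets tractable.
    """

    alpha: float = 0.01
    max_cond_size: int | None = 3

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise MirankError("alpha must lie strictly between 0 and 1")


@dataclass
class Cpdag:
    """CPDAG with explicit directed and undirected edge sets."""

    nodes: list[str]
    directed_edges: set[tuple[str, str]] = field(default_factory=set)
    undirected_edges: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.directed_edges = set(self.directed_edges)
        self.undirected_edges = {frozenset(e) for e in self.undirected_edges}
        for a, b in self.directed_edges:
            if a == b:
                raise MirankError("self-loop in directed edges")
            if (b, a) in self.directed_edges:
                raise MirankError(f"both orientations present for {a}--{b}")
            if frozenset((a, b)) in self.undirected_edges:
                raise MirankError(f"edge {a}--{b} both directed and undirected")
        for e in self.undirected_edges:
            if len(e) != 2:
                raise MirankError("undirected self-loop")

    def adjacent(self, a: str, b: str) -> bool:
        return ((a, b) in self.directed_edges
                or (b, a) in self.directed_edges
                or frozenset((a, b)) in self.undirected_edges)

    def parents(self, v: str) -> set[str]:
        return {a for a, b in self.directed_edges if b == v}

    def children(self, v: str) -> set[str]:
        return {b for a, b in self.directed_edges if a == v}

    def undirected_neighbours(self, v: str) -> set[str]:
        return {next(iter(e - {v})) for e in self.undirected_edges if v in e}

    def neighbours(self, v: str) -> set[str]:
        return self.parents(v) | self.children(v) | self.undirected_neighbours(v)

    def skeleton_components(self) -> dict[str, int]:
        """Connected-component label of each node in the skeleton."""
        label = {v: -1 for v in self.nodes}
        comp = 0
        for start in self.nodes:
            if label[start] != -1:
                continue
            stack = [start]
            label[start] = comp
            while stack:
                v = stack.pop()
                for w in self.neighbours(v):
                    if label[w] == -1:
                        label[w] = comp
                        stack.append(w)
            comp += 1
        return label

    def n_edges(self) -> int:
        return len(self.directed_edges) + len(self.undirected_edges)


# ---------------------------------------------------------------------------
# conditional-independence testing


def fisher_z_pvalue(corr: np.ndarray, n: int, i: int, j: int,
                    cond: tuple[int, ...]) -> float:
    """Two-sided p-value of the Fisher-z partial-correlation test.

    The partial correlation of features i and j given ``cond`` comes from
    inverting the corresponding submatrix of the correlation matrix; the
    statistic is z = atanh(rho) * sqrt(n - |cond| - 3), referred to a
    standard Normal.
    """
    df_adj = n - len(cond) - 3
    if df_adj <= 0:
        raise MirankError(
            f"Fisher-z undefined: n={n} too small for conditioning size "
            f"{len(cond)}"
        )
    if not cond:
        rho = corr[i, j]
    else:
        idx = [i, j, *cond]
        sub = corr[np.ix_(idx, idx)]
        try:
            prec = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            prec = np.linalg.pinv(sub)
        denom = np.sqrt(prec[0, 0] * prec[1, 1])
        rho = -prec[0, 1] / denom if denom > 0 else 0.0
    rho = float(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    z = 0.5 * np.log((1 + rho) / (1 - rho)) * np.sqrt(df_adj)
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# PC-stable skeleton + orientation


def pc_stable(ds: ExpressionDataset, cfg: CiTestConfig | None = None) -> Cpdag:
    """Learn a CPDAG with the order-independent PC-stable algorithm.

    At each level the neighbour sets are frozen before any edge test, so
    the output does not depend on the order in which features appear.
    Separating sets are recorded; v-structures a -> c <- b are oriented
    whenever c is outside sepset(a, b), conflicting v-structure
    orientations leave the edge undirected, and Meek rules are applied
    to a fixed point.
    """
    if cfg is None:
        cfg = CiTestConfig()
    if ds.has_missing():
        raise MirankError("pc_stable: dataset contains missing values")
    if ds.n_samples < 10:
        raise MirankError("pc_stable needs >= 10 samples")

    names = ds.feature_names
    arr = ds.data.to_numpy(dtype=float)
    arr = (arr - arr.mean(axis=0)) / np.where(
        arr.std(axis=0, ddof=1) == 0, 1.0, arr.std(axis=0, ddof=1))
    n, p = arr.shape
    corr = np.corrcoef(arr, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)

    adj = [set(range(p)) - {v} for v in range(p)]
    sepset: dict[frozenset[int], tuple[int, ...]] = {}

    level = 0
    while True:
        if cfg.max_cond_size is not None and level > cfg.max_cond_size:
            break
        if max((len(a) for a in adj), default=0) - 1 < level:
            break
        frozen = [set(a) for a in adj]  # stable variant: freeze per level
        for a in range(p):
            for b in sorted(frozen[a]):
                if b not in adj[a]:
                    continue
                candidates = frozen[a] - {b}
                if len(candidates) < level:
                    continue
                removed = False
                for s in itertools.combinations(sorted(candidates), level):
                    pval = fisher_z_pvalue(corr, n, a, b, s)
                    if pval > cfg.alpha:
                        adj[a].discard(b)
                        adj[b].discard(a)
                        sepset[frozenset((a, b))] = s
                        removed = True
                        break
                if removed:
                    continue
        level += 1

    # orient v-structures: a -> c <- b for unshielded triples with
    # c outside sepset(a, b); conflicts leave edges undirected
    undirected = {frozenset((a, b)) for a in range(p) for b in adj[a] if a < b}
    votes: set[tuple[int, int]] = set()
    for c in range(p):
        nb = sorted(adj[c])
        for a, b in itertools.combinations(nb, 2):
            if b in adj[a]:
                continue  # shielded
            key = frozenset((a, b))
            if c not in sepset.get(key, ()):
                votes.add((a, c))
                votes.add((b, c))
    directed: set[tuple[int, int]] = set()
    for a, c in votes:
        if (c, a) in votes:
            continue  # conflicting orientation: stay undirected
        directed.add((a, c))
        undirected.discard(frozenset((a, c)))

    directed, undirected = _apply_meek_rules(p, directed, undirected)

    return Cpdag(
        nodes=list(names),
        directed_edges={(names[a], names[b]) for a, b in directed},
        undirected_edges={frozenset((names[a], names[b]))
                          for e in undirected for a, b in [tuple(e)]},
    )


def _apply_meek_rules(
    p: int,
    directed: set[tuple[int, int]],
    undirected: set[frozenset[int]],
) -> tuple[set[tuple[int, int]], set[frozenset[int]]]:
    """Meek orientation rules 1-4 iterated to a fixed point."""

    def adjacent(a: int, b: int) -> bool:
        return ((a, b) in directed or (b, a) in directed
                or frozenset((a, b)) in undirected)

    def orient(a: int, b: int) -> bool:
        if (b, a) in directed:
            return False  # never flip an existing orientation
        directed.add((a, b))
        undirected.discard(frozenset((a, b)))
        return True

    changed = True
    while changed:
        changed = False
        for e in list(undirected):
            a, b = tuple(e)
            for x, y in ((a, b), (b, a)):
                # R1: z -> x, x - y, z and y non-adjacent  =>  x -> y
                if any((z, x) in directed and not adjacent(z, y)
                       for z in range(p) if z not in (x, y)):
                    if orient(x, y):
                        changed = True
                        break
                # R2: x -> z -> y and x - y  =>  x -> y
                if any((x, z) in directed and (z, y) in directed
                       for z in range(p) if z not in (x, y)):
                    if orient(x, y):
                        changed = True
                        break
                # R3: x - z1, x - z2, z1 -> y, z2 -> y, z1,z2 non-adjacent
                und_nb = [z for z in range(p) if z not in (x, y)
                          and frozenset((x, z)) in undirected]
                r3 = False
                for z1, z2 in itertools.combinations(und_nb, 2):
                    if ((z1, y) in directed and (z2, y) in directed
                            and not adjacent(z1, z2)):
                        r3 = True
                        break
                if r3 and orient(x, y):
                    changed = True
                    break
                # R4: x - z1, z1 adjacent to w, w -> z2?  Meek's fourth rule:
                # x - y oriented x -> y when x - z, z -> w, w -> y with
                # z,y non-adjacent and x,w adjacent
                r4 = False
                for z in range(p):
                    if z in (x, y) or not frozenset((x, z)) in undirected:
                        continue
                    for w in range(p):
                        if w in (x, y, z):
                            continue
                        if ((z, w) in directed and (w, y) in directed
                                and not adjacent(z, y) and adjacent(x, w)):
                            r4 = True
                            break
                    if r4:
                        break
                if r4 and orient(x, y):
                    changed = True
                    break
            if e not in undirected:
                continue
    return directed, undirected


# ---------------------------------------------------------------------------
# IDA


def _valid_parent_sets(cpdag: Cpdag, x: str) -> list[frozenset[str]]:
    """Candidate parent sets of x consistent with some DAG extension.

    Certain parents (directed into x) are always included; each subset T
    of x's undirected neighbours may additionally be oriented toward x
    provided doing so creates no new v-structure at x, i.e. every member
    of T is adjacent to every other chosen parent.
    """
    certain = cpdag.parents(x)
    und = sorted(cpdag.undirected_neighbours(x))
    out: list[frozenset[str]] = []
    for r in range(len(und) + 1):
        for t in itertools.combinations(und, r):
            tset = set(t)
            ok = True
            for u in tset:
                others = (tset - {u}) | certain
                if any(not cpdag.adjacent(u, o) for o in others):
                    ok = False
                    break
            if ok:
                out.append(frozenset(certain | tset))
    return out


def ida_effects(
    ds: ExpressionDataset, cpdag: Cpdag, mirna: str, mrna: str
) -> list[float]:
    """Multiset of possible causal effects of ``mirna`` on ``mrna``.

    One adjustment regression per valid parent set P of the miRNA: the
    effect is the coefficient of the miRNA in the regression of the mRNA
    on {miRNA} union P (0 when the mRNA is itself in P).  Rank-deficient
    regressions are dropped with a warning.
    """
    for name in (mirna, mrna):
        if name not in cpdag.nodes:
            raise MirankError(f"{name!r} not a CPDAG node")
    arr = ds.data
    effects: list[float] = []
    for pset in _valid_parent_sets(cpdag, mirna):
        if mrna in pset:
            effects.append(0.0)
            continue
        cols = [mirna, *sorted(pset)]
        xmat = np.column_stack(
            [np.ones(ds.n_samples)] + [arr[c].to_numpy(dtype=float)
                                       for c in cols]
        )
        yvec = arr[mrna].to_numpy(dtype=float)
        beta, _, rank, _ = np.linalg.lstsq(xmat, yvec, rcond=None)
        if rank < xmat.shape[1]:
            warnings.warn(
                f"ida_effects: rank-deficient adjustment set {sorted(pset)} "
                f"for {mirna} dropped"
            )
            continue
        effects.append(float(beta[1]))
    return effects


def _min_abs_summary(effects: list[float]) -> float:
    """Minimum-absolute-value element, sign preserved."""
    if not effects:
        return 0.0
    return min(effects, key=abs)


def ida_scores(
    ds: ExpressionDataset, cfg: CiTestConfig | None = None,
    cpdag: Cpdag | None = None,
) -> ScoreMatrix:
    """IDA score matrix: per pair, the minimum-absolute possible effect.

    Pairs whose mRNA lies in a different connected component of the
    CPDAG skeleton than the miRNA score exactly 0: every consistent DAG
    extension d-separates them, so the effect is 0 in all extensions.
    """
    if cpdag is None:
        cpdag = pc_stable(ds, cfg)
    comp = cpdag.skeleton_components()
    out = np.zeros((len(ds.mrna_names), len(ds.mirna_names)))
    parent_sets = {m: _valid_parent_sets(cpdag, m) for m in ds.mirna_names}
    arr = ds.data
    ones = np.ones(ds.n_samples)
    for j, mirna in enumerate(ds.mirna_names):
        psets = parent_sets[mirna]
        for i, mrna in enumerate(ds.mrna_names):
            if comp[mirna] != comp[mrna]:
                continue
            effects: list[float] = []
            for pset in psets:
                if mrna in pset:
                    effects.append(0.0)
                    continue
                cols = [mirna, *sorted(pset)]
                xmat = np.column_stack(
                    [ones] + [arr[c].to_numpy(dtype=float) for c in cols])
                yvec = arr[mrna].to_numpy(dtype=float)
                beta, _, rank, _ = np.linalg.lstsq(xmat, yvec, rcond=None)
                if rank < xmat.shape[1]:
                    continue
                effects.append(float(beta[1]))
            out[i, j] = _min_abs_summary(effects)
    df = pd.DataFrame(out, index=ds.mrna_names, columns=ds.mirna_names)
    return ScoreMatrix(df, "IDA", Ordering.ASC_SIGNED)


def write_cpdag(cpdag: Cpdag, path) -> None:
    """Edge-list CSV export: ``source,target,type``."""
    rows = [(a, b, "directed") for a, b in sorted(cpdag.directed_edges)]
    rows += [(a, b, "undirected")
             for a, b in sorted(tuple(sorted(e))
                                for e in cpdag.undirected_edges)]
    pd.DataFrame(rows, columns=["source", "target", "type"]).to_csv(
        path, index=False, lineterminator="\n"
    )
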
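"""Independent brute-force oracles used to check the implementations.

Everything here is written from the defining formulas with plain Python
loops, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pearson_brute(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx = math.sqrt(sum((v - mx) ** 2 for v in x) / (n - 1))
    sy = math.sqrt(sum((v - my) ** 2 for v in y) / (n - 1))
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)
    return cov / (sx * sy)


def midranks(v) -> list[float]:
    n = len(v)
    out = [0.0] * n
    for i in range(n):
        less = sum(1 for j in range(n) if v[j] < v[i])
        tied = sum(1 for j in range(n) if v[j] == v[i])
        out[i] = less + (tied + 1) / 2.0
    return out


def spearman_brute(x, y) -> float:
    return pearson_brute(midranks(x), midranks(y))


def kendall_taub_brute(x, y) -> float:
    n = len(x)
    nc = nd = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                nc += 1
            else:
                nd += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (nc - nd) / denom if denom > 0 else 0.0


def dcor_brute(x, y) -> float:
    n = len(x)
    a = [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]
    b = [[abs(y[i] - y[j]) for j in range(n)] for i in range(n)]

    def centre(m):
        row = [sum(r) / n for r in m]
        col = [sum(m[i][j] for i in range(n)) / n for j in range(n)]
        grand = sum(row) / n
        return [[m[i][j] - row[i] - col[j] + grand for j in range(n)]
                for i in range(n)]

    ac, bc = centre(a), centre(b)
    dcov2 = sum(ac[i][j] * bc[i][j] for i in range(n) for j in range(n)) / n**2
    dvx = sum(v * v for r in ac for v in r) / n**2
    dvy = sum(v * v for r in bc for v in r) / n**2
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return math.sqrt(max(dcov2, 0.0) / math.sqrt(dvx * dvy))


def hoeffding_brute(x, y) -> float:
    n = len(x)
    r = midranks(x)
    s = midranks(y)
    q = [0.0] * n
    for i in range(n):
        total = 1.0
        for j in range(n):
            if j == i:
                continue
            xl, xe = x[j] < x[i], x[j] == x[i]
            yl, ye = y[j] < y[i], y[j] == y[i]
            if xl and yl:
                total += 1.0
            elif (xl and ye) or (xe and yl):
                total += 0.5
            elif xe and ye:
                total += 0.25
        q[i] = total
    d1 = sum((qi - 1) * (qi - 2) for qi in q)
    d2 = sum((r[i] - 1) * (r[i] - 2) * (s[i] - 1) * (s[i] - 2)
             for i in range(n))
    d3 = sum((r[i] - 2) * (s[i] - 2) * (q[i] - 1) for i in range(n))
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return 30.0 * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3) / denom


def bh_stepup_brute(p) -> list[float]:
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running = 1.0
    for k in range(n - 1, -1, -1):
        i = order[k]
        val = min(p[i] * n / (k + 1), 1.0)
        running = min(running, val)
        adj[i] = running
    return adj


def partial_corr_by_regression(data: np.ndarray, i: int, j: int,
                               cond: tuple[int, ...]) -> float:
    """Partial correlation via residuals of OLS on the conditioning set."""
    n = data.shape[0]
    if not cond:
        return float(np.corrcoef(data[:, i], data[:, j])[0, 1])
    z = np.column_stack([np.ones(n), data[:, list(cond)]])
    ri = data[:, i] - z @ np.linalg.lstsq(z, data[:, i], rcond=None)[0]
    rj = data[:, j] - z @ np.linalg.lstsq(z, data[:, j], rcond=None)[0]
    return float(np.corrcoef(ri, rj)[0, 1])


# ---------------------------------------------------------------------------
# CPDAG extension enumeration


def digraph_is_acyclic(nodes, edges) -> bool:
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
    colour = {v: 0 for v in nodes}

    def dfs(v) -> bool:
        colour[v] = 1
        for w in adj[v]:
            if colour[w] == 1:
                return False
            if colour[w] == 0 and not dfs(w):
                return False
        colour[v] = 2
        return True

    return all(colour[v] != 0 or dfs(v) for v in nodes)


def vstructures(nodes, edges, adjacency=None) -> set:
    """Unshielded colliders a -> c <- b among directed edges.

    ``adjacency`` (set of frozenset pairs) defaults to the adjacencies of
    ``edges``; pass the full skeleton when undirected edges also shield.
    """
    if adjacency is None:
        adjacent = {frozenset((a, b)) for a, b in edges}
    else:
        adjacent = set(adjacency)
    parents = {v: set() for v in nodes}
    for a, b in edges:
        parents[b].add(a)
    out = set()
    for c in nodes:
        for a, b in itertools.combinations(sorted(parents[c]), 2):
            if frozenset((a, b)) not in adjacent:
                out.add((a, b, c))
    return out


def consistent_extensions(cpdag) -> list[set]:
    """All DAGs with the CPDAG's skeleton and v-structures.

    Returns a list of directed-edge sets.  Exponential in the number of
    undirected edges; only for small graphs.
    """
    base = set(cpdag.directed_edges)
    und = [tuple(sorted(e)) for e in sorted(
        tuple(sorted(e)) for e in cpdag.undirected_edges)]
    # v-structures of the CPDAG: directed edges, full-skeleton shielding
    skeleton = {frozenset((a, b)) for a, b in base}
    skeleton |= {frozenset(e) for e in und}
    target_v = vstructures(cpdag.nodes, base, adjacency=skeleton)
    out = []
    for bits in itertools.product([0, 1], repeat=len(und)):
        edges = set(base)
        for (a, b), bit in zip(und, bits):
            edges.add((a, b) if bit else (b, a))
        if not digraph_is_acyclic(cpdag.nodes, edges):
            continue
        if vstructures(cpdag.nodes, edges) != target_v:
            continue
        out.append(edges)
    return out


def ida_effects_by_extensions(ds, cpdag, mirna, mrna) -> list[float]:
    """IDA effects from exhaustive DAG-extension enumeration.

    Collects the distinct parent sets of the miRNA over all consistent
    extensions and runs one adjustment regression per distinct set.
    """
    arr = ds.data
    parent_sets = set()
    for edges in consistent_extensions(cpdag):
        parent_sets.add(frozenset(a for a, b in edges if b == mirna))
    effects = []
    for pset in sorted(parent_sets, key=lambda s: sorted(s)):
        if mrna in pset:
            effects.append(0.0)
            continue
        cols = [mirna, *sorted(pset)]
        xmat = np.column_stack(
            [np.ones(ds.n_samples)]
            + [arr[c].to_numpy(dtype=float) for c in cols]
        )
        yvec = arr[mrna].to_numpy(dtype=float)
        beta, _, rank, _ = np.linalg.lstsq(xmat, yvec, rcond=None)
        if rank < xmat.shape[1]:
            continue
        effects.append(float(beta[1]))
    return effects
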
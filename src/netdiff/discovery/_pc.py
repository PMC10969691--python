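"""PC-stable constraint-based structure discovery with the Fisher-z test.

Skeleton phase uses the order-independent ("stable") adjacency snapshot per
depth level; orientation applies the collider rule followed by the Meek
rules. Operates on a raw data matrix; the public adapter wraps the result
into an EstimatedGraph.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["pc_stable"]


def _fisher_z_pvalue(corr: np.ndarray, n: int, x: int, y: int, s: tuple[int, ...]) -> float:
    """p-value of the conditional-independence test x _||_ y | s."""
    if not s:
        r = corr[x, y]
    else:
        sub = corr[np.ix_((x, y) + s, (x, y) + s)]
        try:
            prec = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            prec = np.linalg.pinv(sub)
        denom = math.sqrt(abs(prec[0, 0] * prec[1, 1]))
        r = -prec[0, 1] / denom if denom > 0 else 0.0
    r = min(max(r, -1.0 + 1e-12), 1.0 - 1e-12)
    dof = n - len(s) - 3
    if dof <= 0:
        return 1.0  # not enough samples to test: treat as independent
    z = 0.5 * math.log1p(2 * r / (1 - r))
    stat = math.sqrt(dof) * abs(z)
    return 2.0 * stats.norm.sf(stat)


def pc_stable(
    x: np.ndarray, alpha: float = 0.05, max_cond_size: int | None = None
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """Run PC-stable on data matrix ``x`` (rows = samples).

    Returns (directed, undirected) edge sets over column indices; undirected
    edges as (min, max) tuples. Fully deterministic.
    """
    n, p = x.shape
    corr = np.corrcoef(x, rowvar=False)
    # constant columns yield nan correlations; treat them as uncorrelated
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)

    adj: list[set[int]] = [set(range(p)) - {i} for i in range(p)]
    sepset: dict[tuple[int, int], frozenset[int]] = {}

    level = 0
    while True:
        if max_cond_size is not None and level > max_cond_size:
            break
        snapshot = [frozenset(a) for a in adj]
        if all(len(snapshot[i]) - 1 < level for i in range(p)):
            break
        for i in range(p):
            for j in sorted(snapshot[i]):
                if j not in adj[i]:
                    continue  # already removed at this level
                others = sorted(snapshot[i] - {j})
                if len(others) < level:
                    continue
                for cond in combinations(others, level):
                    if _fisher_z_pvalue(corr, n, i, j, cond) > alpha:
                        adj[i].discard(j)
                        adj[j].discard(i)
                        sepset[(min(i, j), max(i, j))] = frozenset(cond)
                        break
        level += 1

    # collider orientation: i - k - j with i,j nonadjacent and k not in sepset(i,j)
    directed: set[tuple[int, int]] = set()
    for k in range(p):
        for i, j in combinations(sorted(adj[k]), 2):
            if j in adj[i]:
                continue
            if k not in sepset.get((min(i, j), max(i, j)), frozenset()):
                directed.add((i, k))
                directed.add((j, k))
    # conflicting double orientations fall back to undirected
    conflicts = {(a, b) for (a, b) in directed if (b, a) in directed}
    directed -= conflicts

    undirected = {
        (i, j) for i in range(p) for j in adj[i] if i < j
    } - {tuple(sorted(e)) for e in directed} - {tuple(sorted(e)) for e in conflicts}
    undirected |= {tuple(sorted(e)) for e in conflicts}

    directed, undirected = _apply_meek_rules(p, adj, directed, undirected)
    return directed, undirected


def _apply_meek_rules(
    p: int,
    adj: list[set[int]],
    directed: set[tuple[int, int]],
    undirected: set[tuple[int, int]],
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """Meek rules 1-3, applied to a fixpoint."""

    def orient(a: int, b: int) -> bool:
        e = (min(a, b), max(a, b))
        if e in undirected and (b, a) not in directed:
            undirected.discard(e)
            directed.add((a, b))
            return True
        return False

    changed = True
    while changed:
        changed = False
        for a, b in sorted(undirected):
            for x, y in ((a, b), (b, a)):
                # R1: w -> x, x - y, w and y nonadjacent  =>  x -> y
                if any((w, x) in directed and y not in adj[w] and w != y for w in adj[x]):
                    if orient(x, y):
                        changed = True
                        break
                # R2: x -> w -> y and x - y  =>  x -> y
                if any((x, w) in directed and (w, y) in directed for w in adj[x] & adj[y]):
                    if orient(x, y):
                        changed = True
                        break
                # R3: x - w1 -> y, x - w2 -> y, w1,w2 nonadjacent, x - y  =>  x -> y
                ws = [
                    w
                    for w in adj[x] & adj[y]
                    if (w, y) in directed and (min(x, w), max(x, w)) in undirected
                ]
                if any(w2 not in adj[w1] for w1, w2 in combinations(ws, 2)):
                    if orient(x, y):
                        changed = True
                        break
            if changed:
                break
    return directed, undirected
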
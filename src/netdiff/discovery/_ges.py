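"""Greedy Equivalence Search (GES) with the Gaussian BIC score.

Searches over Markov equivalence classes (CPDAGs): a forward phase applies
the best valid Insert operator until no insertion improves the score, then a
backward phase applies Delete operators; the two phases alternate to a
fixpoint. The decomposable score for node ``v`` with parent set ``P`` is

    score(v | P) = -n/2 * log(sigma^2_{v|P}) - c/2 * log(n) * (|P| + 1)

with ``sigma^2_{v|P}`` the MLE residual variance of regressing v on P and
``c`` the penalty discount (c = 1 is standard BIC). Deterministic: operator
candidates are enumerated in index order and only a strictly better score
delta replaces the incumbent.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from ._cpdag import dag_to_cpdag

__all__ = ["greedy_bic_search"]

_EPS = 1e-9
#: cap on the neighbor-subset enumeration per operator (2^cap subsets)
_MAX_SUBSET = 10


class _Scorer:
    def __init__(self, x: np.ndarray, penalty_discount: float):
        self.n = x.shape[0]
        self.cov = np.atleast_2d(np.cov(x, rowvar=False, bias=True))
        self.penalty = penalty_discount * math.log(self.n) / 2.0
        self._cache: dict[tuple[int, frozenset[int]], float] = {}

    def local(self, v: int, parents: frozenset[int]) -> float:
        key = (v, parents)
        if key in self._cache:
            return self._cache[key]
        if parents:
            p = sorted(parents)
            spp = self.cov[np.ix_(p, p)]
            spv = self.cov[p, v]
            try:
                resid = float(self.cov[v, v] - spv @ np.linalg.solve(spp, spv))
            except np.linalg.LinAlgError:
                resid = float(self.cov[v, v] - spv @ np.linalg.lstsq(spp, spv, rcond=None)[0])
        else:
            resid = float(self.cov[v, v])
        resid = max(resid, 1e-12)
        score = -self.n / 2.0 * math.log(resid) - self.penalty * (len(parents) + 1)
        self._cache[key] = score
        return score


class _Pattern:
    """Mutable CPDAG state: directed parents and undirected neighbors per node."""

    def __init__(self, p: int):
        self.p = p
        self.pa: list[set[int]] = [set() for _ in range(p)]
        self.ch: list[set[int]] = [set() for _ in range(p)]
        self.ne: list[set[int]] = [set() for _ in range(p)]

    def adjacent(self, x: int, y: int) -> bool:
        return y in self.pa[x] or y in self.ch[x] or y in self.ne[x]

    def adj(self, x: int) -> set[int]:
        return self.pa[x] | self.ch[x] | self.ne[x]

    def is_clique(self, nodes: set[int]) -> bool:
        return all(self.adjacent(a, b) for a, b in combinations(sorted(nodes), 2))

    def blocked_semi_directed(self, src: int, dst: int, blockers: set[int]) -> bool:
        """True iff every semi-directed path src ~> dst passes through blockers."""
        if src in blockers:
            return True
        stack, seen = [src], {src}
        while stack:
            v = stack.pop()
            for w in sorted(self.ch[v] | self.ne[v]):
                if w in seen or w in blockers:
                    continue
                if w == dst:
                    return False
                seen.add(w)
                stack.append(w)
        return True

    def rebuild_as_cpdag(self) -> None:
        """Re-close the current PDAG: extend to a consistent DAG, then relabel."""
        parents = _pdag_to_dag(self.p, self.pa, self.ne)
        directed, undirected = dag_to_cpdag(self.p, [sorted(ps) for ps in parents])
        self.pa = [set() for _ in range(self.p)]
        self.ch = [set() for _ in range(self.p)]
        self.ne = [set() for _ in range(self.p)]
        for t, h in directed:
            self.pa[h].add(t)
            self.ch[t].add(h)
        for a, b in undirected:
            self.ne[a].add(b)
            self.ne[b].add(a)


def _pdag_to_dag(p: int, pa: list[set[int]], ne: list[set[int]]) -> list[set[int]]:
    """Consistent DAG extension of a PDAG (sink-elimination construction)."""
    pa_work = [set(s) for s in pa]
    ne_work = [set(s) for s in ne]
    ch_work: list[set[int]] = [set() for _ in range(p)]
    for h in range(p):
        for t in pa_work[h]:
            ch_work[t].add(h)
    result = [set(s) for s in pa]
    remaining = set(range(p))

    def adjacent(a: int, b: int) -> bool:
        return b in pa_work[a] or b in ch_work[a] or b in ne_work[a]

    while remaining:
        chosen = None
        for v in sorted(remaining):
            if ch_work[v] & remaining:
                continue  # not a sink
            nbrs = ne_work[v] & remaining
            adj_v = (pa_work[v] | ne_work[v]) & remaining
            if all(adjacent(w, u) for w in nbrs for u in adj_v - {w}):
                chosen = v
                break
        if chosen is None:
            raise ValueError("PDAG admits no consistent extension")
        for w in ne_work[chosen] & remaining:
            result[chosen].add(w)
        remaining.discard(chosen)
        for s in (pa_work, ch_work, ne_work):
            for v in remaining:
                s[v].discard(chosen)
    return result


def _subsets(candidates: list[int]):
    for r in range(len(candidates) + 1):
        yield from (set(c) for c in combinations(candidates, r))


def _best_insert(g: _Pattern, scorer: _Scorer):
    best_delta, best_op = _EPS, None
    for y in range(g.p):
        pa_y = frozenset(g.pa[y])
        for x in range(g.p):
            if x == y or g.adjacent(x, y):
                continue
            na = g.ne[y] & g.adj(x)
            t_candidates = sorted(g.ne[y] - g.adj(x))[:_MAX_SUBSET]
            for t in _subsets(t_candidates):
                block = na | t
                if not g.is_clique(block):
                    continue
                if not g.blocked_semi_directed(y, x, block):
                    continue
                base = pa_y | block
                delta = scorer.local(y, base | {x}) - scorer.local(y, base)
                if delta > best_delta:
                    best_delta, best_op = delta, (x, y, frozenset(t))
    return best_op


def _best_delete(g: _Pattern, scorer: _Scorer):
    best_delta, best_op = _EPS, None
    for y in range(g.p):
        pa_y = frozenset(g.pa[y])
        for x in sorted(g.pa[y] | g.ne[y]):
            na = g.ne[y] & g.adj(x)
            h_candidates = sorted(na)[:_MAX_SUBSET]
            for h in _subsets(h_candidates):
                if not g.is_clique(na - h):
                    continue
                base = (pa_y | (na - h)) - {x}
                delta = scorer.local(y, base) - scorer.local(y, base | {x})
                if delta > best_delta:
                    best_delta, best_op = delta, (x, y, frozenset(h))
    return best_op


def greedy_bic_search(
    x: np.ndarray, penalty_discount: float = 1.0, max_iter: int | None = None
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """Run GES on data matrix ``x`` (rows = samples).

    Returns (directed, undirected) CPDAG edge sets over column indices,
    undirected edges as (min, max) tuples.
    """
    n, p = x.shape
    scorer = _Scorer(x, penalty_discount)
    g = _Pattern(p)
    if max_iter is None:
        max_iter = 4 * p * p

    for _phase_round in range(max_iter):
        progressed = False
        for _ in range(max_iter):  # forward phase
            op = _best_insert(g, scorer)
            if op is None:
                break
            xx, yy, t = op
            g.pa[yy].add(xx)
            g.ch[xx].add(yy)
            for u in t:
                g.ne[yy].discard(u)
                g.ne[u].discard(yy)
                g.pa[yy].add(u)
                g.ch[u].add(yy)
            g.rebuild_as_cpdag()
            progressed = True
        for _ in range(max_iter):  # backward phase
            op = _best_delete(g, scorer)
            if op is None:
                break
            xx, yy, h = op
            g.pa[yy].discard(xx)
            g.ch[xx].discard(yy)
            g.ne[yy].discard(xx)
            g.ne[xx].discard(yy)
            for u in h:
                if u in g.ne[yy]:
                    g.ne[yy].discard(u)
                    g.ne[u].discard(yy)
                    g.pa[u].add(yy)
                    g.ch[yy].add(u)
                if u in g.ne[xx]:
                    g.ne[xx].discard(u)
                    g.ne[u].discard(xx)
                    g.pa[u].add(xx)
                    g.ch[xx].add(u)
            g.rebuild_as_cpdag()
            progressed = True
        if not progressed:
            break

    directed = {(t, h) for h in range(p) for t in g.pa[h]}
    undirected = {(min(a, b), max(a, b)) for a in range(p) for b in g.ne[a]}
    return directed, undirected
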
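"""DAG -> CPDAG conversion (compelled-edge labelling).

Implements the classic order-edges / label-compelled procedure: edges whose
orientation is shared by every DAG in the Markov equivalence class are kept
directed; the rest become undirected. Operates on integer node ids with a
parent list per node.
"""

from __future__ import annotations

__all__ = ["dag_to_cpdag"]


def _topological_order(parents: list[list[int]]) -> list[int]:
    n = len(parents)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = [0] * n
    for v, ps in enumerate(parents):
        indeg[v] = len(ps)
        for p in ps:
            children[p].append(v)
    frontier = sorted(v for v in range(n) if indeg[v] == 0)
    order: list[int] = []
    while frontier:
        v = frontier.pop(0)
        order.append(v)
        for c in children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                frontier.append(c)
        frontier.sort()
    if len(order) != n:
        raise ValueError("graph is not acyclic")
    return order


def dag_to_cpdag(
    n: int, parents: list[list[int]]
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """Return (directed, undirected) edge sets of the CPDAG of the given DAG.

    ``parents[v]`` lists the parents of node ``v``. Directed edges are
    (tail, head); undirected edges are (min, max).
    """
    order = _topological_order(parents)
    rank = {v: i for i, v in enumerate(order)}

    # Total order over edges: visit heads in topological order; within a head,
    # tails from highest topological rank down.
    edge_order: list[tuple[int, int]] = []
    for y in order:
        for x in sorted(parents[y], key=lambda t: -rank[t]):
            edge_order.append((x, y))

    parent_sets = [set(ps) for ps in parents]
    label: dict[tuple[int, int], str] = {}  # "compelled" | "reversible"

    for x, y in edge_order:
        if (x, y) in label:
            continue
        done = False
        for w in sorted(parent_sets[x], key=lambda t: rank[t]):
            if label.get((w, x)) != "compelled":
                continue
            if w not in parent_sets[y]:
                # w -> x compelled but w not a parent of y: x -> y and every
                # edge into y is compelled
                for t in parent_sets[y]:
                    label[(t, y)] = "compelled"
                done = True
                break
            label[(w, y)] = "compelled"
        if done:
            continue
        # z -> y with z != x and z not a parent of x forces compelled labels
        target = (
            "compelled"
            if any(z != x and z not in parent_sets[x] for z in parent_sets[y])
            else "reversible"
        )
        for t in parent_sets[y]:
            label.setdefault((t, y), target)

    directed: set[tuple[int, int]] = set()
    undirected: set[tuple[int, int]] = set()
    for (x, y), lab in label.items():
        if lab == "compelled":
            directed.add((x, y))
        else:
            undirected.add((min(x, y), max(x, y)))
    return directed, undirected
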
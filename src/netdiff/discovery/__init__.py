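"""Uniform interface to causal structure discovery backends.

Two backends are provided, both returning an equivalence-class pattern
(CPDAG-like partially directed graph): constraint-based PC-stable with the
Fisher-z conditional-independence test, and score-based greedy search with
the Gaussian BIC score. ``graph_to_indicators`` normalizes a pattern into
per-pair 0/1 presence indicators, in oriented or skeleton mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..simulate import Dataset
from ._ges import greedy_bic_search
from ._pc import pc_stable

__all__ = [
    "EstimatedGraph",
    "EdgeIndicatorMap",
    "run_discovery",
    "graph_to_indicators",
    "ALGORITHMS",
    "DEFAULT_PARAMS",
]

#: default backend settings: PC with Fisher-z at alpha=0.05, greedy BIC with
#: penalty discount 1
DEFAULT_PARAMS = {
    "pc": {"alpha": 0.05, "max_cond_size": None},
    "ges": {"penalty_discount": 1.0},
}
ALGORITHMS = tuple(DEFAULT_PARAMS)

_ALIASES = {"pc": "pc", "ges": "ges", "fges": "ges"}


@dataclass(frozen=True)
class EstimatedGraph:
    """A partially directed graph over named variables.

    Every unordered pair is in exactly one state: absent, directed
    (tail, head) or undirected.
    """

    variables: tuple[str, ...]
    directed: frozenset[tuple[str, str]]
    undirected: frozenset[tuple[str, str]]  # stored with sorted endpoints

    def __post_init__(self) -> None:
        und = frozenset(tuple(sorted(e)) for e in self.undirected)
        object.__setattr__(self, "undirected", und)
        seen = set(und)
        for tail, head in self.directed:
            key = tuple(sorted((tail, head)))
            if (head, tail) in self.directed:
                raise ValueError(f"pair {key} directed both ways")
            if key in seen:
                raise ValueError(f"pair {key} has conflicting states")
            seen.add(key)

    def adjacencies(self) -> frozenset[tuple[str, str]]:
        """All adjacent unordered pairs (sorted endpoints)."""
        return frozenset(tuple(sorted(e)) for e in self.directed) | self.undirected

    @property
    def n_edges(self) -> int:
        return len(self.directed) + len(self.undirected)


@dataclass(frozen=True)
class EdgeIndicatorMap:
    """Binary per-pair presence indicators derived from an EstimatedGraph."""

    mode: str  # "orientation" (ordered pairs) or "skeleton" (unordered pairs)
    variables: tuple[str, ...]
    positives: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.mode not in ("orientation", "skeleton"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "skeleton":
            object.__setattr__(
                self, "positives", frozenset(tuple(sorted(p)) for p in self.positives)
            )

    def get(self, pair: tuple[str, str]) -> int:
        if self.mode == "skeleton":
            pair = tuple(sorted(pair))
        return 1 if pair in self.positives else 0


def run_discovery(
    data: Dataset, algorithm: str = "pc", params: dict | None = None
) -> EstimatedGraph:
    """Run a structure discovery backend on a dataset.

    Parameters
    ----------
    data
        The dataset to learn from; must have at least 2 variables.
    algorithm
        ``"pc"`` (constraint-based, Fisher-z) or ``"ges"``/``"fges"``
        (score-based, Gaussian BIC).
    params
        Backend settings overriding the documented defaults
        (pc: ``alpha``, ``max_cond_size``; ges: ``penalty_discount``).

    Deterministic: identical inputs produce identical outputs.
    """
    if data.n_vars < 2:
        raise ValueError("discovery requires at least 2 variables")
    key = _ALIASES.get(str(algorithm).lower())
    if key is None:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from pc, ges/fges")
    settings = dict(DEFAULT_PARAMS[key])
    if params:
        unknown = set(params) - set(settings)
        if unknown:
            raise ValueError(f"unknown {key} parameters: {sorted(unknown)}")
        settings.update(params)
    x = np.asarray(data.values, dtype=np.float64)
    if key == "pc":
        directed_i, undirected_i = pc_stable(x, **settings)
    else:
        directed_i, undirected_i = greedy_bic_search(x, **settings)
    names = data.variables
    return EstimatedGraph(
        variables=names,
        directed=frozenset((names[a], names[b]) for a, b in directed_i),
        undirected=frozenset(tuple(sorted((names[a], names[b]))) for a, b in undirected_i),
    )


def graph_to_indicators(
    g: EstimatedGraph, mode: str = "orientation", undirected_policy: str = "both"
) -> EdgeIndicatorMap:
    """Normalize a pattern into 0/1 edge indicators.

    In skeleton mode a pair scores 1 iff it is adjacent. In orientation mode a
    directed edge X->Y scores 1 for (X, Y) only; an undirected edge scores 1
    for both orderings under policy ``"both"`` and for neither under
    ``"none"`` (an undirected pattern edge does not rule out either
    direction, hence the default).
    """
    if undirected_policy not in ("both", "none"):
        raise ValueError(f"unknown undirected_policy {undirected_policy!r}")
    if mode == "skeleton":
        return EdgeIndicatorMap(
            mode=mode, variables=g.variables, positives=g.adjacencies()
        )
    if mode != "orientation":
        raise ValueError(f"unknown mode {mode!r}")
    positives = set(g.directed)
    if undirected_policy == "both":
        for a, b in g.undirected:
            positives.add((a, b))
            positives.add((b, a))
    return EdgeIndicatorMap(mode=mode, variables=g.variables, positives=frozenset(positives))
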
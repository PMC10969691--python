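"""Three estimators of the structural difference between two causal networks.

Given datasets ``D_i``, ``D_j`` generated by networks ``G_i``, ``G_j``, each
estimator scores every variable pair for membership in ``E_i - E_j`` (edges
present in ``G_i`` but absent from ``G_j``):

naive
    Learn one network per dataset and difference the binary edge indicators;
    a pair scores 1 iff the edge is found in ``D_i`` and not in ``D_j``.
bootstrap (bs)
    Learn networks on B with-replacement resamples of each dataset, record
    per-edge discovery frequencies, and difference the frequencies; scores
    lie in [-1, 1] and carry the confidence of each side's estimate.
equal-sample-size resampling (rsbs)
    Like bootstrap, but the larger dataset is scored on B without-replacement
    subsamples of the smaller dataset's size, equalizing statistical power
    before differencing. Not applicable when the sample sizes are equal.

Resampling streams are derived from the call seed and a content digest of
each dataset, so swapping the argument order reuses bit-identical frequency
maps and the two orderings' score maps are exact negations of each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import child_seed, content_key
from .discovery import EdgeIndicatorMap, EstimatedGraph, graph_to_indicators, run_discovery
from .simulate import Dataset

__all__ = [
    "EdgeScoreMap",
    "DiffScoreMap",
    "naive_diff",
    "bootstrap_edge_frequencies",
    "bootstrap_diff",
    "subsample_frequencies",
    "rsbs_diff",
    "diff_frequency_maps",
    "resample_graphs",
    "frequencies_from_graphs",
    "RsbsNotApplicableError",
    "DEFAULT_B",
]

#: default number of resamples per dataset
DEFAULT_B = 50

METHODS = ("naive", "bs", "rsbs")


class RsbsNotApplicableError(ValueError):
    """Equal-sample-size resampling requires unequal sample sizes."""


@dataclass(frozen=True)
class EdgeScoreMap:
    """Per-pair edge confidence in [0, 1] for one dataset (frequency map)."""

    mode: str
    variables: tuple[str, ...]
    scores: dict[tuple[str, str], float]
    resample_count: int | None = None  # B, when produced by resampling

    def get(self, pair: tuple[str, str]) -> float:
        if self.mode == "skeleton":
            pair = tuple(sorted(pair))
        return self.scores.get(pair, 0.0)


@dataclass(frozen=True)
class DiffScoreMap:
    """Per-pair difference scores estimating membership in E_i - E_j."""

    mode: str
    method: str  # "naive" | "bs" | "rsbs"
    variables: tuple[str, ...]
    scores: dict[tuple[str, str], float]
    direction: tuple[str, str] = ("i", "j")  # labels of the (i, j) ordering

    def get(self, pair: tuple[str, str]) -> float:
        if self.mode == "skeleton":
            pair = tuple(sorted(pair))
        return self.scores.get(pair, 0.0)


def _indicator_to_scores(ind: EdgeIndicatorMap) -> dict[tuple[str, str], float]:
    return {p: 1.0 for p in ind.positives}


def diff_frequency_maps(
    f_i: EdgeScoreMap, f_j: EdgeScoreMap, method: str, direction=("i", "j")
) -> DiffScoreMap:
    """Per-pair difference of two frequency maps: score = f_i - f_j in [-1, 1]."""
    if f_i.mode != f_j.mode:
        raise ValueError("frequency maps have different modes")
    if set(f_i.variables) != set(f_j.variables):
        raise ValueError("frequency maps cover different variable sets")
    scores: dict[tuple[str, str], float] = {}
    for pair in set(f_i.scores) | set(f_j.scores):
        s = f_i.get(pair) - f_j.get(pair)
        if s != 0.0:
            scores[pair] = s
    return DiffScoreMap(
        mode=f_i.mode,
        method=method,
        variables=f_i.variables,
        scores=scores,
        direction=tuple(direction),
    )


def naive_diff(
    d_i: Dataset,
    d_j: Dataset,
    algorithm: str = "pc",
    params: dict | None = None,
    mode: str = "orientation",
    undirected_policy: str = "both",
) -> DiffScoreMap:
    """Single-run indicator difference: 1 where the edge is found in d_i only."""
    _check_shared_variables(d_i, d_j)
    ind_i = graph_to_indicators(run_discovery(d_i, algorithm, params), mode, undirected_policy)
    ind_j = graph_to_indicators(run_discovery(d_j, algorithm, params), mode, undirected_policy)
    scores = {p: 1.0 for p in ind_i.positives - ind_j.positives}
    return DiffScoreMap(
        mode=mode, method="naive", variables=d_i.variables, scores=scores
    )


def resample_graphs(
    d: Dataset,
    algorithm: str,
    params: dict | None,
    b: int,
    seed: int,
    n_target: int | None = None,
) -> list[EstimatedGraph]:
    """Run discovery on B resamples of ``d``.

    With ``n_target=None`` resamples are bootstrap draws (n rows with
    replacement); otherwise each resample is ``n_target`` distinct rows drawn
    without replacement. The RNG stream depends on the dataset contents, not
    the argument position, so repeated calls on the same data reuse the same
    resamples.
    """
    if b < 1:
        raise ValueError("B must be >= 1")
    base = child_seed(seed, "resample", content_key(d.values), n_target or 0)
    rng = np.random.default_rng(base)
    graphs = []
    for _ in range(b):
        if n_target is None:
            idx = rng.integers(0, d.n, d.n)
        else:
            idx = rng.choice(d.n, size=n_target, replace=False)
        sample = Dataset(values=d.values[idx], variables=d.variables)
        graphs.append(run_discovery(sample, algorithm, params))
    return graphs


def frequencies_from_graphs(
    graphs: list[EstimatedGraph], mode: str, undirected_policy: str = "both"
) -> EdgeScoreMap:
    """Per-pair discovery frequency over a list of resample patterns."""
    if not graphs:
        raise ValueError("no graphs given")
    counts: dict[tuple[str, str], int] = {}
    for g in graphs:
        for p in graph_to_indicators(g, mode, undirected_policy).positives:
            counts[p] = counts.get(p, 0) + 1
    b = len(graphs)
    return EdgeScoreMap(
        mode=mode,
        variables=graphs[0].variables,
        scores={p: c / b for p, c in counts.items()},
        resample_count=b,
    )


def bootstrap_edge_frequencies(
    d: Dataset,
    algorithm: str = "pc",
    params: dict | None = None,
    b: int = DEFAULT_B,
    mode: str = "orientation",
    seed: int = 0,
    undirected_policy: str = "both",
) -> EdgeScoreMap:
    """Fraction of B with-replacement resamples in which each edge is found."""
    graphs = resample_graphs(d, algorithm, params, b, seed)
    return frequencies_from_graphs(graphs, mode, undirected_policy)


def subsample_frequencies(
    d_large: Dataset,
    n_target: int,
    algorithm: str = "pc",
    params: dict | None = None,
    b: int = DEFAULT_B,
    mode: str = "orientation",
    seed: int = 0,
    undirected_policy: str = "both",
) -> EdgeScoreMap:
    """Edge frequencies over B without-replacement subsamples of size n_target."""
    if n_target >= d_large.n:
        raise ValueError(
            f"n_target={n_target} must be smaller than the dataset size {d_large.n}; "
            "use bootstrap_edge_frequencies for equal sizes"
        )
    if n_target < 1:
        raise ValueError("n_target must be positive")
    graphs = resample_graphs(d_large, algorithm, params, b, seed, n_target=n_target)
    return frequencies_from_graphs(graphs, mode, undirected_policy)


def bootstrap_diff(
    d_i: Dataset,
    d_j: Dataset,
    algorithm: str = "pc",
    params: dict | None = None,
    b: int = DEFAULT_B,
    mode: str = "orientation",
    seed: int = 0,
    undirected_policy: str = "both",
) -> DiffScoreMap:
    """Difference of the two datasets' bootstrap frequency maps, in (i, j) order."""
    _check_shared_variables(d_i, d_j)
    f_i = bootstrap_edge_frequencies(d_i, algorithm, params, b, mode, seed, undirected_policy)
    f_j = bootstrap_edge_frequencies(d_j, algorithm, params, b, mode, seed, undirected_policy)
    return diff_frequency_maps(f_i, f_j, method="bs")


def rsbs_diff(
    d_i: Dataset,
    d_j: Dataset,
    algorithm: str = "pc",
    params: dict | None = None,
    b: int = DEFAULT_B,
    mode: str = "orientation",
    seed: int = 0,
    undirected_policy: str = "both",
) -> DiffScoreMap:
    """Equal-sample-size resampling difference in (i, j) order.

    The larger dataset is scored by without-replacement subsamples at the
    smaller dataset's size; the smaller dataset by bootstrap. Raises
    RsbsNotApplicableError when the sample sizes are equal.
    """
    _check_shared_variables(d_i, d_j)
    if d_i.n == d_j.n:
        raise RsbsNotApplicableError(
            "equal-sample-size resampling is not applicable when the two datasets "
            f"have the same sample size (n={d_i.n})"
        )
    n_small = min(d_i.n, d_j.n)
    if d_i.n > d_j.n:
        f_i = subsample_frequencies(
            d_i, n_small, algorithm, params, b, mode, seed, undirected_policy
        )
        f_j = bootstrap_edge_frequencies(
            d_j, algorithm, params, b, mode, seed, undirected_policy
        )
    else:
        f_i = bootstrap_edge_frequencies(
            d_i, algorithm, params, b, mode, seed, undirected_policy
        )
        f_j = subsample_frequencies(
            d_j, n_small, algorithm, params, b, mode, seed, undirected_policy
        )
    return diff_frequency_maps(f_i, f_j, method="rsbs")


def _check_shared_variables(d_i: Dataset, d_j: Dataset) -> None:
    if tuple(d_i.variables) != tuple(d_j.variables):
        raise ValueError("datasets must share an identical variable list")
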
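"""Ground-truth difference labels, classification metrics and effect sizes.

Estimating the edge set difference E_i - E_j is treated as binary
classification over the pair universe: every ordered pair (orientation mode,
Nv*(Nv-1) instances) or unordered pair (skeleton mode, Nv*(Nv-1)/2
instances) is an instance, positive iff the edge is in G_i and not in G_j.
Ranking metrics (AUCROC, AUPR) and a calibration metric (cross-entropy) are
computed on the raw scores; threshold metrics at the F1-optimal cut.

The effect size of an edge X -> Y is Cohen's f² from the population
regression of Y on its parent sets,

    f² = (R²(Pa(Y)) - R²(Pa(Y) \\ X)) / (1 - R²(Pa(Y))),

computed in closed form from the network's implied covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .discovery import EstimatedGraph, graph_to_indicators
from .simulate import DagStructure, LinearGaussianNetwork, implied_covariance

__all__ = [
    "DiffLabels",
    "MetricsReport",
    "CorrelationResult",
    "true_edge_diff",
    "pair_universe",
    "classification_metrics",
    "effect_size",
    "effect_size_table",
    "correlate_effectsize_scores",
]

CE_EPS = 1e-6


@dataclass(frozen=True)
class DiffLabels:
    """Binary ground-truth labels for membership in E_i - E_j."""

    mode: str
    variables: tuple[str, ...]
    positives: frozenset[tuple[str, str]]
    direction: tuple[str, str] = ("i", "j")

    def get(self, pair: tuple[str, str]) -> int:
        if self.mode == "skeleton":
            pair = tuple(sorted(pair))
        return 1 if pair in self.positives else 0


@dataclass(frozen=True)
class MetricsReport:
    """Ranking, calibration and thresholded binary metrics for one evaluation.

    Ranking metrics are None when the labels are degenerate (no positives or
    no negatives). ``zero_division`` lists thresholded metrics whose
    denominator was zero (reported as 0 by convention).
    """

    aucroc: float | None
    aupr: float | None
    cross_entropy: float
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    accuracy: float
    n_pos: int
    n_neg: int
    zero_division: tuple[str, ...] = ()
    ce_mapping: str = "clip"

    def as_dict(self) -> dict:
        return {
            "aucroc": self.aucroc,
            "aupr": self.aupr,
            "cross_entropy": self.cross_entropy,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def pair_universe(variables: tuple[str, ...], mode: str) -> list[tuple[str, str]]:
    """All instances of the classification problem, in deterministic order."""
    if mode == "orientation":
        return list(permutations(variables, 2))
    if mode == "skeleton":
        return [tuple(sorted(p)) for p in combinations(variables, 2)]
    raise ValueError(f"unknown mode {mode!r}")


def _edge_indicator(g, mode: str) -> frozenset[tuple[str, str]]:
    """Positive pairs of a network/DAG/pattern under the given mode."""
    if isinstance(g, LinearGaussianNetwork):
        g = g.dag
    if isinstance(g, DagStructure):
        if mode == "orientation":
            return frozenset(g.edges)
        return frozenset(tuple(sorted(e)) for e in g.edges)
    if isinstance(g, EstimatedGraph):
        return graph_to_indicators(g, mode, undirected_policy="both").positives
    raise TypeError(f"cannot derive edge indicators from {type(g).__name__}")


def true_edge_diff(g_i, g_j, mode: str = "orientation", direction=("i", "j")) -> DiffLabels:
    """Ground-truth labels: pair positive iff its edge is in g_i and not g_j.

    Accepts networks, bare DAGs or estimated patterns (the latter for
    reference graphs in the real-data protocol, where an undirected pattern
    edge counts for both orderings).
    """
    vars_i = tuple(g_i.variables)
    if tuple(g_j.variables) != vars_i:
        raise ValueError("graphs must share an identical variable list")
    e_i = _edge_indicator(g_i, mode)
    e_j = _edge_indicator(g_j, mode)
    return DiffLabels(
        mode=mode,
        variables=vars_i,
        positives=frozenset(e_i - e_j),
        direction=tuple(direction),
    )


def classification_metrics(
    labels: DiffLabels, scores, ce_mapping: str = "clip"
) -> MetricsReport:
    """Evaluate a difference score map against ground-truth labels.

    AUCROC is the trapezoidal area (equivalently, the probability that a
    random positive outscores a random negative, ties counting 1/2); AUPR is
    the interpolation-free step-wise precision-recall sum. Cross-entropy maps
    a score s to a probability p = clip(max(s, 0), eps, 1-eps) by default
    (negative scores are evidence against membership), or p = (s+1)/2 under
    ``ce_mapping="shift"``. The threshold is scanned over midpoints of
    consecutive distinct scores and chosen to maximize F1, ties broken toward
    the higher threshold.
    """
    if labels.mode != scores.mode:
        raise ValueError("labels and scores have different modes")
    universe = pair_universe(labels.variables, labels.mode)
    y = np.array([labels.get(p) for p in universe], dtype=int)
    s = np.array([scores.get(p) for p in universe], dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos

    aucroc = aupr = None
    if n_pos > 0 and n_neg > 0:
        aucroc = float(roc_auc_score(y, s))
        aupr = float(average_precision_score(y, s))

    if ce_mapping == "clip":
        p = np.clip(np.maximum(s, 0.0), CE_EPS, 1.0 - CE_EPS)
    elif ce_mapping == "shift":
        p = np.clip((s + 1.0) / 2.0, CE_EPS, 1.0 - CE_EPS)
    else:
        raise ValueError(f"unknown ce_mapping {ce_mapping!r}")
    cross_entropy = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1.0 - p)))

    threshold, thr_metrics, zero_div = _f1_threshold_metrics(y, s)
    return MetricsReport(
        aucroc=aucroc,
        aupr=aupr,
        cross_entropy=cross_entropy,
        threshold=threshold,
        n_pos=n_pos,
        n_neg=n_neg,
        zero_division=tuple(zero_div),
        ce_mapping=ce_mapping,
        **thr_metrics,
    )


def _f1_threshold_metrics(y: np.ndarray, s: np.ndarray):
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.array([])
    candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    best_t, best_f1 = candidates[0], -1.0
    for t in candidates:  # ascending: later >= ties win -> higher threshold
        f1 = _f1_at(y, s, t)
        if f1 >= best_f1:
            best_f1, best_t = f1, t
    pred = s > best_t
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    zero_div = []

    def ratio(num, den, name):
        if den == 0:
            zero_div.append(name)
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    ppv = ratio(tp, tp + fp, "ppv")
    npv = ratio(tn, tn + fn, "npv")
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "f1")
    acc = ratio(tp + tn, len(y), "accuracy")
    metrics = {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "f1": f1,
        "accuracy": acc,
    }
    return float(best_t), metrics, zero_div


def _f1_at(y: np.ndarray, s: np.ndarray, t: float) -> float:
    pred = s > t
    tp = np.sum(pred & (y == 1))
    denom = 2 * tp + np.sum(pred & (y == 0)) + np.sum(~pred & (y == 1))
    return float(2 * tp / denom) if denom > 0 else 0.0


def _population_r2(cov: np.ndarray, y_idx: int, x_idx: list[int]) -> float:
    """Population R² of regressing variable y on the set x (unit variances)."""
    if not x_idx:
        return 0.0
    sxx = cov[np.ix_(x_idx, x_idx)]
    sxy = cov[x_idx, y_idx]
    return float(sxy @ np.linalg.solve(sxx, sxy) / cov[y_idx, y_idx])


def effect_size(
    net: LinearGaussianNetwork,
    edge: tuple[str, str],
    cov: np.ndarray | None = None,
) -> float:
    """Cohen's f² of an edge: the parent's incremental explained variance.

    Computed from the implied (population) covariance, so it reflects the
    ground-truth network rather than any sample.
    """
    tail, head = edge
    if edge not in net.edges:
        raise ValueError(f"edge {tail!r}->{head!r} is not in the network")
    if cov is None:
        cov = implied_covariance(net)
    idx = {v: i for i, v in enumerate(net.variables)}
    parents = [idx[p] for p in net.dag.parents(head)]
    reduced = [i for i in parents if i != idx[tail]]
    r2_full = _population_r2(cov, idx[head], parents)
    r2_reduced = _population_r2(cov, idx[head], reduced)
    return max(r2_full - r2_reduced, 0.0) / max(1.0 - r2_full, 1e-12)


def effect_size_table(net: LinearGaussianNetwork) -> dict[tuple[str, str], float]:
    """f² for every edge of the network (single covariance factorization)."""
    cov = implied_covariance(net)
    return {e: effect_size(net, e, cov=cov) for e in sorted(net.edges)}


@dataclass(frozen=True)
class CorrelationResult:
    """Rank correlation between edge effect sizes and difference scores."""

    rho: float | None
    pvalue: float | None
    pairs: tuple[tuple[float, float], ...]  # (f2, score) per edge, for plotting
    flag: str | None = None


def correlate_effectsize_scores(table: dict, scores) -> CorrelationResult:
    """Spearman rank correlation of f² vs score over the edges in ``table``.

    ``table`` should be restricted to the true-different edges of interest.
    Undefined (< 3 edges, or zero variance in either list) results carry a
    flag and rho=None.
    """
    edges = sorted(table)
    pairs = tuple((float(table[e]), float(scores.get(e))) for e in edges)
    if len(pairs) < 3:
        return CorrelationResult(None, None, pairs, flag="fewer than 3 edges")
    f2s = np.array([p[0] for p in pairs])
    sc = np.array([p[1] for p in pairs])
    if np.ptp(f2s) == 0 or np.ptp(sc) == 0:
        return CorrelationResult(None, None, pairs, flag="zero variance")
    rho, pval = stats.spearmanr(f2s, sc)
    return CorrelationResult(float(rho), float(pval), pairs)
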
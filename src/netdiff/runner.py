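"""Simulation-grid and real-data experiment orchestration.

Enumerates the factorial simulation grid (network size/density, number of
differing edges, sample sizes), runs repeated paired-network experiments
per condition with all applicable estimators, aggregates per-condition
metrics, applies the one-standard-deviation best-method tabulation rule,
and implements the real-data permutation protocol that manufactures a
ground-truth network pair from a single observational dataset.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from ._seeds import child_rng, child_seed
from .diff import (
    DiffScoreMap,
    RsbsNotApplicableError,
    diff_frequency_maps,
    frequencies_from_graphs,
    naive_diff,
    resample_graphs,
)
from .discovery import run_discovery
from .evaluate import classification_metrics, true_edge_diff
from .simulate import Dataset, derive_pair, random_network, sample_data

logger = logging.getLogger("netdiff")

__all__ = [
    "GridSpec",
    "Condition",
    "ConditionResult",
    "SMOKE_SPEC",
    "enumerate_conditions",
    "run_condition",
    "best_method_table",
    "permute_and_split",
    "realdata_condition",
]


@dataclass(frozen=True)
class GridSpec:
    """Factorial simulation grid; the defaults reproduce the full study grid.

    ``ne_multipliers`` scale the node count into edge counts; ``nd_fractions``
    scale the edge count into differing-edge counts (ceil applied); ``n2_ratios``
    scale N1 into N2 (ceil applied).
    """

    nv: tuple[int, ...] = (100,)
    ne_multipliers: tuple[float, ...] = (1.5, 2.0, 2.5)
    nd_fractions: tuple[float, ...] = (0.05, 0.1, 0.2, 0.5, 1.0)
    n1: tuple[int, ...] = (500, 1000, 2000, 5000)
    n2_ratios: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0)
    repeats: int = 50
    algorithms: tuple[str, ...] = ("pc", "ges")
    methods: tuple[str, ...] = ("naive", "bs", "rsbs")
    modes: tuple[str, ...] = ("orientation", "skeleton")
    directions: tuple[str, ...] = ("12", "21")
    b: int = 50
    undirected_policy: str = "both"
    ce_mapping: str = "clip"
    algorithm_params: dict = field(default_factory=dict)


#: reduced-scale preset for laptop-sized runs; clearly labeled, never a
#: silent substitute for the full grid
SMOKE_SPEC = GridSpec(
    nv=(20,),
    ne_multipliers=(2.0,),
    nd_fractions=(0.2,),
    n1=(1000,),
    n2_ratios=(0.2, 0.5, 1.0),
    repeats=10,
    algorithms=("pc",),
    b=25,
)


@dataclass(frozen=True)
class Condition:
    nv: int
    ne: int
    nd: int
    n1: int
    n2: int

    @property
    def rsbs_applicable(self) -> bool:
        return self.n1 != self.n2

    def as_dict(self) -> dict:
        return {"nv": self.nv, "ne": self.ne, "nd": self.nd, "n1": self.n1, "n2": self.n2}


@dataclass
class ConditionResult:
    """Per-repeat metric rows plus per-metric aggregates for one condition."""

    condition: Condition
    rows: pd.DataFrame  # one row per repeat x method x direction x mode x algorithm

    def aggregate(self) -> pd.DataFrame:
        keys = ["algorithm", "method", "direction", "mode"]
        metrics = ["aucroc", "aupr", "cross_entropy", "f1"]
        return self.rows.groupby(keys)[metrics].agg(["mean", "std"]).reset_index()


def enumerate_conditions(spec: GridSpec) -> list[Condition]:
    """Cartesian product of the grid, in deterministic order.

    Dataset-pair count is ``len(conditions) * spec.repeats``.
    """
    if not (spec.nv and spec.ne_multipliers and spec.nd_fractions and spec.n1 and spec.n2_ratios):
        raise ValueError("grid spec has an empty axis")
    out = []
    for nv, mult, frac, n1, ratio in product(
        spec.nv, spec.ne_multipliers, spec.nd_fractions, spec.n1, spec.n2_ratios
    ):
        ne = int(round(mult * nv))
        out.append(
            Condition(
                nv=nv,
                ne=ne,
                nd=math.ceil(frac * ne),
                n1=n1,
                n2=math.ceil(ratio * n1),
            )
        )
    return out


def _condition_seed(master_seed: int, cond: Condition, repeat: int) -> int:
    return child_seed(master_seed, "cond", cond.nv, cond.ne, cond.nd, cond.n1, cond.n2, repeat)


def _score_maps_for_repeat(
    d1: Dataset,
    d2: Dataset,
    algorithm: str,
    params: dict | None,
    spec: GridSpec,
    seed: int,
) -> dict[tuple[str, str, str], DiffScoreMap]:
    """All (method, direction, mode) score maps for one dataset pair.

    Resample discovery runs are shared across modes and directions: bootstrap
    and subsample graphs are computed once per dataset and indicator maps for
    both modes are read off the same runs.
    """
    maps: dict[tuple[str, str, str], DiffScoreMap] = {}
    policy = spec.undirected_policy
    methods = spec.methods

    if "naive" in methods:
        for mode in spec.modes:
            maps[("naive", "12", mode)] = naive_diff(d1, d2, algorithm, params, mode, policy)
            maps[("naive", "21", mode)] = naive_diff(d2, d1, algorithm, params, mode, policy)

    need_bs = "bs" in methods
    need_rsbs = "rsbs" in methods and d1.n != d2.n
    if not (need_bs or need_rsbs):
        return maps

    n_small = min(d1.n, d2.n)
    d_large = d1 if d1.n >= d2.n else d2
    need_boot1 = need_bs or (need_rsbs and d_large is d2)
    boot1 = resample_graphs(d1, algorithm, params, spec.b, seed) if need_boot1 else None
    boot2 = resample_graphs(d2, algorithm, params, spec.b, seed)
    sub_large = (
        resample_graphs(d_large, algorithm, params, spec.b, seed, n_target=n_small)
        if need_rsbs
        else None
    )

    for mode in spec.modes:
        f2_bs = frequencies_from_graphs(boot2, mode, policy)
        if need_bs:
            f1_bs = frequencies_from_graphs(boot1, mode, policy)
            maps[("bs", "12", mode)] = diff_frequency_maps(f1_bs, f2_bs, "bs")
            maps[("bs", "21", mode)] = diff_frequency_maps(f2_bs, f1_bs, "bs")
        if need_rsbs:
            # D1 is the larger dataset in the study design; score it by
            # equal-size subsamples and D2 (smaller) by bootstrap
            f_large_rs = frequencies_from_graphs(sub_large, mode, policy)
            if d_large is d1:
                maps[("rsbs", "12", mode)] = diff_frequency_maps(f_large_rs, f2_bs, "rsbs")
                maps[("rsbs", "21", mode)] = diff_frequency_maps(f2_bs, f_large_rs, "rsbs")
            else:
                f1_for_rs = frequencies_from_graphs(boot1, mode, policy)
                maps[("rsbs", "12", mode)] = diff_frequency_maps(f1_for_rs, f_large_rs, "rsbs")
                maps[("rsbs", "21", mode)] = diff_frequency_maps(f_large_rs, f1_for_rs, "rsbs")
    return maps


def run_condition(condition: Condition, spec: GridSpec, master_seed: int) -> ConditionResult:
    """Run all repeats of one simulation condition.

    Per repeat: simulate a network pair, sample D1 (from G1) and D2 (from
    G2), run every applicable method, and evaluate both directions and both
    modes. Fully deterministic given ``master_seed``.
    """
    rows = []
    for repeat in range(spec.repeats):
        seed = _condition_seed(master_seed, condition, repeat)
        t0 = time.perf_counter()
        g1 = random_network(condition.nv, condition.ne, child_seed(seed, "g1"))
        pair = derive_pair(g1, condition.nd, child_seed(seed, "pair"))
        d1 = sample_data(pair.g1, condition.n1, child_seed(seed, "d1"))
        d2 = sample_data(pair.g2, condition.n2, child_seed(seed, "d2"))
        graphs = {"12": (pair.g1, pair.g2), "21": (pair.g2, pair.g1)}
        for algorithm in spec.algorithms:
            params = spec.algorithm_params.get(algorithm)
            try:
                maps = _score_maps_for_repeat(d1, d2, algorithm, params, spec, seed)
            except Exception:
                logger.exception(
                    "repeat aborted: condition=%s repeat=%d algorithm=%s",
                    condition,
                    repeat,
                    algorithm,
                )
                raise
            for (method, direction, mode), scores in maps.items():
                if direction not in spec.directions:
                    continue
                ga, gb = graphs[direction]
                labels = true_edge_diff(ga, gb, mode, direction=tuple(direction))
                report = classification_metrics(labels, scores, spec.ce_mapping)
                rows.append(
                    {
                        **condition.as_dict(),
                        "repeat": repeat,
                        "algorithm": algorithm,
                        "method": method,
                        "direction": direction,
                        "mode": mode,
                        **report.as_dict(),
                    }
                )
        logger.info(
            "condition %s repeat %d done in %.2fs", condition, repeat, time.perf_counter() - t0
        )
    return ConditionResult(condition=condition, rows=pd.DataFrame(rows))


LOWER_IS_BETTER = {"cross_entropy"}


def best_method_table(
    results: list[ConditionResult],
    metric: str = "aucroc",
    direction: str = "12",
    mode: str = "orientation",
    algorithm: str | None = None,
) -> pd.DataFrame:
    """Percentage of conditions on which each method is (tied-)best.

    Per condition, the best method is the one with the best mean metric;
    any method whose mean lies within one standard deviation of the best
    (the best method's SD) is also marked best. Percentages for rsbs are
    over its applicable conditions only. Conditions missing the metric are
    excluded and counted in the ``excluded`` column.
    """
    if not results:
        raise ValueError("no condition results given")
    marks: dict[str, int] = {}
    applicable: dict[str, int] = {}
    excluded = 0
    for res in results:
        rows = res.rows
        sel = (rows["direction"] == direction) & (rows["mode"] == mode)
        if algorithm is not None:
            sel &= rows["algorithm"] == algorithm
        sub = rows[sel].dropna(subset=[metric])
        if sub.empty:
            excluded += 1
            continue
        stats = sub.groupby("method")[metric].agg(["mean", "std"]).fillna({"std": 0.0})
        if len(stats) < 1:
            excluded += 1
            continue
        for m in stats.index:
            applicable[m] = applicable.get(m, 0) + 1
        lower = metric in LOWER_IS_BETTER
        best = stats["mean"].idxmin() if lower else stats["mean"].idxmax()
        bmean, bsd = stats.loc[best, "mean"], stats.loc[best, "std"]
        cutoff = bmean + bsd if lower else bmean - bsd
        for m in stats.index:
            ok = stats.loc[m, "mean"] <= cutoff if lower else stats.loc[m, "mean"] >= cutoff
            if ok:
                marks[m] = marks.get(m, 0) + 1
    records = [
        {
            "method": m,
            "metric": metric,
            "direction": direction,
            "mode": mode,
            "n_conditions": applicable[m],
            "n_best": marks.get(m, 0),
            "percent_best": 100.0 * marks.get(m, 0) / applicable[m],
            "excluded": excluded,
        }
        for m in sorted(applicable)
    ]
    return pd.DataFrame(records)


def permute_and_split(
    d0: Dataset, n_permute: int, seed: int
) -> tuple[Dataset, Dataset, tuple[tuple[str, ...], tuple[str, ...]]]:
    """Manufacture a ground-truth-different dataset pair by permutation.

    Two disjoint variable sets of size ``n_permute`` are drawn; each full-size
    copy of ``d0`` has its own set's columns independently row-shuffled, which
    destroys every dependence involving those variables while preserving each
    column's marginal distribution.
    """
    if n_permute < 1:
        raise ValueError("n_permute must be positive")
    if 2 * n_permute > d0.n_vars:
        raise ValueError(
            f"need 2*{n_permute} distinct variables but dataset has {d0.n_vars}"
        )
    rng = child_rng(seed, "permute-select")
    chosen = rng.choice(d0.n_vars, size=2 * n_permute, replace=False)
    set1 = tuple(d0.variables[i] for i in chosen[:n_permute])
    set2 = tuple(d0.variables[i] for i in chosen[n_permute:])

    def shuffle_columns(names: tuple[str, ...], tag: str) -> Dataset:
        values = d0.values.copy()
        idx = {v: i for i, v in enumerate(d0.variables)}
        for k, name in enumerate(names):
            perm = child_rng(seed, "permute-col", tag, k).permutation(d0.n)
            values[:, idx[name]] = values[perm, idx[name]]
        return Dataset(values=values, variables=d0.variables)

    return shuffle_columns(set1, "d1"), shuffle_columns(set2, "d2"), (set1, set2)


def realdata_condition(
    d1_full: Dataset,
    d2_full: Dataset,
    seed: int,
    ratios: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0),
    algorithm: str = "ges",
    params: dict | None = None,
    b: int = 50,
    modes: tuple[str, ...] = ("orientation", "skeleton"),
    methods: tuple[str, ...] = ("naive", "bs", "rsbs"),
    subsample_fraction: float = 0.6,
    undirected_policy: str = "both",
    ce_mapping: str = "clip",
) -> pd.DataFrame:
    """Real-data protocol for one manufactured pair.

    Reference graphs are learned from the full datasets and their difference
    is the evaluation gold standard. D1 is a without-replacement subsample of
    ``subsample_fraction`` of d1_full (N1); D2 is subsampled from d2_full at
    each ratio of N1. rsbs is recorded as not applicable at ratio 1.
    """
    g1_ref = run_discovery(d1_full, algorithm, params)
    g2_ref = run_discovery(d2_full, algorithm, params)
    n1 = math.ceil(subsample_fraction * d1_full.n)
    rng1 = child_rng(seed, "real-d1")
    d1 = Dataset(
        values=d1_full.values[rng1.choice(d1_full.n, size=n1, replace=False)],
        variables=d1_full.variables,
    )
    spec = GridSpec(
        methods=tuple(methods),
        modes=tuple(modes),
        b=b,
        undirected_policy=undirected_policy,
        ce_mapping=ce_mapping,
    )
    rows = []
    for ratio in ratios:
        n2 = math.ceil(ratio * n1)
        if n2 > d2_full.n:
            raise ValueError(
                f"ratio {ratio} needs n2={n2} rows but d2_full has only {d2_full.n}"
            )
        rng2 = child_rng(seed, "real-d2", int(round(1000 * ratio)))
        d2 = Dataset(
            values=d2_full.values[rng2.choice(d2_full.n, size=n2, replace=False)],
            variables=d2_full.variables,
        )
        maps = _score_maps_for_repeat(d1, d2, algorithm, params, spec, child_seed(seed, "real"))
        graphs = {"12": (g1_ref, g2_ref), "21": (g2_ref, g1_ref)}
        for (method, direction, mode), scores in maps.items():
            ga, gb = graphs[direction]
            labels = true_edge_diff(ga, gb, mode, direction=tuple(direction))
            report = classification_metrics(labels, scores, ce_mapping)
            rows.append(
                {
                    "n1": n1,
                    "n2": n2,
                    "ratio": ratio,
                    "algorithm": algorithm,
                    "method": method,
                    "direction": direction,
                    "mode": mode,
                    **report.as_dict(),
                }
            )
    return pd.DataFrame(rows)
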
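"""Paired linear-Gaussian network simulator.

Generates random DAGs, parameterizes them as linear structural equation
models whose every variable has marginal variance exactly 1, derives a
second network differing in a controlled number of edges, and samples
i.i.d. datasets from either network.

The structural equation for a node ``V`` with parents ``Pa(V)`` is

    V = sum_p beta_p * P_p + eps,   eps ~ N(0, sigma_noise^2)

with ``beta_p = b * u``, ``P(b=1) = 0.6``, ``P(b=-1) = 0.4`` and
``u ~ Uniform(0.1, 0.35)``. ``sigma_noise`` is solved per node, in
topological order, so that the implied marginal variance of every variable
is 1; parentless nodes are standard normal. When a node's pre-noise
variance already exceeds 1 no valid noise scale exists and the attempt is
discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._seeds import child_rng, child_seed

__all__ = [
    "DagStructure",
    "LinearGaussianNetwork",
    "NetworkPair",
    "Dataset",
    "VarianceOverflowError",
    "generate_random_dag",
    "parameterize_sem",
    "random_network",
    "implied_covariance",
    "derive_pair",
    "sample_data",
    "COEF_MIN",
    "COEF_MAX",
    "POSITIVE_SIGN_PROB",
]

COEF_MIN = 0.1
COEF_MAX = 0.35
POSITIVE_SIGN_PROB = 0.6

#: tolerance for the unit-marginal-variance invariant
VARIANCE_TOL = 1e-8


class VarianceOverflowError(RuntimeError):
    """A node's pre-noise variance exceeds 1, so unit marginal variance is unreachable."""

    def __init__(self, node: str, variance: float):
        self.node = node
        self.variance = variance
        super().__init__(
            f"pre-noise variance of node {node!r} is {variance:.6f} > 1; "
            "unit marginal variance is not achievable"
        )


@dataclass(frozen=True)
class DagStructure:
    """A directed acyclic graph with an explicit generation (topological) order."""

    variables: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    order: tuple[str, ...]  # topological order used at generation time

    def __post_init__(self) -> None:
        pos = {v: i for i, v in enumerate(self.order)}
        if set(self.order) != set(self.variables):
            raise ValueError("order must be a permutation of variables")
        for tail, head in self.edges:
            if tail == head:
                raise ValueError(f"self-loop on {tail!r}")
            if pos[tail] >= pos[head]:
                raise ValueError(f"edge {tail!r}->{head!r} violates the stored order")

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(t for t, h in self.edges if h == node))

    def parent_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {v: [] for v in self.variables}
        for tail, head in sorted(self.edges):
            out[head].append(tail)
        return out


@dataclass(frozen=True)
class LinearGaussianNetwork:
    """A DAG plus edge coefficients and per-node noise scales (unit marginals)."""

    dag: DagStructure
    coefficients: dict[tuple[str, str], float]
    noise_sd: dict[str, float]

    @property
    def variables(self) -> tuple[str, ...]:
        return self.dag.variables

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return self.dag.edges

    def validate(self, tol: float = VARIANCE_TOL) -> None:
        for edge, beta in self.coefficients.items():
            if not (COEF_MIN <= abs(beta) <= COEF_MAX):
                raise ValueError(f"|beta| for {edge} out of [{COEF_MIN}, {COEF_MAX}]: {beta}")
        cov = implied_covariance(self)
        dev = np.abs(np.diag(cov) - 1.0).max()
        if dev > tol:
            raise ValueError(f"marginal variances deviate from 1 by {dev:.3e}")


@dataclass(frozen=True)
class NetworkPair:
    """Two networks sharing all but a controlled set of edges.

    ``deleted_edges`` are in g1 only, ``added_edges`` in g2 only; shared edges
    carry bitwise-identical coefficients.
    """

    g1: LinearGaussianNetwork
    g2: LinearGaussianNetwork
    deleted_edges: frozenset[tuple[str, str]]
    added_edges: frozenset[tuple[str, str]]
    metadata: dict = field(default_factory=dict)

    @property
    def n_diff(self) -> int:
        return len(self.deleted_edges) + len(self.added_edges)


@dataclass(frozen=True)
class Dataset:
    """An n x Nv matrix of continuous observations with named columns."""

    values: np.ndarray
    variables: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != len(self.variables):
            raise ValueError("values must be an n x Nv matrix matching variables")
        if v.shape[0] < 1:
            raise ValueError("dataset must contain at least one row")
        if np.isnan(v).any():
            raise ValueError("dataset contains missing values")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=list(self.variables))


def _default_names(n_vars: int) -> tuple[str, ...]:
    width = len(str(n_vars))
    return tuple(f"V{i:0{width}d}" for i in range(1, n_vars + 1))


def generate_random_dag(
    n_vars: int,
    n_edges: int,
    seed: int,
    names: Sequence[str] | None = None,
) -> DagStructure:
    """Draw a uniformly random topological order, then sample ``n_edges``
    pairs uniformly without replacement among the order-respecting pairs."""
    if n_vars < 1:
        raise ValueError("n_vars must be positive")
    max_edges = n_vars * (n_vars - 1) // 2
    if not (0 <= n_edges <= max_edges):
        raise ValueError(
            f"n_edges={n_edges} out of range: a DAG on {n_vars} nodes holds at most "
            f"{max_edges} edges"
        )
    variables = tuple(names) if names is not None else _default_names(n_vars)
    if len(set(variables)) != n_vars:
        raise ValueError("variable names must be unique and match n_vars")
    rng = child_rng(seed, "dag")
    order = tuple(variables[i] for i in rng.permutation(n_vars))
    candidates = [(order[i], order[j]) for i in range(n_vars) for j in range(i + 1, n_vars)]
    chosen = rng.choice(len(candidates), size=n_edges, replace=False)
    edges = frozenset(candidates[k] for k in chosen)
    return DagStructure(variables=variables, edges=edges, order=order)


def _solve_noise(
    dag: DagStructure, coefficients: dict[tuple[str, str], float]
) -> dict[str, float]:
    """Solve sigma_noise per node (topological order) for unit marginal variance.

    Maintains the implied covariance over already-processed nodes; raises
    VarianceOverflowError on the first node whose pre-noise variance exceeds 1.
    """
    order = dag.order
    idx = {v: i for i, v in enumerate(order)}
    k = len(order)
    cov = np.zeros((k, k))
    parent_map = dag.parent_map()
    noise_sd: dict[str, float] = {}
    for v in order:
        i = idx[v]
        parents = parent_map[v]
        if not parents:
            cov[i, i] = 1.0
            noise_sd[v] = 1.0
            continue
        p_idx = np.array([idx[p] for p in parents])
        beta = np.array([coefficients[(p, v)] for p in parents])
        var_pre = float(beta @ cov[np.ix_(p_idx, p_idx)] @ beta)
        if var_pre > 1.0 + VARIANCE_TOL:
            raise VarianceOverflowError(v, var_pre)
        # covariance with every already-processed node
        cross = cov[:, p_idx] @ beta
        cov[i, :] = cross
        cov[:, i] = cross
        cov[i, i] = 1.0
        noise_sd[v] = math.sqrt(max(1.0 - var_pre, 0.0))
    return noise_sd


def _draw_coefficients(
    edges: Iterable[tuple[str, str]], rng: np.random.Generator
) -> dict[tuple[str, str], float]:
    edges = sorted(edges)
    signs = np.where(rng.random(len(edges)) < POSITIVE_SIGN_PROB, 1.0, -1.0)
    mags = rng.uniform(COEF_MIN, COEF_MAX, len(edges))
    return {e: float(s * u) for e, s, u in zip(edges, signs, mags)}


def parameterize_sem(
    dag: DagStructure, seed: int, max_attempts: int = 100
) -> LinearGaussianNetwork:
    """Draw edge coefficients (b*u law) and solve noise scales for unit marginals.

    Each attempt draws a fresh coefficient set for the given DAG; attempts for
    which some node's pre-noise variance exceeds 1 are discarded. After
    ``max_attempts`` failures the last offending node is reported.
    """
    last: VarianceOverflowError | None = None
    for attempt in range(max_attempts):
        rng = child_rng(seed, "coeffs", attempt)
        coefficients = _draw_coefficients(dag.edges, rng)
        try:
            noise_sd = _solve_noise(dag, coefficients)
        except VarianceOverflowError as err:
            last = err
            continue
        return LinearGaussianNetwork(dag=dag, coefficients=coefficients, noise_sd=noise_sd)
    raise VarianceOverflowError(last.node, last.variance) if last else RuntimeError(
        "max_attempts must be positive"
    )


def random_network(
    n_vars: int, n_edges: int, seed: int, max_attempts: int = 100
) -> LinearGaussianNetwork:
    """Fresh-DAG-per-attempt generation: when a parameterization overflows the
    unit-variance budget, a new DAG is generated and parameterized anew."""
    last: VarianceOverflowError | None = None
    for attempt in range(max_attempts):
        dag = generate_random_dag(n_vars, n_edges, child_seed(seed, "net-dag", attempt))
        try:
            return parameterize_sem(dag, child_seed(seed, "net-par", attempt), max_attempts=1)
        except VarianceOverflowError as err:
            last = err
    assert last is not None
    raise last


def coefficient_matrix(net: LinearGaussianNetwork) -> np.ndarray:
    """A with A[i, p] = beta for edge p -> i, indexed by net.variables order."""
    idx = {v: i for i, v in enumerate(net.variables)}
    a = np.zeros((len(idx), len(idx)))
    for (tail, head), beta in net.coefficients.items():
        a[idx[head], idx[tail]] = beta
    return a


def implied_covariance(net: LinearGaussianNetwork) -> np.ndarray:
    """Exact covariance of the joint distribution: (I-A)^-1 D (I-A)^-T.

    Rows/columns follow ``net.variables``. For a valid network the diagonal
    is all ones.
    """
    a = coefficient_matrix(net)
    d = np.diag([net.noise_sd[v] ** 2 for v in net.variables])
    inv = np.linalg.inv(np.eye(a.shape[0]) - a)
    return inv @ d @ inv.T


def derive_pair(
    g1: LinearGaussianNetwork,
    n_diff: int,
    seed: int,
    max_attempts: int = 100,
) -> NetworkPair:
    """Derive g2 from g1 by deleting ceil(n_diff/2) edges and adding
    floor(n_diff/2) order-respecting non-edges.

    Shared edges keep g1's coefficients bitwise; added-edge coefficients follow
    the same b*u law; all noise scales of g2 are re-solved so its marginals are
    unit variance. On variance overflow the added-edge coefficients are
    redrawn up to ``max_attempts`` times, then a fresh addition set is drawn.
    """
    if n_diff < 1:
        raise ValueError("n_diff must be positive")
    dag1 = g1.dag
    n_delete = -(-n_diff // 2)  # ceil
    n_add = n_diff // 2
    edges1 = sorted(dag1.edges)
    pos = {v: i for i, v in enumerate(dag1.order)}
    candidates = sorted(
        (t, h)
        for i, t in enumerate(dag1.order)
        for h in dag1.order[i + 1 :]
        if (t, h) not in dag1.edges
    )
    if n_delete > len(edges1) or n_add > len(candidates):
        raise ValueError(
            f"n_diff={n_diff} infeasible: {len(edges1)} edges deletable, "
            f"{len(candidates)} order-respecting non-edges available"
        )
    del_rng = child_rng(seed, "delete")
    deleted = frozenset(
        edges1[k] for k in del_rng.choice(len(edges1), size=n_delete, replace=False)
    )
    kept_coeffs = {e: b for e, b in g1.coefficients.items() if e not in deleted}

    last: VarianceOverflowError | None = None
    for add_round in range(max_attempts):
        add_rng = child_rng(seed, "add-set", add_round)
        added = frozenset(
            candidates[k] for k in add_rng.choice(len(candidates), size=n_add, replace=False)
        )
        edges2 = frozenset(kept_coeffs) | added
        dag2 = DagStructure(variables=dag1.variables, edges=edges2, order=dag1.order)
        for coef_round in range(max_attempts):
            coef_rng = child_rng(seed, "add-coeffs", add_round, coef_round)
            coefficients = dict(kept_coeffs)
            coefficients.update(_draw_coefficients(added, coef_rng))
            try:
                noise_sd = _solve_noise(dag2, coefficients)
            except VarianceOverflowError as err:
                last = err
                continue
            g2 = LinearGaussianNetwork(dag=dag2, coefficients=coefficients, noise_sd=noise_sd)
            return NetworkPair(
                g1=g1,
                g2=g2,
                deleted_edges=deleted,
                added_edges=added,
                metadata={
                    "seed": int(seed),
                    "n_diff": int(n_diff),
                    "n_deleted": n_delete,
                    "n_added": n_add,
                },
            )
    assert last is not None
    raise last


def sample_data(net: LinearGaussianNetwork, n: int, seed: int) -> Dataset:
    """Draw ``n`` i.i.d. rows by evaluating the SEM in topological order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = child_rng(seed, "sample")
    order = net.dag.order
    idx = {v: i for i, v in enumerate(net.variables)}
    parent_map = net.dag.parent_map()
    x = np.empty((n, len(net.variables)))
    noise = rng.standard_normal((n, len(net.variables)))
    for v in order:
        i = idx[v]
        col = noise[:, i] * net.noise_sd[v]
        for p in parent_map[v]:
            col = col + net.coefficients[(p, v)] * x[:, idx[p]]
        x[:, i] = col
    return Dataset(values=x, variables=net.variables)
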
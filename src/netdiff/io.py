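"""Readers/writers for serialized artifacts and run configuration.

Datasets are CSV with a header row; networks are edge-list TSV
(tail, head, coefficient) with a JSON sidecar (variables, noise scales,
metadata); estimated patterns are TSV of (node1, node2, state) with state
tokens ``-->`` and ``---``; score maps are TSV of (node1, node2, score)
with a ``#``-comment provenance header. All artifacts round-trip losslessly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diff import DiffScoreMap, EdgeScoreMap
from .discovery import EstimatedGraph
from .simulate import DagStructure, Dataset, LinearGaussianNetwork

__all__ = [
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "write_network",
    "read_network",
    "write_graph",
    "read_graph",
    "write_scores",
    "read_scores",
    "load_config",
    "save_config",
]


@dataclass
class RunConfig:
    """Run settings with documented defaults; round-trips via YAML/JSON."""

    algorithm: str = "pc"
    algorithm_params: dict = field(default_factory=dict)
    methods: tuple[str, ...] = ("naive", "bs", "rsbs")
    b: int = 50
    modes: tuple[str, ...] = ("orientation", "skeleton")
    undirected_policy: str = "both"
    ce_mapping: str = "clip"
    seed: int = 0

    def as_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        d["modes"] = list(self.modes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("methods", "modes"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.as_dict(), fh, sort_keys=True)


def read_dataset(path: str | Path) -> Dataset:
    """Read a CSV dataset (header row, numeric body) with cell-level validation."""
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh), [])
    dups = sorted({h for h in header if header.count(h) > 1})
    if dups:
        raise ValueError(f"duplicate column headers in {path}: {dups}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric value {df[col][row]!r} at row {row + 1}, column {col!r} in {path}"
            )
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ValueError(f"missing value at row {row + 1}, column {col!r} in {path}")
        df[col] = numeric
    return Dataset(values=df.to_numpy(dtype=np.float64), variables=tuple(df.columns))


def write_dataset(data: Dataset, path: str | Path) -> None:
    # %.17g keeps the binary64 values bit-identical across a round-trip
    data.to_frame().to_csv(path, index=False, float_format="%.17g")


def write_network(net: LinearGaussianNetwork, path: str | Path, metadata: dict | None = None) -> None:
    """Edge-list TSV plus JSON sidecar (<path>.json) for variables/noise/metadata."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("tail\thead\tcoefficient\n")
        for tail, head in sorted(net.edges):
            fh.write(f"{tail}\t{head}\t{net.coefficients[(tail, head)]!r}\n")
    sidecar = {
        "variables": list(net.variables),
        "order": list(net.dag.order),
        "noise_sd": {v: net.noise_sd[v] for v in net.variables},
        "metadata": metadata or {},
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_network(path: str | Path) -> LinearGaussianNetwork:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    coefficients: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "tail\thead\tcoefficient":
            raise ValueError(f"unexpected network header in {path}: {header!r}")
        for line in fh:
            tail, head, coef = line.rstrip("\n").split("\t")
            coefficients[(tail, head)] = float(coef)
    dag = DagStructure(
        variables=tuple(sidecar["variables"]),
        edges=frozenset(coefficients),
        order=tuple(sidecar["order"]),
    )
    return LinearGaussianNetwork(
        dag=dag,
        coefficients=coefficients,
        noise_sd={v: float(s) for v, s in sidecar["noise_sd"].items()},
    )


def write_graph(g: EstimatedGraph, path: str | Path) -> None:
    """Estimated pattern as TSV of (node1, node2, state in {-->, ---})."""
    with open(path, "w") as fh:
        fh.write("# variables: " + ",".join(g.variables) + "\n")
        fh.write("node1\tnode2\tstate\n")
        for tail, head in sorted(g.directed):
            fh.write(f"{tail}\t{head}\t-->\n")
        for a, b in sorted(g.undirected):
            fh.write(f"{a}\t{b}\t---\n")


def read_graph(path: str | Path) -> EstimatedGraph:
    directed, undirected = set(), set()
    variables: tuple[str, ...] = ()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# variables: "):
                variables = tuple(line[len("# variables: ") :].split(","))
                continue
            if not line or line.startswith(("#", "node1\t")):
                continue
            a, b, state = line.split("\t")
            if state == "-->":
                directed.add((a, b))
            elif state == "---":
                undirected.add((a, b))
            else:
                raise ValueError(f"unknown edge state {state!r} in {path}")
    return EstimatedGraph(
        variables=variables, directed=frozenset(directed), undirected=frozenset(undirected)
    )


def write_scores(scores: EdgeScoreMap | DiffScoreMap, path: str | Path, provenance: dict | None = None) -> None:
    """Score map as TSV with a provenance comment header."""
    meta = {"mode": scores.mode, "variables": ",".join(scores.variables)}
    if isinstance(scores, DiffScoreMap):
        meta["method"] = scores.method
        meta["direction"] = ",".join(scores.direction)
    elif scores.resample_count is not None:
        meta["resample_count"] = scores.resample_count
    meta.update(provenance or {})
    with open(path, "w") as fh:
        for key in sorted(meta):
            fh.write(f"# {key}: {meta[key]}\n")
        fh.write("node1\tnode2\tscore\n")
        for (a, b), s in sorted(scores.scores.items()):
            fh.write(f"{a}\t{b}\t{s!r}\n")


def read_scores(path: str | Path) -> EdgeScoreMap | DiffScoreMap:
    meta: dict[str, str] = {}
    scores: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, value = line[2:].partition(": ")
                meta[key] = value
                continue
            if not line or line.startswith("node1\t"):
                continue
            a, b, s = line.split("\t")
            scores[(a, b)] = float(s)
    variables = tuple(meta["variables"].split(","))
    if "method" in meta:
        return DiffScoreMap(
            mode=meta["mode"],
            method=meta["method"],
            variables=variables,
            scores=scores,
            direction=tuple(meta.get("direction", "i,j").split(",")),
        )
    rc = meta.get("resample_count")
    return EdgeScoreMap(
        mode=meta["mode"],
        variables=variables,
        scores=scores,
        resample_count=int(rc) if rc is not None else None,
    )
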
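"""Plain-text readers and writers for the pipeline's objects.

Graphs travel as whitespace-delimited undirected edge lists (0-based node
ids) with a companion truth table for benchmarks; correlation and
membership matrices as delimited dense tables; datasets as one ROI x time
matrix per run in an animal/session/run directory tree with a YAML
manifest recording metadata and seeds.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BinaryGraph, CorrelationMatrix, Dataset, MembershipMatrix, RunRecord

__all__ = [
    "write_edge_list",
    "read_edge_list",
    "write_truth_table",
    "read_truth_table",
    "write_membership",
    "read_membership",
    "write_matrix",
    "read_matrix",
    "write_dataset",
    "read_dataset",
    "write_config",
    "read_config",
]


def write_edge_list(graph: BinaryGraph, path: str | Path) -> None:
    np.savetxt(path, graph.edge_list(), fmt="%d")


def read_edge_list(path: str | Path, n_nodes: int | None = None) -> BinaryGraph:
    edges = np.loadtxt(path, dtype=int, ndmin=2)
    if edges.size == 0:
        raise ValueError(f"no edges in {path}")
    n = int(edges.max()) + 1 if n_nodes is None else n_nodes
    adj = np.zeros((n, n), dtype=np.int8)
    adj[edges[:, 0], edges[:, 1]] = 1
    adj |= adj.T
    return BinaryGraph(adj)


def write_truth_table(truth: np.ndarray, path: str | Path) -> None:
    """Rows (node, community, membership) for every nonzero affiliation."""
    i, k = np.nonzero(truth)
    pd.DataFrame(
        {"node": i, "community": k, "membership": np.asarray(truth)[i, k]}
    ).to_csv(path, sep="\t", index=False)


def read_truth_table(
    path: str | Path, n_nodes: int, n_communities: int
) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    truth = np.zeros((n_nodes, n_communities))
    truth[df["node"], df["community"]] = df["membership"]
    return truth


def write_membership(m: MembershipMatrix, path: str | Path, **meta) -> None:
    """Delimited node x community table with a commented metadata header."""
    header = {
        "K": m.K,
        "condition": m.condition,
        "level": m.level,
        **meta,
    }
    with open(path, "w") as fh:
        for key, val in header.items():
            if val is not None:
                fh.write(f"# {key}: {val}\n")
        df = pd.DataFrame(
            m.pi, columns=[f"community_{k}" for k in range(m.K)]
        )
        df.insert(0, "node", np.arange(m.n_nodes))
        df.to_csv(fh, sep="\t", index=False)


def read_membership(path: str | Path) -> MembershipMatrix:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t")
    pi = df.drop(columns="node").to_numpy()
    return MembershipMatrix(
        pi, condition=meta.get("condition"), level=meta.get("level")
    )


def write_matrix(values: np.ndarray | CorrelationMatrix, path: str | Path) -> None:
    vals = values.values if isinstance(values, CorrelationMatrix) else values
    np.savetxt(path, vals, delimiter="\t")


def read_matrix(path: str | Path, as_correlation: bool = False):
    vals = np.loadtxt(path, delimiter="\t")
    return CorrelationMatrix(vals) if as_correlation else vals


def write_dataset(dataset: Dataset, root: str | Path, seed: int | None = None) -> None:
    """Directory tree animal/session/run with signal (and motion) tables
    plus a manifest recording metadata."""
    root = Path(root)
    manifest: dict = {"seed": seed, "runs": []}
    for run in dataset:
        d = root / run.animal_id / run.session_id / run.run_id
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / "signal.tsv", run.signal, delimiter="\t")
        if run.motion is not None:
            np.savetxt(d / "motion.tsv", run.motion, delimiter="\t")
        manifest["runs"].append(
            {
                "animal_id": run.animal_id,
                "session_id": run.session_id,
                "run_id": run.run_id,
                "condition": run.condition,
                "fs": float(run.fs),
                "has_motion": run.motion is not None,
            }
        )
    with open(root / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_dataset(root: str | Path) -> Dataset:
    root = Path(root)
    with open(root / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    runs = []
    for entry in manifest["runs"]:
        d = root / entry["animal_id"] / entry["session_id"] / entry["run_id"]
        signal = np.loadtxt(d / "signal.tsv", delimiter="\t", ndmin=2)
        motion = (
            np.loadtxt(d / "motion.tsv", delimiter="\t")
            if entry["has_motion"]
            else None
        )
        runs.append(
            RunRecord(
                animal_id=entry["animal_id"],
                session_id=entry["session_id"],
                run_id=entry["run_id"],
                condition=entry["condition"],
                fs=entry["fs"],
                signal=signal,
                motion=motion,
            )
        )
    return Dataset(runs)


def write_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
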
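"""Shared data containers for the overlapping-network pipeline.

The pipeline's central objects are small, validated wrappers around numpy
arrays: per-run ROI x time signals (:class:`RunRecord`), their hierarchical
collection (:class:`Dataset`), symmetric correlation matrices
(:class:`CorrelationMatrix`), fixed-density binary graphs
(:class:`BinaryGraph`), and node x community membership matrices on the
probability simplex (:class:`MembershipMatrix`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "RunRecord",
    "Dataset",
    "CorrelationMatrix",
    "BinaryGraph",
    "MembershipMatrix",
    "BootstrapResult",
    "SIMPLEX_ATOL",
]

#: tolerance on row sums of membership matrices
SIMPLEX_ATOL = 1e-9

CONDITIONS = ("bold", "ca_slow", "ca_fast")


@dataclass
class RunRecord:
    """One acquisition run: an ROI x time signal matrix plus metadata.

    Parameters
    ----------
    animal_id, session_id, run_id
        Hierarchy identifiers (animal > session > run).
    condition
        Imaging condition label, one of ``bold``, ``ca_slow``, ``ca_fast``.
    fs
        Sampling rate in Hz.
    signal
        Array of shape (n_rois, n_timepoints).
    motion
        Optional per-frame displacement trace in mm, length n_timepoints.
    """

    animal_id: str
    session_id: str
    run_id: str
    condition: str
    fs: float
    signal: np.ndarray
    motion: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D ROI x time matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition {self.condition!r} not in {CONDITIONS}"
            )
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape != (self.signal.shape[1],):
                raise ValueError("motion length must equal time length")

    @property
    def n_rois(self) -> int:
        return self.signal.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signal.shape[1]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.animal_id, self.session_id, self.run_id)

    def replace_signal(
        self, signal: np.ndarray, motion: np.ndarray | None = None
    ) -> "RunRecord":
        return RunRecord(
            animal_id=self.animal_id,
            session_id=self.session_id,
            run_id=self.run_id,
            condition=self.condition,
            fs=self.fs,
            signal=signal,
            motion=motion,
        )


@dataclass
class Dataset:
    """A hierarchically organised collection of runs (animal > session > run)."""

    runs: list[RunRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_rois = {r.n_rois for r in self.runs}
        if len(n_rois) > 1:
            raise ValueError(f"inconsistent ROI counts across runs: {n_rois}")

    def __len__(self) -> int:
        return len(self.runs)

    def __iter__(self) -> Iterator[RunRecord]:
        return iter(self.runs)

    @property
    def animals(self) -> list[str]:
        return sorted({r.animal_id for r in self.runs})

    def sessions(self, animal_id: str) -> list[str]:
        return sorted(
            {r.session_id for r in self.runs if r.animal_id == animal_id}
        )

    def runs_in(self, animal_id: str, session_id: str) -> list[RunRecord]:
        out = [
            r
            for r in self.runs
            if r.animal_id == animal_id and r.session_id == session_id
        ]
        return sorted(out, key=lambda r: r.run_id)

    def nested_values(self, per_run: dict[tuple[str, str, str], float]
                      ) -> list[list[list[float]]]:
        """Arrange per-run scalars into the animal > session > run nesting."""
        out = []
        for a in self.animals:
            sess = []
            for s in self.sessions(a):
                sess.append([per_run[r.key] for r in self.runs_in(a, s)])
            out.append(sess)
        return out


@dataclass
class CorrelationMatrix:
    """Symmetric ROI x ROI Pearson correlation matrix with unit diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryGraph:
    """Symmetric, loop-free 0/1 adjacency matrix."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be loop-free (zero diagonal)")
        vals = np.unique(a)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("adjacency must be binary")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edge_list(self) -> np.ndarray:
        """Upper-triangle edges as an (E, 2) array of 0-based node ids."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack([i, j])


@dataclass
class MembershipMatrix:
    """Node x community affiliation strengths pi on the probability simplex.

    Each row holds a node's membership strengths across the K communities;
    rows sum to 1 (rows zeroed by statistical thresholding may sum to 0).
    """

    pi: np.ndarray
    condition: str | None = None
    level: str | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pi, dtype=float)
        if p.ndim != 2:
            raise ValueError("pi must be a 2-D node x community matrix")
        if np.any(p < -SIMPLEX_ATOL) or np.any(p > 1 + SIMPLEX_ATOL):
            raise ValueError("membership values must lie in [0, 1]")
        sums = p.sum(axis=1)
        ok = np.isclose(sums, 1.0, atol=SIMPLEX_ATOL) | np.isclose(
            sums, 0.0, atol=SIMPLEX_ATOL
        )
        if not np.all(ok):
            bad = np.flatnonzero(~ok)
            raise ValueError(
                f"rows must sum to 1 (or 0 if thresholded away); "
                f"offending rows: {bad[:5].tolist()}"
            )
        self.pi = np.clip(p, 0.0, 1.0)

    @property
    def n_nodes(self) -> int:
        return self.pi.shape[0]

    @property
    def K(self) -> int:
        return self.pi.shape[1]

    def renormalized(self) -> "MembershipMatrix":
        """Rescale each nonzero row to sum to exactly 1."""
        sums = self.pi.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(sums > 0, self.pi / sums, 0.0)
        return MembershipMatrix(p, condition=self.condition, level=self.level)

    def permute_columns(self, perm: Sequence[int]) -> "MembershipMatrix":
        perm = np.asarray(perm, dtype=int)
        if sorted(perm.tolist()) != list(range(self.K)):
            raise ValueError("perm must be a permutation of 0..K-1")
        return MembershipMatrix(
            self.pi[:, perm], condition=self.condition, level=self.level
        )


@dataclass
class BootstrapResult:
    """Point estimate with bootstrap SE and a BCa confidence interval."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_iter: int
    seed: int
    method: str = "bca"

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be nonnegative")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            # BCa can, rarely, exclude the point estimate on pathological
            # bootstrap distributions; surface it instead of clipping.
            warnings.warn(
                "confidence interval does not bracket the point estimate",
                RuntimeWarning,
                stacklevel=2,
            )
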
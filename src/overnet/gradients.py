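"""Diffusion-map connectivity gradients of group functional connectivity.

A group-averaged correlation matrix is turned into a sparse affinity (top
fraction of each row's connections, cosine similarity between the
sparsified connectivity profiles), normalized with the anisotropic
diffusion-map kernel (exponent alpha), and eigendecomposed. The nontrivial
eigenvectors, ordered by eigenvalue magnitude, are the connectivity
gradients: continuous axes along which connectivity varies across regions.
Gradients have arbitrary units and sign, so each component is z-scored and
its sign fixed by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import linear_sum_assignment
from scipy.sparse.csgraph import connected_components

from .core import CorrelationMatrix

__all__ = ["GradientSet", "compute_gradients", "match_gradients"]


@dataclass
class GradientSet:
    """Connectivity gradients: z-scored components with their eigenvalues
    and fractions of variance (eigenvalue mass) explained."""

    components: np.ndarray  # (N, M), z-scored per column
    eigenvalues: np.ndarray  # (M,), nonnegative, non-increasing
    variance_fraction: np.ndarray  # (M,)

    def __post_init__(self) -> None:
        if np.any(self.eigenvalues < -1e-12):
            raise ValueError("eigenvalues must be nonnegative")
        if np.any(np.diff(self.variance_fraction) > 1e-12):
            raise ValueError("variance fractions must be non-increasing")
        if self.variance_fraction.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must sum to at most 1")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def _row_sparsify(fc: np.ndarray, top: float) -> np.ndarray:
    """Keep the top fraction of each row's off-diagonal entries (by value)."""
    n = fc.shape[0]
    keep = max(1, int(round(top * (n - 1))))
    out = np.zeros_like(fc)
    for i in range(n):
        row = fc[i].copy()
        row[i] = -np.inf
        idx = np.argpartition(row, -keep)[-keep:]
        out[i, idx] = np.maximum(fc[i, idx], 0.0)
    return out


def compute_gradients(
    group_fc: CorrelationMatrix,
    n_components: int = 4,
    sparsify_top: float = 0.10,
    diffusion_alpha: float = 0.5,
) -> GradientSet:
    """Decompose a group FC matrix into diffusion-map gradients.

    Each row keeps its top ``sparsify_top`` fraction of connections
    (negatives zeroed); affinity is the cosine similarity between the
    sparsified connectivity profiles; the affinity is normalized by
    (d_i d_j)^alpha and converted to the symmetric diffusion operator,
    whose eigenvectors (excluding the trivial constant one) are returned
    ordered by eigenvalue magnitude. Components are z-scored, and each
    sign is fixed so the largest-magnitude loading is positive. The
    variance fraction of component m is its eigenvalue over the total
    nontrivial positive eigenvalue mass.
    """
    fc = group_fc.values
    n = group_fc.n_rois
    if not (1 <= n_components < n):
        raise ValueError("need 1 <= n_components < N")
    sparse = _row_sparsify(fc, sparsify_top)
    norms = np.linalg.norm(sparse, axis=1)
    if np.any(norms == 0):
        raise ValueError("a row lost all connections during sparsification")
    aff = (sparse @ sparse.T) / np.outer(norms, norms)
    aff = np.clip((aff + aff.T) / 2.0, 0.0, None)
    np.fill_diagonal(aff, 1.0)

    n_comp, _ = connected_components(aff > 0, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"affinity graph is disconnected ({n_comp} components); "
            "gradients are not defined across components"
        )

    # anisotropic normalization then symmetric diffusion operator
    d = aff.sum(axis=1)
    w = aff / np.outer(d, d) ** diffusion_alpha
    dw = w.sum(axis=1)
    m = w / np.sqrt(np.outer(dw, dw))
    evals, evecs = eigh(m)
    order = np.argsort(np.abs(evals))[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # drop the trivial stationary component (eigenvalue 1)
    psi = evecs[:, 1: n_components + 1] / np.sqrt(dw)[:, None]
    lam = evals[1: n_components + 1]

    nontrivial = np.clip(evals[1:], 0.0, None)
    total = nontrivial.sum()
    var_frac = np.clip(lam, 0.0, None) / total if total > 0 else np.zeros_like(lam)

    z = (psi - psi.mean(axis=0)) / psi.std(axis=0)
    flip = np.sign(z[np.abs(z).argmax(axis=0), np.arange(z.shape[1])])
    z = z * np.where(flip == 0, 1.0, flip)
    return GradientSet(
        components=z,
        eigenvalues=np.clip(lam, 0.0, None),
        variance_fraction=var_frac,
    )


def match_gradients(
    a: GradientSet, b: GradientSet
) -> tuple[np.ndarray, np.ndarray]:
    """Correlate all gradient pairs across two decompositions.

    Returns the M x M Pearson correlation matrix (rows: a's components,
    columns: b's) and the optimal pairing ``pairing[i] = j`` maximizing
    total absolute correlation — eigenvector signs are arbitrary, so the
    assignment ignores sign while the returned matrix keeps it.
    """
    if a.components.shape != b.components.shape:
        raise ValueError("gradient sets must share a shape")
    M = a.n_components
    corr = np.corrcoef(a.components.T, b.components.T)[:M, M:]
    rows, cols = linear_sum_assignment(np.abs(corr), maximize=True)
    pairing = np.empty(M, dtype=int)
    pairing[rows] = cols
    return corr, pairing
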
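"""Assortative mixed-membership stochastic blockmodel (MMSB) inference.

The model: each node i carries a membership vector pi_i on the K-simplex,
drawn from Dirichlet(alpha). For every pair (i, j), each node draws a
community indicator from its memberships; when the indicators agree on some
community the pair links at the within-community rate b, otherwise at a
small background rate epsilon, so the marginal link probability grows with
the membership overlap sum_k pi_ik pi_jk.

Inference is variational, by stochastic natural-gradient ascent on the
per-node Dirichlet factors q(pi_i) = Dir(gamma_i):

* per pair, the optimal categorical factor phi_ij over "agree on k" /
  "disagree" is computed in closed form from the current gamma and rates;
* gamma is updated by a natural-gradient step toward
  alpha + sum_j phi_ijk. With the default full-node batch the unit step is
  exact coordinate ascent; with node mini-batching the step size follows
  the Robbins-Monro schedule rho_t = (tau + t)^(-kappa);
* the rates (b, epsilon) are re-estimated each iteration as the empirical
  link rates inside and across the current disjointified partition, which
  keeps them anchored to the graph rather than to the factors they feed;
* a marginal pseudo-likelihood sum_pairs log p(A_ij) is monitored and the
  best-scoring iterate is returned. Mean-field ascent on dense graphs can
  drift toward a single giant community after it has found the structure;
  the monitor peaks at the structured solution, so snapshotting protects
  against that drift.

Initialization seeds the basins with structure: a spectral embedding of
the normalized adjacency is clustered by seeded k-means and the resulting
labels receive a degree-proportional head start on top of a random
perturbation. Different seeds explore different k-means solutions and
perturbations; consensus across seeds is handled downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.special import digamma
from sklearn.cluster import KMeans

from .core import BinaryGraph, MembershipMatrix

__all__ = ["FitConfig", "MMSBFit", "fit_mmsb", "predict_link_prob"]


@dataclass
class FitConfig:
    """Settings of the variational MMSB fit.

    ``batch_nodes`` selects node mini-batching (None = all nodes). The
    Robbins-Monro schedule (tau, kappa) applies to mini-batched fits;
    kappa must lie in (0.5, 1] for valid stochastic-approximation
    convergence. ``rate_burn`` delays rate re-estimation for a few
    iterations so the initial partition can settle.
    """

    K: int
    seed: int = 0
    max_iters: int = 150
    tau: float = 1024.0
    kappa: float = 0.9
    batch_nodes: int | None = None
    tol: float = 1e-6
    patience: int = 10
    alpha: float | None = None  # default 1/K, symmetric
    rate_burn: int = 3

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if not (0.5 < self.kappa <= 1.0):
            raise ValueError("kappa must lie in (0.5, 1]")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if self.alpha is None:
            self.alpha = 1.0 / self.K
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass
class MMSBFit:
    """Full fit output: memberships plus learned rates and the trace."""

    membership: MembershipMatrix
    within_rate: float
    background_rate: float
    objective_trace: np.ndarray
    n_iters: int
    converged: bool


def predict_link_prob(
    pi_i: np.ndarray, pi_j: np.ndarray, rates: np.ndarray | float = 1.0
) -> float:
    """Link probability sum_k pi_ik pi_jk beta_k, clipped to [0, 1]."""
    pi_i = np.asarray(pi_i, dtype=float)
    pi_j = np.asarray(pi_j, dtype=float)
    rates = np.broadcast_to(np.asarray(rates, dtype=float), pi_i.shape)
    return float(np.clip(np.sum(pi_i * pi_j * rates), 0.0, 1.0))


def _spectral_init(
    A: np.ndarray, K: int, seed: int, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Degree-weighted head start from a spectral partition of the graph."""
    N = A.shape[0]
    deg = A.sum(axis=1).astype(float)
    dinv = 1.0 / np.sqrt(np.maximum(deg, 1.0))
    M = A * dinv[:, None] * dinv[None, :]
    # top-K eigenvectors of the normalized adjacency (dense: deterministic)
    _, vecs = eigh(M, subset_by_index=[N - K, N - 1])
    norms = np.maximum(np.linalg.norm(vecs, axis=1, keepdims=True), 1e-12)
    labels = (
        KMeans(n_clusters=K, n_init=10, random_state=seed)
        .fit(vecs / norms)
        .labels_
    )
    gamma = alpha + rng.random((N, K))
    gamma[np.arange(N), labels] += np.maximum(deg, 1.0) * 0.5
    return gamma


def _partition_rates(
    A: np.ndarray, labels: np.ndarray, b: float, eps: float
) -> tuple[float, float]:
    """Empirical link rates inside / across the hard partition."""
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    cross = ~same
    np.fill_diagonal(cross, False)
    n_same, n_cross = same.sum(), cross.sum()
    if n_same > 0:
        b = float(np.clip((A[same].sum() + 1.0) / (n_same + 2.0),
                          1e-4, 1.0 - 1e-4))
    if n_cross > 0:
        eps = float(np.clip((A[cross].sum() + 1.0) / (n_cross + 2.0),
                            1e-6, 0.9))
    if eps >= b:
        eps = b / 2.0
    return b, eps


def fit_mmsb(
    graph: BinaryGraph,
    config: FitConfig,
    init_gamma: np.ndarray | None = None,
    return_details: bool = False,
) -> MembershipMatrix | MMSBFit:
    """Fit the assortative MMSB to a binary graph.

    Returns the node x community membership matrix (rows on the simplex),
    the posterior mean of the best-objective Dirichlet factors.
    Deterministic given ``config.seed``. ``init_gamma`` overrides the
    spectral initialization; permuting its columns permutes the output
    identically.
    """
    A = graph.adjacency.astype(float)
    Ab = graph.adjacency.astype(bool)
    N = graph.n_nodes
    K = config.K
    if N < 2 or graph.n_edges == 0:
        raise ValueError("graph must be nonempty (at least one edge)")
    if K >= N:
        raise ValueError("K must be smaller than the node count")
    isolated = np.flatnonzero(graph.degrees == 0)
    if isolated.size:
        warnings.warn(
            f"{isolated.size} isolated node(s); their memberships will be "
            "near-uniform",
            RuntimeWarning,
            stacklevel=2,
        )

    rng = np.random.default_rng(config.seed)
    if init_gamma is not None:
        gamma = np.array(init_gamma, dtype=float)
        if gamma.shape != (N, K):
            raise ValueError("init_gamma must be (n_nodes, K)")
    else:
        gamma = _spectral_init(A, K, config.seed, config.alpha, rng)

    b = 0.8
    eps = max(graph.density / 4.0, 1e-5)
    idx = np.arange(N)
    iu = np.triu_indices(N, k=1)
    full_batch = config.batch_nodes is None or config.batch_nodes >= N

    trace: list[float] = []
    best_obj, best_gamma = -np.inf, gamma.copy()
    since_best = 0
    converged = False
    t_final = 0
    for t in range(1, config.max_iters + 1):
        t_final = t
        if t > config.rate_burn:
            b, eps = _partition_rates(Ab, gamma.argmax(axis=1), b, eps)

        Elog = digamma(gamma) - digamma(gamma.sum(axis=1))[:, None]
        S = np.exp(Elog)
        if full_batch:
            rows = idx
            rho = 1.0  # unit natural-gradient step == coordinate ascent
        else:
            rows = rng.choice(N, size=config.batch_nodes, replace=False)
            rho = (config.tau + t) ** (-config.kappa)

        Ar = Ab[rows]
        Stot = S.sum(axis=1)
        SS = S[rows] @ S.T
        p0 = np.clip(np.outer(Stot[rows], Stot) - SS, 1e-12, None)
        lik_agree = np.where(Ar, b, 1.0 - b)
        D = p0 * np.where(Ar, eps, 1.0 - eps)
        phi = np.empty((K, rows.size, N))
        for k in range(K):
            phi[k] = (
                S[rows, k][:, None] * S[:, k][None, :] * lik_agree
            )
            D += phi[k]
        phi /= D
        phi[:, np.arange(rows.size), rows] = 0.0

        gamma_hat = config.alpha + phi.sum(axis=2).T
        gamma[rows] = (1.0 - rho) * gamma[rows] + rho * gamma_hat

        if full_batch:
            obj = float(np.log(D[iu[0], iu[1]]).sum())
            trace.append(obj)
            improved = obj > best_obj + abs(best_obj) * config.tol
            if obj > best_obj:
                best_obj, best_gamma = obj, gamma.copy()
            since_best = 0 if improved else since_best + 1
            if since_best >= config.patience:
                converged = True
                break

    gamma = best_gamma if full_batch else gamma
    # no links, no evidence: isolated nodes revert to the (uniform) prior
    if isolated.size:
        gamma[isolated] = config.alpha
    pi = gamma / gamma.sum(axis=1, keepdims=True)
    membership = MembershipMatrix(pi)
    if return_details:
        return MMSBFit(
            membership=membership,
            within_rate=float(b),
            background_rate=float(eps),
            objective_trace=np.asarray(trace),
            n_iters=t_final,
            converged=converged,
        )
    return membership
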
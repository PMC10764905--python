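"""Node- and network-level statistics of overlapping community solutions.

Covers the full battery reported for overlapping functional networks:
membership entropy (diversity), statistical thresholding of memberships,
"belonging" counts and the global overlap score, membership tiers,
binned membership/entropy distributions, degree variants, percentile maps,
the participation coefficient, cosine network similarity, and
disjointification (argmax labels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .core import BinaryGraph, CorrelationMatrix, MembershipMatrix
from .inference import benjamini_hochberg

__all__ = [
    "BelongingConfig",
    "BelongingResult",
    "node_entropy",
    "entropy_profile",
    "threshold_memberships",
    "belonging_matrix",
    "membership_tiers",
    "membership_distribution",
    "degree_stats",
    "percentile_map",
    "participation_coefficient",
    "network_cosine_similarity",
    "similarity_profile",
    "disjointify",
]


@dataclass
class BelongingConfig:
    """Settings of the belonging test: null level mu0 (default 1/K),
    significance level, and multiple-comparison correction."""

    mu0: float | None = None  # None -> 1/K
    alpha_level: float = 0.05
    df: int | None = None  # t degrees of freedom; None -> normal reference

    def resolve_mu0(self, K: int) -> float:
        mu0 = 1.0 / K if self.mu0 is None else self.mu0
        if not (0.0 < mu0 < 1.0):
            raise ValueError("mu0 must lie in (0, 1)")
        return mu0


def node_entropy(pi_row: np.ndarray, K: int | None = None) -> float:
    """Normalized membership entropy h_i = -sum_k pi_ik log_K pi_ik.

    Base-K Shannon entropy with the 0 log 0 = 0 convention; 0 for a node in
    a single community, 1 for uniform affiliation across all K.
    """
    p = np.asarray(pi_row, dtype=float)
    if K is None:
        K = p.size
    if K < 2:
        raise ValueError("entropy needs K >= 2")
    nz = p[p > 0]
    return float(-(nz * (np.log(nz) / np.log(K))).sum())


def entropy_profile(pi: MembershipMatrix) -> np.ndarray:
    """Per-node normalized entropies of a membership matrix."""
    return np.array([node_entropy(row, pi.K) for row in pi.pi])


def threshold_memberships(
    per_run_pis: list[MembershipMatrix], fdr_q: float = 0.05
) -> MembershipMatrix:
    """Zero memberships that are not significantly above zero, per animal.

    For each (node, community) entry, the run-level values are tested
    against zero with a one-sample t-test (one-sided: memberships are
    nonnegative); p-values are corrected across all entries at FDR q.
    Entries failing the test are zeroed in the across-run mean, and the
    surviving values are rescaled to sum to 1 per node. Zero-variance
    entries are kept when their common value is positive and zeroed when it
    is zero. Rows losing all entries stay at zero, with a warning.
    """
    if not per_run_pis:
        raise ValueError("need at least one run")
    stack = np.stack([m.pi for m in per_run_pis])  # (R, N, K)
    R, N, K = stack.shape
    mean = stack.mean(axis=0)
    if R == 1:
        pvals = np.where(mean > 0, 0.0, 1.0)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = sp_stats.ttest_1samp(
                stack, 0.0, axis=0, alternative="greater"
            )
        pvals = np.asarray(res.pvalue)
        # zero-variance entries: nan p-value; decide by the common value
        degenerate = ~np.isfinite(pvals)
        pvals[degenerate] = np.where(mean[degenerate] > 0, 0.0, 1.0)
    reject, _ = benjamini_hochberg(pvals.ravel(), q=fdr_q)
    keep = reject.reshape(N, K)
    thresholded = np.where(keep, mean, 0.0)
    dead = thresholded.sum(axis=1) == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} node(s) lost every membership at q={fdr_q}",
            RuntimeWarning,
            stacklevel=2,
        )
    sums = thresholded.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rescaled = np.where(sums > 0, thresholded / sums, 0.0)
    return MembershipMatrix(
        rescaled, condition=per_run_pis[0].condition, level="animal"
    )


@dataclass
class BelongingResult:
    """Binary belonging matrix with per-node counts and the overlap score."""

    belongs: np.ndarray  # (N, K) bool
    counts: np.ndarray  # (N,) int
    overlap_score: float
    tstats: np.ndarray
    pvals: np.ndarray


def _belonging_test(
    pi: np.ndarray,
    se: np.ndarray,
    mu0: float,
    alpha_level: float,
    df: int | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-sided test of pi > mu0 with bootstrap SEs, BH-corrected."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (pi - mu0) / se
    t[~np.isfinite(t)] = np.where(pi[~np.isfinite(t)] > mu0, np.inf, -np.inf)
    if df is None:
        pvals = sp_stats.norm.sf(t)
    else:
        pvals = sp_stats.t.sf(t, df)
    reject, _ = benjamini_hochberg(pvals.ravel(), q=alpha_level)
    return reject.reshape(pi.shape), t, pvals


def belonging_matrix(
    group_pi: MembershipMatrix,
    se: np.ndarray,
    cfg: BelongingConfig | None = None,
) -> BelongingResult:
    """Which communities does each node statistically belong to?

    Entry (i, k) belongs when t_ik = (pi_ik - mu0) / SE_ik is significantly
    positive (SE from the hierarchical bootstrap), after FDR correction
    across all entries. The overlap score is the fraction of nodes
    belonging to more than one community.
    """
    cfg = cfg or BelongingConfig()
    se = np.asarray(se, dtype=float)
    if se.shape != group_pi.pi.shape:
        raise ValueError("SE matrix must match the membership matrix shape")
    mu0 = cfg.resolve_mu0(group_pi.K)
    belongs, t, pvals = _belonging_test(
        group_pi.pi, se, mu0, cfg.alpha_level, cfg.df
    )
    counts = belongs.sum(axis=1).astype(int)
    return BelongingResult(
        belongs=belongs,
        counts=counts,
        overlap_score=float((counts > 1).mean()),
        tstats=t,
        pvals=pvals,
    )


def membership_tiers(
    group_pi: MembershipMatrix,
    se: np.ndarray,
    tier_multipliers: tuple[float, ...] = (0.5, 1.5, 2.5, 3.5),
    cfg: BelongingConfig | None = None,
) -> np.ndarray:
    """Tier label per (node, community): the highest multiplier m of the
    null level 1/K that the membership significantly exceeds (0 = none).

    The default multipliers place the thresholds between consecutive
    multiples of 1/K; each multiplier level is tested (and FDR-corrected)
    separately.
    """
    cfg = cfg or BelongingConfig()
    se = np.asarray(se, dtype=float)
    base = 1.0 / group_pi.K
    tiers = np.zeros(group_pi.pi.shape, dtype=int)
    for rank, m in enumerate(sorted(tier_multipliers), start=1):
        sig, _, _ = _belonging_test(
            group_pi.pi, se, m * base, cfg.alpha_level, cfg.df
        )
        tiers[sig] = rank
    return tiers


def membership_distribution(
    run_pi: MembershipMatrix,
    bins: np.ndarray | None = None,
    floor: float = 0.2,
    per_community: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentage histogram of membership values above the robustness floor.

    The default bins are the four intervals of width 0.2 covering
    (0.2, 1.0]; values at or below ``floor`` are excluded (they fall below
    the detection floor established on disjoint synthetic graphs).
    Percentages are relative to the considered (above-floor) values; an
    empty selection returns zeros with a warning. With ``per_community``
    the histogram is computed per community column, stacked as (K, bins).
    """
    if bins is None:
        bins = np.array([floor, 0.4, 0.6, 0.8, 1.0])
    bins = np.asarray(bins, dtype=float)

    def _hist(vals: np.ndarray) -> np.ndarray:
        vals = vals[vals > floor]
        if vals.size == 0:
            return np.zeros(bins.size - 1)
        counts, _ = np.histogram(vals, bins=bins)
        return 100.0 * counts / vals.size

    if per_community:
        out = np.stack([_hist(run_pi.pi[:, k]) for k in range(run_pi.K)])
        if not out.any():
            warnings.warn("no membership values above the floor",
                          RuntimeWarning, stacklevel=2)
        return out, bins
    hist = _hist(run_pi.pi.ravel())
    if not hist.any():
        warnings.warn("no membership values above the floor",
                      RuntimeWarning, stacklevel=2)
    return hist, bins


def degree_stats(
    graph: BinaryGraph, weights: CorrelationMatrix | None = None
) -> dict[str, np.ndarray]:
    """Per-node degree, degree normalized by the region count, and the
    weighted degree (sum of retained correlation weights) when weights are
    supplied."""
    deg = graph.degrees
    out = {
        "degree": deg,
        "normalized_degree": deg / graph.n_nodes,
    }
    if weights is not None:
        if weights.n_rois != graph.n_nodes:
            raise ValueError("weights shape must match the graph")
        out["weighted_degree"] = (weights.values * graph.adjacency).sum(axis=1)
    return out


def percentile_map(values_per_run: np.ndarray) -> np.ndarray:
    """Rank-ordered t-statistic map across runs.

    ``values_per_run`` is (runs, nodes); a one-sample t-statistic is
    computed per node across runs and converted to percentile ranks in
    (0, 100], which discards scale/variability differences between
    conditions.
    """
    v = np.asarray(values_per_run, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("need a (runs, nodes) array with >= 2 runs")
    mean = v.mean(axis=0)
    se = v.std(axis=0, ddof=1) / np.sqrt(v.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, mean / se, np.sign(mean) * np.inf)
    t[np.isnan(t)] = 0.0
    return 100.0 * sp_stats.rankdata(t) / t.size


def participation_coefficient(
    graph: BinaryGraph, labels: np.ndarray
) -> np.ndarray:
    """Participation coefficient 1 - sum_s (k_is / k_i)^2 over hard modules.

    Measures how evenly a node's links spread across the disjoint modules:
    0 when all links stay within one module, approaching 1 - 1/K for links
    spread equally over K modules. Isolated nodes get 0 by convention.
    """
    labels = np.asarray(labels)
    if labels.shape != (graph.n_nodes,):
        raise ValueError("labels must be one hard module label per node")
    deg = graph.degrees.astype(float)
    pc = np.zeros(graph.n_nodes)
    mods = np.unique(labels)
    k_to = np.stack(
        [graph.adjacency[:, labels == m].sum(axis=1) for m in mods], axis=1
    ).astype(float)
    nz = deg > 0
    pc[nz] = 1.0 - ((k_to[nz] / deg[nz, None]) ** 2).sum(axis=1)
    n_isolated = int((~nz).sum())
    if n_isolated:
        warnings.warn(
            f"{n_isolated} isolated node(s) assigned participation 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return pc


def network_cosine_similarity(
    u: np.ndarray, v: np.ndarray, centered: bool = True
) -> float:
    """Similarity of two community membership columns on a [0, 1] scale.

    The columns are mean-centered (so that anti-correlated patterns are
    representable), their cosine c in [-1, 1] is computed, and the result
    is mapped affinely to s = (c + 1) / 2: 1 = identical, 0.5 = orthogonal
    (unrelated), 0 = perfectly dissimilar (inversely correlated). Set
    ``centered=False`` for the raw nonnegative-vector cosine on the same
    affine scale.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must share a shape")
    if centered:
        u = u - u.mean()
        v = v - v.mean()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.5  # empty pattern: indistinguishable from unrelated
    c = float(np.clip((u @ v) / (nu * nv), -1.0, 1.0))
    return (c + 1.0) / 2.0


def similarity_profile(
    a: MembershipMatrix, b: MembershipMatrix, centered: bool = True
) -> tuple[np.ndarray, float]:
    """Per-community similarity between two aligned solutions, plus the
    collapsed mean across communities."""
    if a.pi.shape != b.pi.shape:
        raise ValueError("membership matrices must share a shape")
    per = np.array(
        [
            network_cosine_similarity(a.pi[:, k], b.pi[:, k], centered)
            for k in range(a.K)
        ]
    )
    return per, float(per.mean())


def disjointify(pi: MembershipMatrix) -> np.ndarray:
    """Hard labels by per-node argmax membership.

    Ties go to the lowest community index; the number of tied nodes is
    reported in a warning when any occur.
    """
    labels = pi.pi.argmax(axis=1)
    maxed = pi.pi.max(axis=1, keepdims=True)
    n_tied = int(((pi.pi == maxed).sum(axis=1) > 1).sum())
    if n_tied:
        warnings.warn(
            f"{n_tied} node(s) had tied maximal memberships; lowest index "
            "kept",
            RuntimeWarning,
            stacklevel=2,
        )
    return labels
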
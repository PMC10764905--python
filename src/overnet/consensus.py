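"""Aligning community solutions across seeds and aggregating up the hierarchy.

Communities come out of the blockmodel fit in arbitrary order, so solutions
must be aligned before they can be averaged. Alignment follows the k-means /
cosine / optimal-assignment recipe: membership column vectors from all
seeds are clustered into K centroids, each seed's columns are matched to the
centroids by maximizing total cosine similarity over permutations (the
Hungarian algorithm), and the aligned matrices are averaged and
row-renormalized. The same machinery aggregates run-level results within
sessions, sessions within animals, and animals into a group result, aligning
to a common set of centroids at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .core import MembershipMatrix

__all__ = [
    "AlignmentResult",
    "HierarchyResult",
    "align_to_centroids",
    "consensus_over_seeds",
    "aggregate_hierarchy",
]


@dataclass
class AlignmentResult:
    """A column alignment: permutation, similarity matrix, aligned matrix.

    ``permutation[s] = t`` maps source column s onto target (centroid)
    column t; ``similarity`` is the K x K cosine-similarity matrix from
    source columns (rows) to centroid columns (columns).
    """

    permutation: np.ndarray
    similarity: np.ndarray
    aligned: MembershipMatrix

    def __post_init__(self) -> None:
        perm = np.asarray(self.permutation, dtype=int)
        if sorted(perm.tolist()) != list(range(perm.size)):
            raise ValueError("permutation must be a bijection on 0..K-1")
        self.permutation = perm


def _column_cosine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between columns of a and columns of b."""
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, (a.T @ b) / denom, 0.0)
    return sim


def align_to_centroids(
    source: MembershipMatrix, centroids: MembershipMatrix | np.ndarray
) -> AlignmentResult:
    """Match source communities to centroid communities.

    The permutation maximizes the total cosine similarity along the matched
    diagonal (optimal assignment). Ties are resolved by the assignment
    solver's deterministic lowest-index convention.
    """
    cent = centroids.pi if isinstance(centroids, MembershipMatrix) else centroids
    cent = np.asarray(cent, dtype=float)
    if cent.shape != source.pi.shape:
        raise ValueError(
            f"shape mismatch: source {source.pi.shape} vs centroids "
            f"{cent.shape}"
        )
    sim = _column_cosine(source.pi, cent)
    rows, cols = linear_sum_assignment(sim, maximize=True)
    perm = np.empty(source.K, dtype=int)
    perm[rows] = cols
    aligned_pi = np.empty_like(source.pi)
    aligned_pi[:, perm] = source.pi
    aligned = MembershipMatrix(
        aligned_pi, condition=source.condition, level=source.level
    )
    return AlignmentResult(permutation=perm, similarity=sim, aligned=aligned)


def _kmeans_centroids(
    fits: list[MembershipMatrix], K: int, seed: int, n_init: int
) -> np.ndarray:
    """K centroids of the pooled membership column vectors, as an N x K matrix.

    The pooled vectors are sorted canonically before clustering so the
    result cannot depend on the column order inside any seed's matrix.
    """
    vectors = np.concatenate([m.pi.T for m in fits], axis=0)
    vectors = vectors[np.lexsort(vectors.T[::-1])]
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed).fit(vectors)
    cent = km.cluster_centers_.T  # (N, K)
    # canonical column order: output independent of any input column order
    return cent[:, np.lexsort(cent[::-1])]


def consensus_over_seeds(
    fits: list[MembershipMatrix],
    K: int,
    seed: int = 0,
    n_init: int = 10,
) -> MembershipMatrix:
    """Combine per-seed membership matrices into one consensus matrix.

    All seeds' membership columns are pooled and k-means-clustered into K
    centroids; each seed is aligned to the centroids by optimal assignment
    on cosine similarity; the aligned matrices are averaged and rows are
    renormalized onto the simplex. Invariant under arbitrary independent
    column permutations of each seed's input.
    """
    if not fits:
        raise ValueError("need at least one fitted membership matrix")
    if any(m.K != K for m in fits):
        raise ValueError("all fits must have the requested K")
    if len(fits) == 1:
        return fits[0].renormalized()
    cent = _kmeans_centroids(fits, K, seed, n_init)
    aligned = [align_to_centroids(m, cent).aligned.pi for m in fits]
    mean_pi = np.mean(aligned, axis=0)
    return MembershipMatrix(
        mean_pi, condition=fits[0].condition, level="consensus"
    ).renormalized()


@dataclass
class HierarchyResult:
    """Aggregates at every level of the animal > session > run hierarchy."""

    session_level: dict[tuple[str, str], MembershipMatrix]
    animal_level: dict[str, MembershipMatrix]
    group: MembershipMatrix


def aggregate_hierarchy(
    run_level: dict[tuple[str, str, str], MembershipMatrix],
    seed: int = 0,
) -> HierarchyResult:
    """Average run-level memberships up to session, animal, and group.

    A single set of group centroids is derived from all run-level matrices
    (pooled k-means, as in seed consensus); every run is aligned to those
    centroids, then plain averages are taken within sessions, within
    animals, and across animals, renormalizing rows at every stage. Keys
    are (animal, session, run) tuples; aggregation order is fixed by sorted
    keys, so results do not depend on dict insertion order.
    """
    if not run_level:
        raise ValueError("run_level is empty")
    keys = sorted(run_level)
    mats = [run_level[k] for k in keys]
    K = mats[0].K
    if any(m.K != K or m.n_nodes != mats[0].n_nodes for m in mats):
        raise ValueError("inconsistent membership shapes across runs")
    if len(mats) == 1:
        only = mats[0].renormalized()
        (a, s, _r) = keys[0]
        return HierarchyResult(
            session_level={(a, s): only}, animal_level={a: only}, group=only
        )

    cent = _kmeans_centroids(mats, K, seed, n_init=10)
    aligned = {
        k: align_to_centroids(run_level[k], cent).aligned.pi for k in keys
    }

    def _mean(mats_pi: list[np.ndarray], level: str) -> MembershipMatrix:
        return MembershipMatrix(
            np.mean(mats_pi, axis=0), level=level
        ).renormalized()

    session_level: dict[tuple[str, str], MembershipMatrix] = {}
    for a, s in sorted({(k[0], k[1]) for k in keys}):
        pis = [aligned[k] for k in keys if k[0] == a and k[1] == s]
        session_level[(a, s)] = _mean(pis, "session")

    animal_level: dict[str, MembershipMatrix] = {}
    for a in sorted({k[0] for k in keys}):
        pis = [m.pi for (aa, _s), m in session_level.items() if aa == a]
        animal_level[a] = _mean(pis, "animal")

    group = _mean([m.pi for m in animal_level.values()], "group")
    return HierarchyResult(
        session_level=session_level, animal_level=animal_level, group=group
    )
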
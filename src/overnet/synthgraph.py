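"""Synthetic inputs: MMSB graphs, overlapping LFR-style benchmarks, and
hierarchical multi-animal time-series datasets.

Three generators cover everything the pipeline consumes:

* :func:`sample_mmsb_graph` draws graphs from the assortative
  mixed-membership stochastic blockmodel generative process (memberships
  from a Dirichlet; per-pair community indicators; a link when the
  indicators agree, accepted at the community's link rate).
* :func:`generate_lfr_graph` builds binary overlapping benchmark graphs in
  the LFR style: power-law degree and community-size sequences, a chosen
  number of overlapping nodes (ON) with a fixed number of memberships each
  (OM), and a topological mixing parameter mu giving the fraction of each
  node's links that leave its own communities.
* :func:`generate_hierarchical_dataset` emulates the study design the
  pipeline targets — n animals x sessions x runs of ROI x time signals with
  planted overlapping community covariance and synthetic motion traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .core import BinaryGraph, Dataset, MembershipMatrix, RunRecord

__all__ = [
    "MMSBHyper",
    "LFRParams",
    "BenchmarkGraph",
    "sample_mmsb_graph",
    "generate_lfr_graph",
    "generate_hierarchical_dataset",
    "degree_for_density",
    "estimate_t1",
    "LFRGenerationError",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class MMSBHyper:
    """Hyperparameters of the mixed-membership blockmodel sampler.

    ``alpha`` is the Dirichlet concentration (scalar or per-community);
    ``beta`` the per-community link rate. ``beta = 1`` reproduces the
    deterministic rule "link if the two indicators agree".
    """

    K: int
    alpha: float | np.ndarray = 1.0
    beta: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be at least 2")
        self.alpha = np.broadcast_to(
            np.asarray(self.alpha, dtype=float), (self.K,)
        ).copy()
        if np.any(self.alpha <= 0):
            raise ValueError("alpha must be positive")
        beta = 1.0 if self.beta is None else self.beta
        self.beta = np.broadcast_to(
            np.asarray(beta, dtype=float), (self.K,)
        ).copy()
        if np.any(self.beta < 0) or np.any(self.beta > 1):
            raise ValueError("beta must lie in [0, 1]")


@dataclass
class LFRParams:
    """Parameters of the overlapping LFR-style benchmark generator.

    N nodes; average degree k; topological mixing mu_topo (fraction of a
    node's links outside its own communities); minus-exponents t1 (degree
    sequence) and t2 (community sizes); community-size bounds
    [c_min, c_max]; ON overlapping nodes with OM memberships each.
    """

    N: int
    k: float
    mu_topo: float = 0.2
    t1: float = 2.0
    t2: float = 0.1
    c_min: int = 27
    c_max: int = 190
    ON: int = 0
    OM: int = 2
    k_max: int | None = None

    def __post_init__(self) -> None:
        if not (2 <= self.c_min <= self.c_max <= self.N):
            raise ValueError("need 2 <= c_min <= c_max <= N")
        if not (0 <= self.ON <= self.N):
            raise ValueError("ON must lie in [0, N]")
        if self.OM < 1:
            raise ValueError("OM must be >= 1")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("exponents must be positive")
        if not (0.0 <= self.mu_topo <= 1.0):
            raise ValueError("mu_topo must lie in [0, 1]")
        if not (1 <= self.k <= self.N - 1):
            raise ValueError("average degree k must lie in [1, N-1]")
        if self.k_max is None:
            self.k_max = int(min(self.N - 1, max(3 * self.k, self.k + 1)))


@dataclass
class BenchmarkGraph:
    """A synthetic graph bundled with its planted ground truth.

    ``truth`` is the binary node x community membership; ``memberships``
    additionally stores the continuous simplex memberships for graphs drawn
    from the MMSB. ``mixing`` records the realized per-node fraction of
    external links when the generator tracks it.
    """

    graph: BinaryGraph
    truth: np.ndarray
    params: "LFRParams | MMSBHyper"
    seed: int
    memberships: MembershipMatrix | None = None
    mixing: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.truth)
        if t.ndim != 2 or t.shape[0] != self.graph.n_nodes:
            raise ValueError("truth must be node x community")
        if np.any(t.sum(axis=1) < 1):
            raise ValueError("every node needs at least one true community")
        self.truth = t.astype(np.int8)

    @property
    def n_overlapping(self) -> int:
        return int((self.truth.sum(axis=1) > 1).sum())


class LFRGenerationError(RuntimeError):
    """Raised when no realizable degree/community-size assignment is found."""


# --------------------------------------------------------------------------
# MMSB sampler
# --------------------------------------------------------------------------

def sample_mmsb_graph(
    n_nodes: int, hyper: MMSBHyper, seed: int
) -> BenchmarkGraph:
    """Draw a graph from the assortative MMSB generative process.

    For each node, memberships pi_i ~ Dirichlet(alpha). For each unordered
    pair (i, j), community indicators z_{i->j} ~ Categorical(pi_i) and
    z_{i<-j} ~ Categorical(pi_j); a link is placed when the indicators agree
    on community k, accepted with probability beta_k. The marginal link
    probability is therefore sum_k pi_ik pi_jk beta_k.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    K = hyper.K
    pi = rng.dirichlet(hyper.alpha, size=n_nodes)

    # vectorized categorical draws: one indicator per ordered pair
    cum = np.cumsum(pi, axis=1)
    u = rng.random((n_nodes, n_nodes))
    # z[i, j] = community drawn from pi_i for the pair (i, j)
    z = (u[:, :, None] > cum[:, None, :]).sum(axis=2)
    agree = z == z.T
    accept = rng.random((n_nodes, n_nodes)) < hyper.beta[z]
    adj = np.triu(agree & accept, k=1)
    adj = (adj | adj.T).astype(np.int8)

    truth = np.zeros((n_nodes, K), dtype=np.int8)
    truth[pi >= 1.0 / K] = 1
    truth[np.arange(n_nodes), pi.argmax(axis=1)] = 1
    return BenchmarkGraph(
        graph=BinaryGraph(adj),
        truth=truth,
        params=hyper,
        seed=seed,
        memberships=MembershipMatrix(pi),
    )


# --------------------------------------------------------------------------
# overlapping LFR-style benchmark
# --------------------------------------------------------------------------

def degree_for_density(n_nodes: int, density: float) -> float:
    """Average degree of a graph with the given edge density."""
    return density * (n_nodes - 1)


def estimate_t1(degrees: np.ndarray) -> float:
    """Estimate the degree-sequence exponent via an exponential fit.

    Fits log p(k) ~ -t1 * log k on the positive-count bins of the degree
    histogram, mirroring how a reference graph's degree distribution is
    matched when one is supplied.
    """
    degrees = np.asarray(degrees)
    degrees = degrees[degrees > 0]
    if degrees.size < 3:
        raise ValueError("need at least 3 positive degrees")
    vals, counts = np.unique(degrees, return_counts=True)
    if vals.size < 2:
        raise ValueError("degenerate degree distribution")
    slope, _ = np.polyfit(np.log(vals), np.log(counts / counts.sum()), 1)
    return float(max(-slope, 0.1))


def _truncated_powerlaw(
    rng: np.random.Generator, exponent: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Inverse-CDF samples from a continuous power law x^-exponent on [lo, hi]."""
    u = rng.random(size)
    if abs(exponent - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    a = 1.0 - exponent
    return (lo**a + u * (hi**a - lo**a)) ** (1.0 / a)


def _powerlaw_mean(exponent: float, lo: float, hi: float) -> float:
    if abs(exponent - 1.0) < 1e-12:
        return (hi - lo) / np.log(hi / lo)
    if abs(exponent - 2.0) < 1e-12:
        num = np.log(hi / lo)
    else:
        a2 = 2.0 - exponent
        num = (hi**a2 - lo**a2) / a2
    a1 = 1.0 - exponent
    den = (hi**a1 - lo**a1) / a1
    return num / den


def _degree_sequence(
    rng: np.random.Generator, params: LFRParams
) -> np.ndarray:
    """Power-law degrees with the requested mean, via a bisected lower cut."""
    hi = float(params.k_max)
    lo_lo, lo_hi = 1.0, hi - 1e-9
    if _powerlaw_mean(params.t1, lo_lo, hi) > params.k:
        raise LFRGenerationError(
            f"average degree k={params.k} unreachable: even k_min=1 with "
            f"k_max={params.k_max}, t1={params.t1} gives a larger mean"
        )
    for _ in range(80):
        mid = 0.5 * (lo_lo + lo_hi)
        if _powerlaw_mean(params.t1, mid, hi) < params.k:
            lo_lo = mid
        else:
            lo_hi = mid
    lo = 0.5 * (lo_lo + lo_hi)
    deg = np.rint(
        _truncated_powerlaw(rng, params.t1, lo, hi, params.N)
    ).astype(int)
    return np.clip(deg, 1, params.N - 1)


def _community_sizes(
    rng: np.random.Generator, params: LFRParams, slots: int
) -> np.ndarray:
    """Community sizes ~ power law (exponent t2) on [c_min, c_max], summing
    exactly to the number of membership slots."""
    sizes: list[int] = []
    while sum(sizes) < slots:
        s = int(
            np.rint(
                _truncated_powerlaw(
                    rng, params.t2, params.c_min, params.c_max, 1
                )[0]
            )
        )
        sizes.append(int(np.clip(s, params.c_min, params.c_max)))
    excess = sum(sizes) - slots
    # shrink the largest communities (respecting c_min) to hit the total
    order = np.argsort(sizes)[::-1]
    for idx in order:
        if excess == 0:
            break
        room = sizes[idx] - params.c_min
        take = min(room, excess)
        sizes[idx] -= take
        excess -= take
    if excess > 0:
        raise LFRGenerationError(
            "community sizes cannot sum to the membership slots within "
            f"[c_min={params.c_min}, c_max={params.c_max}]"
        )
    return np.asarray(sizes, dtype=int)


def _assign_memberships(
    rng: np.random.Generator,
    params: LFRParams,
    sizes: np.ndarray,
) -> np.ndarray:
    """Binary node x community truth honouring sizes, ON and OM exactly."""
    n_comm = sizes.size
    if n_comm < params.OM and params.ON > 0:
        raise LFRGenerationError(
            f"only {n_comm} communities but overlapping nodes need "
            f"OM={params.OM} distinct memberships"
        )
    capacity = sizes.astype(float).copy()
    truth = np.zeros((params.N, n_comm), dtype=np.int8)
    nodes = rng.permutation(params.N)
    overlapping, singles = nodes[: params.ON], nodes[params.ON:]
    for node in overlapping:
        if (capacity > 0).sum() < params.OM:
            raise LFRGenerationError(
                "ran out of distinct communities with free capacity for an "
                "overlapping node"
            )
        p = capacity / capacity.sum()
        chosen = rng.choice(n_comm, size=params.OM, replace=False, p=p)
        truth[node, chosen] = 1
        capacity[chosen] -= 1
    for node in singles:
        p = capacity / capacity.sum()
        chosen = rng.choice(n_comm, p=p)
        truth[node, chosen] = 1
        capacity[chosen] -= 1
    assert capacity.sum() == 0
    return truth


def _chung_lu_edges(
    rng: np.random.Generator, stubs: np.ndarray, allowed: np.ndarray
) -> np.ndarray:
    """Chung-Lu edge sampling restricted to an allowed-pair mask.

    Pair (u, v) receives an edge with probability min(1, s_u s_v / S) where
    S is the total stub count; expected degrees approximate ``stubs``. The
    probabilities are rescaled a few times so the expected edge count
    matches sum(stubs)/2 despite capping at 1 and masked pairs.
    """
    total = stubs.sum()
    if total <= 0:
        return np.zeros((stubs.size, stubs.size), dtype=bool)
    p = np.minimum(np.outer(stubs, stubs) / total, 1.0)
    p[~allowed] = 0.0
    np.fill_diagonal(p, 0.0)
    target = total / 2.0
    for _ in range(4):
        expected = p.sum() / 2.0
        if expected <= 0 or abs(expected - target) < 0.01 * target:
            break
        p = np.minimum(p * (target / expected), 1.0)
    draw = rng.random(p.shape)
    edges = np.triu(draw < p, k=1)
    return edges | edges.T


def generate_lfr_graph(params: LFRParams, seed: int) -> BenchmarkGraph:
    """Generate a binary, overlapping LFR-style benchmark graph.

    Degrees follow a truncated power law with exponent ``t1`` and mean
    ``k``; community sizes follow a power law with exponent ``t2`` on
    [c_min, c_max]. Exactly ``ON`` nodes receive ``OM`` memberships; the
    rest one. A fraction ``mu_topo`` of each node's links is external to its
    communities. Internal and external links are laid down by degree-
    matched (Chung-Lu) sampling inside and outside the communities, so ON
    and OM are exact while degrees and mixing are approximate; the realized
    per-node mixing is returned for bookkeeping.

    A node whose internal-degree demand exceeds its communities' capacity
    has the excess shifted to external links (realized mixing above the
    request for such nodes).
    """
    rng = np.random.default_rng(seed)
    if params.k > params.k_max:
        raise LFRGenerationError(
            f"average degree k={params.k} exceeds the maximum degree "
            f"k_max={params.k_max}"
        )
    last_err: Exception | None = None
    for _attempt in range(100):
        try:
            degrees = _degree_sequence(rng, params)
            slots = params.N + params.ON * (params.OM - 1)
            sizes = _community_sizes(rng, params, slots)
            truth = _assign_memberships(rng, params, sizes)
        except LFRGenerationError as err:
            last_err = err
            continue
        break
    else:
        raise LFRGenerationError(
            f"no realizable configuration after 100 attempts: {last_err}"
        )

    n_comm = truth.shape[1]
    memberships = [np.flatnonzero(truth[i]) for i in range(params.N)]
    comm_nodes = [np.flatnonzero(truth[:, c]) for c in range(n_comm)]

    # split each node's internal degree across its communities, capping at
    # what the community can host
    int_target = np.rint((1.0 - params.mu_topo) * degrees).astype(int)
    int_stubs = np.zeros((params.N, n_comm))
    for i in range(params.N):
        comms = memberships[i]
        share = int_target[i] / comms.size
        for c in comms:
            cap = truth[:, c].sum() - 1
            int_stubs[i, c] = min(share, cap)

    adj = np.zeros((params.N, params.N), dtype=bool)
    allowed = np.ones((params.N, params.N), dtype=bool)
    for c in range(n_comm):
        nodes = comm_nodes[c]
        sub = _chung_lu_edges(
            rng, int_stubs[nodes, c], np.ones((nodes.size,) * 2, dtype=bool)
        )
        adj[np.ix_(nodes, nodes)] |= sub

    shares_community = (truth @ truth.T) > 0
    ext_stubs = np.maximum(degrees - int_stubs.sum(axis=1), 0.0)
    adj |= _chung_lu_edges(rng, ext_stubs, ~shares_community)
    adj = adj.astype(np.int8)

    deg_real = adj.sum(axis=1)
    internal_real = np.array(
        [adj[i, shares_community[i]].sum() for i in range(params.N)]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mixing = np.where(
            deg_real > 0, 1.0 - internal_real / np.maximum(deg_real, 1), 0.0
        )

    return BenchmarkGraph(
        graph=BinaryGraph(adj),
        truth=truth,
        params=params,
        seed=seed,
        mixing=mixing,
    )


# --------------------------------------------------------------------------
# hierarchical time-series datasets
# --------------------------------------------------------------------------

def _smoothed_noise(
    rng: np.random.Generator, n: int, fs: float, cutoff_hz: float
) -> np.ndarray:
    """Low-pass-filtered unit-variance white noise (one latent time course)."""
    x = rng.standard_normal(n)
    if cutoff_hz < fs / 2:
        sos = sp_signal.butter(3, cutoff_hz, btype="low", fs=fs, output="sos")
        x = sp_signal.sosfiltfilt(sos, x)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_hierarchical_dataset(
    n_animals: int,
    n_sessions: int,
    n_runs: int,
    n_rois: int,
    n_timepoints: int,
    truth: MembershipMatrix,
    noise_sd: float,
    fs: float,
    seed: int,
    *,
    condition: str = "bold",
    perturb_sd: float = 0.02,
    latent_cutoff_hz: float | None = None,
    motion_base_mm: float = 0.02,
    motion_spike_prob: float = 0.005,
    motion_spike_mm: float = 0.2,
) -> Dataset:
    """Simulate the hierarchical study design with planted community structure.

    Each ROI's signal is a membership-weighted mixture of K latent community
    time courses (independent low-pass-smoothed noise, fresh per run) plus
    Gaussian observation noise: x_i(t) = sum_k pi_ik s_k(t) + eps. Each
    animal carries a small random perturbation of the planted memberships so
    that between-animal variance exists; sessions and runs differ through
    their latent draws. A per-run motion trace with occasional spikes
    supports frame-censoring simulations.
    """
    if truth.n_nodes != n_rois:
        raise ValueError(
            f"truth has {truth.n_nodes} rows but n_rois={n_rois}"
        )
    rng = np.random.default_rng(seed)
    if latent_cutoff_hz is None:
        latent_cutoff_hz = 0.4 * fs / 2
    runs: list[RunRecord] = []
    for a in range(n_animals):
        if perturb_sd > 0:
            p = truth.pi + rng.normal(0.0, perturb_sd, truth.pi.shape)
            p = np.clip(p, 1e-12, None)
            p /= p.sum(axis=1, keepdims=True)
        else:
            p = truth.pi
        for s in range(n_sessions):
            for r in range(n_runs):
                latent = np.stack(
                    [
                        _smoothed_noise(rng, n_timepoints, fs, latent_cutoff_hz)
                        for _ in range(truth.K)
                    ]
                )
                x = p @ latent
                if noise_sd > 0:
                    x = x + rng.normal(0.0, noise_sd, x.shape)
                motion = np.abs(
                    rng.normal(motion_base_mm, motion_base_mm / 2, n_timepoints)
                )
                spikes = rng.random(n_timepoints) < motion_spike_prob
                motion[spikes] += rng.exponential(
                    motion_spike_mm, spikes.sum()
                )
                runs.append(
                    RunRecord(
                        animal_id=f"animal{a:02d}",
                        session_id=f"session{s}",
                        run_id=f"run{r}",
                        condition=condition,
                        fs=fs,
                        signal=x,
                        motion=motion,
                    )
                )
    return Dataset(runs)
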
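"""Inferential machinery: hierarchical bootstrap with BCa intervals, paired
sign-flip permutation tests, and multiple-comparison corrections.

The bootstrap respects the nesting of the study design: animals are
resampled with replacement, then sessions within each sampled animal, then
runs within each sampled session, so every resampled run path exists in the
original data (sessions stay yoked to their animal, runs to their session).
Confidence intervals use the bias-corrected and accelerated (BCa) method
with the acceleration estimated by a jackknife over animals — the natural
exchangeable unit of the design.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .core import BootstrapResult

__all__ = [
    "hierarchical_bootstrap",
    "hierarchical_resample",
    "hierarchical_bootstrap_se_matrix",
    "paired_permutation_test",
    "holm_bonferroni",
    "benjamini_hochberg",
]

NestedValues = Sequence[Sequence[Sequence[float]]]


def _as_nested(data) -> list[list[np.ndarray]]:
    """Coerce animal > session > run values to nested arrays."""
    nested = [
        [np.asarray(runs, dtype=float) for runs in animal] for animal in data
    ]
    if not nested or any(not a for a in nested) or any(
        r.size == 0 for a in nested for r in a
    ):
        raise ValueError("dataset must be nonempty at every level")
    return nested


def hierarchical_resample(
    nested: list[list[np.ndarray]], rng: np.random.Generator
) -> np.ndarray:
    """One yoked resample: animals, then sessions within each sampled
    animal, then runs within each sampled session (all with replacement)."""
    out: list[np.ndarray] = []
    n_a = len(nested)
    for ai in rng.integers(0, n_a, n_a):
        animal = nested[ai]
        n_s = len(animal)
        for si in rng.integers(0, n_s, n_s):
            runs = animal[si]
            out.append(runs[rng.integers(0, runs.size, runs.size)])
    return np.concatenate(out)


def _bca_interval(
    boot: np.ndarray,
    theta_hat: float,
    jack: np.ndarray | None,
    ci: float,
) -> tuple[float, float, str]:
    alpha = (1.0 - ci) / 2.0
    if boot.std() == 0:
        return float(boot[0]), float(boot[0]), "degenerate"
    if jack is None or jack.size < 2 or np.allclose(jack, jack.mean()):
        lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
        return float(lo), float(hi), "percentile"
    # bias correction from the bootstrap distribution's position
    prop = np.clip((boot < theta_hat).mean(), 1e-12, 1 - 1e-12)
    z0 = sp_stats.norm.ppf(prop)
    d = jack.mean() - jack
    a = (d**3).sum() / (6.0 * ((d**2).sum()) ** 1.5)
    z = sp_stats.norm.ppf([alpha, 1.0 - alpha])
    adj = sp_stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
    lo, hi = np.quantile(boot, adj)
    return float(lo), float(hi), "bca"


def hierarchical_bootstrap(
    data: NestedValues,
    statistic: Callable[[np.ndarray], float] | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
    ci: float = 0.95,
) -> BootstrapResult:
    """Bootstrap a statistic of run-level values over the yoked hierarchy.

    ``data`` holds run-level scalars nested animal > session > run (see
    :meth:`overnet.core.Dataset.nested_values`). ``statistic`` maps the
    pooled resampled run values to a scalar (default: mean, vectorized).
    The SE is the bootstrap standard deviation; the interval is BCa with
    the acceleration from an animal-level jackknife. With a single animal
    the acceleration is undefined and a percentile interval is returned
    with a warning.
    """
    nested = _as_nested(data)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([r for a in nested for r in a])
    stat = statistic if statistic is not None else (lambda v: float(v.mean()))
    theta_hat = float(stat(pooled))

    if statistic is None and all(
        len({r.size for r in a}) == 1 for a in nested
    ) and len({len(a) for a in nested}) == 1 and len(
        {r.size for a in nested for r in a}
    ) == 1:
        # balanced design + mean statistic: fully vectorized resampling
        arr = np.asarray(
            [[list(r) for r in a] for a in nested], dtype=float
        )  # (A, S, R)
        A, S, R = arr.shape
        ai = rng.integers(0, A, (n_iter, A))
        si = rng.integers(0, S, (n_iter, A, S))
        ri = rng.integers(0, R, (n_iter, A, S, R))
        vals = arr[
            ai[:, :, None, None],
            si[:, :, :, None],
            ri,
        ]
        boot = vals.reshape(n_iter, -1).mean(axis=1)
    else:
        boot = np.array(
            [
                stat(hierarchical_resample(nested, rng))
                for _ in range(n_iter)
            ]
        )

    n_animals = len(nested)
    jack = None
    if n_animals >= 2:
        jack = np.array(
            [
                stat(
                    np.concatenate(
                        [r for a2 in nested[:i] + nested[i + 1:] for r in a2]
                    )
                )
                for i in range(n_animals)
            ]
        )
    else:
        warnings.warn(
            "single animal: BCa acceleration undefined, using a percentile "
            "interval",
            RuntimeWarning,
            stacklevel=2,
        )
    lo, hi, method = _bca_interval(boot, theta_hat, jack, ci)
    return BootstrapResult(
        estimate=theta_hat,
        se=float(boot.std(ddof=1)) if boot.size > 1 else 0.0,
        ci_low=lo,
        ci_high=hi,
        n_iter=n_iter,
        seed=seed,
        method=method,
    )


def hierarchical_bootstrap_se_matrix(
    values: np.ndarray,
    n_iter: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Bootstrap SE of the mean for every entry of a per-run value array.

    ``values`` has shape (animals, sessions, runs, ...) for a balanced
    design; the same yoked resampling indices are applied to all trailing
    entries at once, giving the SE matrix used e.g. for the belonging
    t-statistics in one pass.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim < 3:
        raise ValueError("values must be (animals, sessions, runs, ...)")
    A, S, R = values.shape[:3]
    rng = np.random.default_rng(seed)
    ai = rng.integers(0, A, (n_iter, A))
    si = rng.integers(0, S, (n_iter, A, S))
    ri = rng.integers(0, R, (n_iter, A, S, R))
    resampled = values[ai[:, :, None, None], si[:, :, :, None], ri]
    boot = resampled.reshape(n_iter, A * S * R, *values.shape[3:]).mean(axis=1)
    return boot.std(axis=0, ddof=1)


def paired_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided paired permutation test by sign-flipping the differences.

    The null hypothesis exchanges each pair's two values, i.e. flips the
    sign of its difference. All 2^n sign patterns are enumerated when that
    is within ``n_resamples``; otherwise Monte-Carlo sampling is used with
    the add-one correction p = (b + 1) / (B + 1), which never returns 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("x and y must be equal-length 1-D value vectors")
    d = x - y
    n = d.size
    obs = abs(d.mean())
    tol = 1e-12 * max(1.0, obs)
    if 2**n <= n_resamples:
        signs = np.array(
            np.meshgrid(*([[-1.0, 1.0]] * n), indexing="ij")
        ).reshape(n, -1)
        stats = np.abs((signs * d[:, None]).mean(axis=0))
        return float((stats >= obs - tol).mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_resamples, n))
    stats = np.abs((signs * d).mean(axis=1))
    b = int((stats >= obs - tol).sum())
    return float((b + 1) / (n_resamples + 1))


def holm_bonferroni(
    pvals: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm's step-down correction; returns (reject, adjusted p-values)."""
    reject, p_adj, _, _ = multipletests(
        np.asarray(pvals, dtype=float), alpha=alpha, method="holm"
    )
    return reject, p_adj


def benjamini_hochberg(
    pvals: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control; returns (reject, adjusted)."""
    reject, p_adj, _, _ = multipletests(
        np.asarray(pvals, dtype=float), alpha=q, method="fdr_bh"
    )
    return reject, p_adj
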
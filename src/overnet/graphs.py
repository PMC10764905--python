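"""From run time series to fixed-density binary functional-connectivity graphs.

The construction pipeline is: zero-phase Butterworth band-pass filtering with
edge trimming, motion-based frame censoring (drop the run when too many
frames move), pairwise Pearson correlation, and rank-order binarization that
retains the top fraction d of connection weights so every run's graph has
exactly the same edge density. Group functional-connectivity matrices are
averaged through Fisher's r-to-z transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .core import BinaryGraph, CorrelationMatrix, Dataset, RunRecord

__all__ = [
    "bandpass_filter",
    "censor_frames",
    "censor_dataset",
    "CensorOutcome",
    "correlation_matrix",
    "threshold_density",
    "fisher_group_average",
]


def bandpass_filter(
    run: RunRecord,
    low_hz: float,
    high_hz: float,
    order: int = 3,
    trim: int = 15,
) -> RunRecord:
    """Zero-phase Butterworth band-pass of each ROI trace, trimming the edges.

    The filter is applied forward and backward (``sosfiltfilt``), which
    cancels phase distortion and doubles the effective order. ``trim`` time
    points are discarded from both the beginning and the end of the filtered
    traces (and of the motion trace) to avoid filtering edge artifacts. A
    band touching 0 Hz degrades to a low-pass; one touching Nyquist to a
    high-pass.
    """
    nyq = run.fs / 2.0
    if not (0.0 <= low_hz < high_hz <= nyq):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz invalid for Nyquist {nyq} Hz"
        )
    if low_hz <= 0.0:
        sos = sp_signal.butter(order, high_hz, btype="low", fs=run.fs,
                               output="sos")
    elif high_hz >= nyq:
        sos = sp_signal.butter(order, low_hz, btype="high", fs=run.fs,
                               output="sos")
    else:
        sos = sp_signal.butter(order, [low_hz, high_hz], btype="band",
                               fs=run.fs, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, run.signal, axis=1)
    if trim > 0:
        if 2 * trim >= filtered.shape[1]:
            raise ValueError("trim removes the entire trace")
        filtered = filtered[:, trim:-trim]
        motion = run.motion[trim:-trim] if run.motion is not None else None
    else:
        motion = run.motion
    return run.replace_signal(np.ascontiguousarray(filtered), motion)


@dataclass
class CensorOutcome:
    """Result of motion scrubbing: the censored run, or a removal flag."""

    run: RunRecord | None
    flagged: bool
    n_censored: int
    fraction_censored: float


def censor_frames(
    run: RunRecord,
    threshold_mm: float = 0.1,
    drop_fraction: float = 0.5,
) -> CensorOutcome:
    """Scrub frames whose motion exceeds ``threshold_mm``.

    Frames above threshold are removed from the signal. When the censored
    fraction exceeds ``drop_fraction`` the run is flagged for removal from
    the data pool (``run`` is None in that case).
    """
    if run.motion is None:
        raise ValueError(
            f"run {run.key} has no motion trace; censoring needs one"
        )
    bad = run.motion > threshold_mm
    frac = bad.mean()
    if frac > drop_fraction:
        return CensorOutcome(None, True, int(bad.sum()), float(frac))
    kept = run.replace_signal(run.signal[:, ~bad], run.motion[~bad])
    return CensorOutcome(kept, False, int(bad.sum()), float(frac))


def censor_dataset(
    dataset: Dataset,
    threshold_mm: float = 0.1,
    drop_fraction: float = 0.5,
) -> tuple[Dataset, list[tuple[str, str, str]]]:
    """Censor every run; return the surviving dataset and removed run keys."""
    kept, removed = [], []
    for run in dataset:
        out = censor_frames(run, threshold_mm, drop_fraction)
        if out.flagged:
            removed.append(run.key)
        else:
            kept.append(out.run)
    return Dataset(kept), removed


def correlation_matrix(run: RunRecord) -> CorrelationMatrix:
    """Pairwise Pearson correlation of the run's ROI traces.

    Constant traces have undefined correlations; those entries are set to 0
    with a warning (the diagonal stays 1).
    """
    x = run.signal
    sd = x.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant ROI trace(s); their "
            "correlations are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        r[constant, :] = 0.0
        r[:, constant] = 0.0
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r)


def threshold_density(
    corr: CorrelationMatrix, d: float, absolute: bool = False
) -> BinaryGraph:
    """Binarize by rank-ordering weights and keeping the top fraction ``d``.

    Weights compete by signed value by default ("top d% strongest edges" as
    largest correlations); set ``absolute=True`` to rank by magnitude. Ties
    at the cutoff are broken deterministically by lexicographic (i, j) order,
    so the edge count is exactly round(d * N(N-1)/2).
    """
    if not (0.0 < d <= 1.0):
        raise ValueError("density d must lie in (0, 1]")
    n = corr.n_rois
    iu, ju = np.triu_indices(n, k=1)
    w = corr.values[iu, ju]
    if absolute:
        w = np.abs(w)
    n_keep = int(round(d * iu.size))
    # sort by descending weight, then ascending (i, j) to break ties
    order = np.lexsort((ju, iu, -w))
    keep = order[:n_keep]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return BinaryGraph(adj)


def fisher_group_average(mats: list[CorrelationMatrix]) -> CorrelationMatrix:
    """Fisher r-to-z transform, average elementwise, and back-transform.

    Off-diagonal values at exactly +/-1 are nudged inside the open interval
    before atanh; the diagonal is forced back to 1.
    """
    if not mats:
        raise ValueError("need at least one matrix")
    shapes = {m.values.shape for m in mats}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent shapes: {shapes}")
    eps = 1e-12
    z = np.mean(
        [np.arctanh(np.clip(m.values, -1 + eps, 1 - eps)) for m in mats],
        axis=0,
    )
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r)
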
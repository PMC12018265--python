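"""Trial alignment in time.

Real walking trials are aligned to each other with dynamic time warping
(DTW) on their 2D positions; the medoid trial (minimum summed DTW distance)
serves as the template, and route turns located on the template are mapped
through each warp path to yield per-trial turn anchor times.  Anchors then
drive piecewise-linear warping of behavioral variables and band amplitudes
onto the condition-mean timing, and segment-length normalization onto a
common unit-segment timeline.  Imagined-position estimates are aligned to
the task structure with a Sakoe-Chiba-banded DTW whose band implements the
+/- 2 s maximal time shift.

The DTW step pattern is symmetric with unit steps {(1,0), (0,1), (1,1)};
distances are Euclidean for trajectories and squared circular distance for
phase series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numba import njit

from ._circular import wrap

__all__ = ["WarpPath", "dtw_path", "dtw_distance",
           "dtw_align_trajectories", "piecewise_linear_warp",
           "normalize_segment_lengths", "capped_dtw_align", "apply_warp_path"]


# --------------------------------------------------------------------------
# core DTW (numba)
# --------------------------------------------------------------------------

@njit(cache=True)
def _dtw_core(cost: np.ndarray, band: int):
    """Accumulate the DTW cost matrix and backtrack the optimal path.

    ``band``: Sakoe-Chiba half-width in samples around the (slope-corrected)
    diagonal; negative means unconstrained.
    """
    n, m = cost.shape
    big = 1e300
    D = np.full((n + 1, m + 1), big)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        if band >= 0:
            centre = (i - 1) * (m - 1) / max(n - 1, 1)
            j_lo = max(1, int(centre - band) + 1)
            j_hi = min(m, int(centre + band) + 1)
        else:
            j_lo, j_hi = 1, m
        for j in range(j_lo, j_hi + 1):
            c = cost[i - 1, j - 1]
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = c + best
    # backtrack
    path_i = np.empty(n + m, dtype=np.int64)
    path_j = np.empty(n + m, dtype=np.int64)
    k = 0
    i, j = n, m
    while i > 0 and j > 0:
        path_i[k] = i - 1
        path_j[k] = j - 1
        k += 1
        a, b, c = D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]
        if a <= b and a <= c:
            i -= 1
            j -= 1
        elif b <= c:
            i -= 1
        else:
            j -= 1
    return D[n, m], path_i[:k][::-1].copy(), path_j[:k][::-1].copy()


def _pair_cost(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        aa = np.atleast_2d(a.T).T if a.ndim == 1 else a
        bb = np.atleast_2d(b.T).T if b.ndim == 1 else b
        diff = aa[:, None, :] - bb[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))
    if metric == "sq_circular":
        return wrap(a[:, None] - b[None, :]) ** 2
    raise ValueError(f"unknown metric {metric!r}")


@njit(cache=True)
def _phase_cost_banded(a: np.ndarray, b: np.ndarray, band: int) -> np.ndarray:
    """Squared circular distance cost, computed only inside the band."""
    n, m = len(a), len(b)
    cost = np.full((n, m), 1e300)
    two_pi = 2.0 * np.pi
    for i in range(n):
        centre = i * (m - 1) / max(n - 1, 1)
        j_lo = max(0, int(centre - band))
        j_hi = min(m - 1, int(centre + band))
        for j in range(j_lo, j_hi + 1):
            d = (a[i] - b[j]) % two_pi
            if d > np.pi:
                d -= two_pi
            cost[i, j] = d * d
    return cost


def dtw_path(a: np.ndarray, b: np.ndarray, metric: str = "euclidean",
             band: int = -1):
    """Optimal monotone alignment path between two sequences.

    Returns ``(distance, idx_a, idx_b)`` where the index arrays have equal
    length and are jointly non-decreasing with endpoints pinned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if metric == "sq_circular" and band >= 0:
        cost = _phase_cost_banded(a, b, band)
    else:
        cost = _pair_cost(a, b, metric)
    return _dtw_core(cost, band)


def dtw_distance(a, b, metric: str = "euclidean", band: int = -1) -> float:
    return dtw_path(a, b, metric=metric, band=band)[0]


# --------------------------------------------------------------------------
# warp path container
# --------------------------------------------------------------------------

@dataclass
class WarpPath:
    """Monotone source-time -> target-time mapping as knot pairs."""

    src_times: np.ndarray
    dst_times: np.ndarray
    max_shift_s: float = np.inf
    edge_pinned_fraction: float = 0.0   # fraction of path on the band edge

    def __post_init__(self):
        s, d = np.asarray(self.src_times, float), np.asarray(self.dst_times, float)
        if len(s) != len(d) or len(s) < 2:
            raise ValueError("need >= 2 knot pairs of equal length")
        if np.any(np.diff(s) < 0) or np.any(np.diff(d) < 0):
            raise ValueError("warp knots must be non-decreasing in both coordinates")
        if np.isfinite(self.max_shift_s) and np.any(np.abs(s - d) > self.max_shift_s + 1e-9):
            raise ValueError("warp exceeds the configured maximal time shift")
        self.src_times, self.dst_times = s, d

    @property
    def mean_offset_s(self) -> float:
        return float(np.mean(self.src_times - self.dst_times))

    def source_time(self, t_dst: np.ndarray) -> np.ndarray:
        return np.interp(t_dst, self.dst_times, self.src_times)


def apply_warp_path(path: WarpPath, series: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Resample ``series`` (sampled at times ``t`` on the source clock) onto
    the target clock of the path (same time grid ``t``)."""
    src = path.source_time(t)
    if series.ndim == 1:
        return np.interp(src, t, series)
    return np.vstack([np.interp(src, t, row) for row in series])


# --------------------------------------------------------------------------
# trajectory alignment
# --------------------------------------------------------------------------

def dtw_align_trajectories(trajectories: Sequence, route,
                           fs_align: float = 40.0):
    """Locate turn anchor times on every real trial via DTW to the medoid.

    Parameters
    ----------
    trajectories : sequence of objects with ``t``, ``xy`` and ``duration``
        attributes (see :class:`thetanav.synth.Trajectory`).
    route : :class:`RouteTemplate`; its turn vertices are located on the
        medoid by nearest approach, then mapped through each warp path.
    fs_align : resampling rate used for the DTW (trajectory DTW does not
        need full motion resolution).

    Returns
    -------
    anchors : list of arrays (start, turn_1..turn_k, end) in trial-local
        seconds; ``None`` for trials dropped as too short.
    medoid : index of the template trial.
    """
    if len(trajectories) < 2:
        raise ValueError("need >= 2 real trials to align")
    durs = np.array([tr.duration for tr in trajectories])
    med_dur = np.median(durs)
    keep = durs >= 0.5 * med_dur
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} trial(s) shorter than 50% of the median duration")
    idx_keep = np.where(keep)[0]

    rs = []
    for tr in trajectories:
        n = max(int(round(tr.duration * fs_align)), 4)
        tt = np.linspace(0, tr.duration, n)
        rs.append((tt, np.column_stack([np.interp(tt, tr.t, tr.xy[:, 0]),
                                        np.interp(tt, tr.t, tr.xy[:, 1])])))

    k = len(idx_keep)
    dist = np.zeros((k, k))
    for ii in range(k):
        for jj in range(ii + 1, k):
            d = dtw_distance(rs[idx_keep[ii]][1], rs[idx_keep[jj]][1])
            dist[ii, jj] = dist[jj, ii] = d
    medoid = int(idx_keep[np.argmin(dist.sum(axis=1))])

    t_med, xy_med = rs[medoid]
    turn_idx = [int(np.argmin(np.linalg.norm(xy_med - v, axis=1)))
                for v in route.vertices[1:-1]]

    anchors = []
    for i, tr in enumerate(trajectories):
        if not keep[i]:
            anchors.append(None)
            continue
        tt, xy = rs[i]
        if i == medoid:
            turns = t_med[turn_idx]
        else:
            _, pi, pj = dtw_path(xy_med, xy)
            turns = np.array([tt[pj[pi == q]].mean() for q in turn_idx])
        turns = np.maximum.accumulate(turns)  # guard monotonicity
        anchors.append(np.concatenate([[0.0], turns, [tr.duration]]))
    return anchors, medoid


# --------------------------------------------------------------------------
# piecewise-linear warping and segment normalization
# --------------------------------------------------------------------------

def piecewise_linear_warp(series: np.ndarray, t: np.ndarray,
                          anchors_src: np.ndarray, anchors_dst: np.ndarray,
                          t_out: Optional[np.ndarray] = None) -> np.ndarray:
    """Warp ``series`` (at source times ``t``) so that source anchors land on
    destination anchors, linearly interpolating in between.

    ``t_out`` defaults to a grid with the input sampling step spanning the
    destination anchors.
    """
    a_src = np.asarray(anchors_src, float)
    a_dst = np.asarray(anchors_dst, float)
    if len(a_src) != len(a_dst):
        raise ValueError("anchor counts must match")
    if np.any(np.diff(a_src) <= 0) or np.any(np.diff(a_dst) <= 0):
        raise ValueError("anchors must be strictly increasing")
    if t_out is None:
        dt = t[1] - t[0]
        t_out = np.arange(a_dst[0], a_dst[-1] + dt / 2, dt)
    src_t = np.interp(t_out, a_dst, a_src)
    if series.ndim == 1:
        return np.interp(src_t, t, series)
    return np.vstack([np.interp(src_t, t, row) for row in np.atleast_2d(series)])


def normalize_segment_lengths(series: np.ndarray, t: np.ndarray,
                              anchors: np.ndarray,
                              samples_per_segment: int = 125) -> np.ndarray:
    """Resample every inter-anchor span to a common length.

    Output length is ``n_segments * samples_per_segment``; sample ``k`` of a
    span sits at relative position ``k / samples_per_segment`` (segment entry
    inclusive, turn exclusive), matching the phase convention phi in
    [0, 2*pi).
    """
    anchors = np.asarray(anchors, float)
    if np.any(np.diff(anchors) <= 0):
        raise ValueError("zero-duration segment span")
    chunks = []
    for a, b in zip(anchors[:-1], anchors[1:]):
        frac = np.arange(samples_per_segment) / samples_per_segment
        tt = a + frac * (b - a)
        if series.ndim == 1:
            chunks.append(np.interp(tt, t, series))
        else:
            chunks.append(np.vstack([np.interp(tt, t, row) for row in series]))
    return np.concatenate(chunks, axis=-1)


# --------------------------------------------------------------------------
# capped DTW for phase alignment
# --------------------------------------------------------------------------

def capped_dtw_align(estimated_phase: np.ndarray, task_phase: np.ndarray,
                     cap_s: float = 2.0, fs: float = 50.0) -> WarpPath:
    """Align an estimated phase series to the task structure under a
    +/- ``cap_s`` maximal time shift (Sakoe-Chiba band).

    Both series must live on the same uniform timeline at rate ``fs``.
    Distance is squared circular distance between phases.  The returned
    path maps source (estimate) time to target (task) time.
    """
    est = np.asarray(estimated_phase, float)
    task = np.asarray(task_phase, float)
    if len(est) != len(task):
        raise ValueError("series must share one timeline")
    band = int(round(cap_s * fs))
    if band < 1:
        raise ValueError("cap smaller than one sample")
    _, pi, pj = dtw_path(est, task, metric="sq_circular", band=band)
    # one source time per target sample (mean of matched indices)
    n = len(task)
    counts = np.bincount(pj, minlength=n).astype(float)
    sums = np.bincount(pj, weights=pi, minlength=n)
    valid = counts > 0
    src_idx = np.interp(np.arange(n), np.where(valid)[0], sums[valid] / counts[valid])
    src_idx = np.maximum.accumulate(src_idx)
    shift = np.clip(src_idx - np.arange(n), -band, band)
    src_idx = np.arange(n) + shift
    pinned = np.mean(np.abs(shift) >= band - 0.5)
    return WarpPath(src_times=src_idx / fs, dst_times=np.arange(n) / fs,
                    max_shift_s=cap_s + 1.0 / fs,
                    edge_pinned_fraction=float(pinned))
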
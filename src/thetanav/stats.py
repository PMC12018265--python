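"""Shared nonparametric inference machinery.

All tests here are permutation-based and respect the grouped structure of
ambulatory iEEG data: channels are nested in participants, so exchangeable
units are restricted to participant blocks (multilevel block permutation)
for label-exchange tests, while sign-flip tests flip channels — the same
exchangeable unit the cluster permutation uses.  Cluster-based
correction scores contiguous supra-threshold regions against the maximum
cluster size under the null.  Every engine takes a seed and is exactly
reproducible.

Cohen's d follows the convention (condition A - condition B) / SD of the
paired differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import label as nd_label

__all__ = ["PermutationResult", "ClusterTestResult", "turn_aligned_average",
           "cluster_signflip_test", "peak_latency_test",
           "behavior_theta_analysis", "route_rmse", "cohens_d_paired",
           "cluster_bootstrap_ci"]


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p: float
    ci: Optional[tuple] = None
    cohens_d: Optional[float] = None
    mean_difference: Optional[float] = None
    note: str = ""

    def __post_init__(self):
        n = len(self.null)
        assert self.p >= 1.0 / (n + 1) - 1e-12


@dataclass
class ClusterTestResult:
    mask: np.ndarray              # significant after cluster correction
    primary_mask: np.ndarray      # pointwise supra-threshold
    cluster_sizes: list
    cluster_p: list
    observed: np.ndarray          # channel-mean map


def _perm_p(observed: float, null: np.ndarray, alternative: str = "greater") -> float:
    n = len(null)
    if alternative == "greater":
        k = np.sum(null >= observed)
    elif alternative == "less":
        k = np.sum(null <= observed)
    else:
        k = np.sum(np.abs(null) >= abs(observed))
    return float((1 + k) / (n + 1))


def cohens_d_paired(diff: np.ndarray) -> float:
    sd = np.std(diff, ddof=1)
    if sd < 1e-9 * max(abs(float(np.mean(diff))), 1.0):
        return np.nan
    return float(np.mean(diff) / sd)


def cluster_bootstrap_ci(values: np.ndarray, participants: np.ndarray,
                         rng: np.random.Generator, n_boot: int = 2000,
                         level: float = 0.95) -> tuple:
    """Percentile CI of the mean, resampling participants (clusters)."""
    parts = np.unique(participants)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.choice(parts, size=len(parts), replace=True)
        sel = np.concatenate([np.where(participants == p)[0] for p in pick])
        boots[b] = values[sel].mean()
    a = (1 - level) / 2
    return (float(np.quantile(boots, a)), float(np.quantile(boots, 1 - a)))


# --------------------------------------------------------------------------
# event-locked averaging
# --------------------------------------------------------------------------

def turn_aligned_average(series: np.ndarray, fs: float, event_times: np.ndarray,
                         window_s: float = 2.0):
    """Mean of ``series`` in windows of +/- window_s around each event.

    Parameters
    ----------
    series : (S,) or (C, S) or (C, F, S); averaging is over events.
    Returns (lags_s, mean) where time 0 is the event.
    """
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    S = x.shape[-1]
    w = int(round(window_s * fs))
    events = [int(round(e * fs)) for e in np.atleast_1d(event_times)]
    events = [e for e in events if e - w >= 0 and e + w < S]
    if not events:
        raise ValueError("no events with a full window inside the recording")
    stack = np.stack([x[..., e - w:e + w + 1] for e in events])
    mean = stack.mean(axis=0)
    lags = np.arange(-w, w + 1) / fs
    return lags, (mean[0] if squeeze else mean)


# --------------------------------------------------------------------------
# cluster-based sign-flip permutation
# --------------------------------------------------------------------------

def cluster_signflip_test(maps: np.ndarray, n_perm: int = 1000,
                          p_primary: float = 0.05, p_cluster: float = 0.05,
                          seed: int = 0, two_sided: bool = True) -> ClusterTestResult:
    """Test where the channel-mean map deviates from zero.

    ``maps``: (n_channels, ...) event-locked maps (1D band series or 2D
    time-frequency).  The null flips the sign of a randomly selected half
    of the channels before averaging; pointwise thresholds come from the
    null percentiles at ``p_primary``, and contiguous supra-threshold
    clusters (4-connectivity) are scored by size against the max-cluster
    null.  ``p_cluster = 1`` reduces to the pointwise test.
    """
    maps = np.asarray(maps, dtype=float)
    C = maps.shape[0]
    if C < 2:
        raise ValueError("need >= 2 channels")
    rng = np.random.default_rng(seed)
    observed = maps.mean(axis=0)
    null_maps = np.empty((n_perm,) + observed.shape)
    half = C // 2
    for b in range(n_perm):
        flip = np.zeros(C)
        flip[:] = 1.0
        flip[rng.choice(C, size=half, replace=False)] = -1.0
        null_maps[b] = (maps * flip.reshape((C,) + (1,) * observed.ndim)).mean(axis=0)
    if two_sided:
        lo = np.quantile(null_maps, p_primary / 2, axis=0)
        hi = np.quantile(null_maps, 1 - p_primary / 2, axis=0)
        primary = (observed > hi) | (observed < lo)
        perm_primary = (null_maps > hi) | (null_maps < lo)
    else:
        hi = np.quantile(null_maps, 1 - p_primary, axis=0)
        primary = observed > hi
        perm_primary = null_maps > hi

    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]) if observed.ndim == 2 else None
    lab, n_clus = nd_label(primary, structure=structure)
    sizes = [int(np.sum(lab == k)) for k in range(1, n_clus + 1)]
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        labb, nb = nd_label(perm_primary[b], structure=structure)
        max_null[b] = max((np.sum(labb == k) for k in range(1, nb + 1)), default=0)
    cluster_p = [float((1 + np.sum(max_null >= s)) / (n_perm + 1)) for s in sizes]
    mask = np.zeros_like(primary)
    for k, p in enumerate(cluster_p, start=1):
        if p <= p_cluster:
            mask |= lab == k
    return ClusterTestResult(mask=mask, primary_mask=primary,
                             cluster_sizes=sizes, cluster_p=cluster_p,
                             observed=observed)


# --------------------------------------------------------------------------
# peak latency
# --------------------------------------------------------------------------

def peak_latency_test(band_series: np.ndarray, fs: float, turn_times: np.ndarray,
                      window_s: float, participants: np.ndarray,
                      n_perm: int = 1000, seed: int = 0) -> PermutationResult:
    """Latency of each channel's turn-locked peak, tested against zero.

    The group null flips the sign of each channel's latency (channel-level
    sign flip, the same exchangeable unit the cluster test uses); the
    participant labels drive the cluster-bootstrap CI.  Ties in the
    per-channel peak break toward the earlier latency; flat averages drop
    the channel with a warning.
    """
    C = band_series.shape[0]
    lat = []
    keep_parts = []
    for c in range(C):
        lags, avg = turn_aligned_average(band_series[c], fs, turn_times, window_s)
        if np.ptp(avg) <= 0:
            warnings.warn(f"flat turn-locked average on channel {c}; dropped")
            continue
        lat.append(lags[int(np.argmax(avg))])   # argmax: first max = earlier latency
        keep_parts.append(participants[c])
    lat = np.asarray(lat)
    parts = np.asarray(keep_parts)
    rng = np.random.default_rng(seed)
    observed = float(lat.mean())
    null = np.empty(n_perm)
    for b in range(n_perm):
        signs = np.where(rng.random(len(lat)) < 0.5, 1.0, -1.0)
        null[b] = float(np.mean(lat * signs))
    p = _perm_p(observed, null, "two-sided")
    ci = cluster_bootstrap_ci(lat, parts, rng)
    return PermutationResult(observed=observed, null=null, p=p, ci=ci,
                             cohens_d=cohens_d_paired(lat),
                             mean_difference=observed)


# --------------------------------------------------------------------------
# behavior ~ theta
# --------------------------------------------------------------------------

def _xcorr_lagprofile(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """Pearson correlation of a vs b at lags -max_lag..max_lag.

    A peak at a negative lag means ``a`` leads ``b`` (the pattern appears
    in ``a`` first).
    """
    out = np.empty(2 * max_lag + 1)
    n = len(a)
    for i, lag in enumerate(range(-max_lag, max_lag + 1)):
        k = -lag
        if k < 0:
            x, y = a[-k:], b[:n + k]
        elif k > 0:
            x, y = a[:n - k], b[k:]
        else:
            x, y = a, b
        sx, sy = np.std(x), np.std(y)
        out[i] = np.corrcoef(x, y)[0, 1] if sx > 0 and sy > 0 else 0.0
    return out


def behavior_theta_analysis(theta: np.ndarray, behaviors: dict, fs: float,
                            participants: np.ndarray, max_lag_s: float = 2.0,
                            n_perm: int = 1000, seed: int = 0) -> dict:
    """Cross-correlation lag profiles and single-trial joint regression.

    Parameters
    ----------
    theta : (C, n_trials, T) warped band amplitudes.
    behaviors : name -> (n_trials, T) behavioral series on the same timeline.
    Returns a dict with ``lags_s``, per-variable trial-averaged lag profiles
    (C, L), per-variable group-level regression results (channel-level sign-flip
    with max-statistic correction across variables), and the per-channel
    coefficient means.
    """
    C, n_trials, T = theta.shape
    names = []
    mats = []
    for name, b in behaviors.items():
        b = np.asarray(b, dtype=float)
        if np.allclose(np.std(b, axis=1), 0):
            warnings.warn(f"behavior variable {name!r} is constant; dropped")
            continue
        names.append(name)
        mats.append(b)
    V = len(names)
    max_lag = int(round(max_lag_s * fs))

    profiles = {}
    for name, b in zip(names, mats):
        prof = np.zeros((C, 2 * max_lag + 1))
        for c in range(C):
            per_trial = [_xcorr_lagprofile(theta[c, k], b[k], max_lag)
                         for k in range(n_trials)]
            prof[c] = np.mean(per_trial, axis=0)
        profiles[name] = prof

    # single-trial OLS per channel, coefficients averaged over trials
    coefs = np.zeros((C, V))
    for c in range(C):
        trial_coefs = np.empty((n_trials, V))
        for k in range(n_trials):
            X = np.column_stack([np.ones(T)] + [ (m[k] - m[k].mean()) / (m[k].std() or 1.0)
                                                 for m in mats])
            beta, *_ = np.linalg.lstsq(X, theta[c, k], rcond=None)
            trial_coefs[k] = beta[1:]
        coefs[c] = trial_coefs.mean(axis=0)

    rng = np.random.default_rng(seed)
    obs = coefs.mean(axis=0)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        signs = np.where(rng.random(C) < 0.5, 1.0, -1.0)
        flipped = (coefs * signs[:, None]).mean(axis=0)
        null_max[b] = np.max(np.abs(flipped))
    p_corr = {name: float((1 + np.sum(null_max >= abs(obs[v]))) / (n_perm + 1))
              for v, name in enumerate(names)}
    return dict(lags_s=np.arange(-max_lag, max_lag + 1) / fs,
                lag_profiles=profiles, coefficients=coefs,
                coefficient_names=names, group_mean=dict(zip(names, obs)),
                p_corrected=p_corr)


# --------------------------------------------------------------------------
# route adherence
# --------------------------------------------------------------------------

def _point_polyline_dist(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Perpendicular (nearest) distance of each point to the polyline."""
    p = points[:, None, :]                       # (N, 1, 2)
    a = vertices[None, :-1, :]                   # (1, M, 2)
    b = vertices[None, 1:, :]
    ab = b - a
    denom = (ab ** 2).sum(axis=2)
    tpar = np.clip(((p - a) * ab).sum(axis=2) / denom, 0.0, 1.0)
    proj = a + tpar[..., None] * ab
    d = np.linalg.norm(p - proj, axis=2)
    return d.min(axis=1)


def route_rmse(trajectory_xy: np.ndarray, route) -> float:
    """Root mean squared perpendicular distance to the ideal route (metres)."""
    xy = np.asarray(trajectory_xy, dtype=float)
    if xy.ndim != 2 or len(xy) == 0:
        raise ValueError("trajectory must be a non-empty (n, 2) array")
    d = _point_polyline_dist(xy, np.asarray(route.vertices, dtype=float))
    return float(np.sqrt(np.mean(d ** 2)))
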
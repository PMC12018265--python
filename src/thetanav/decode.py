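"""Circular position decoding from multichannel theta dynamics.

The route is abstracted into a sinusoidal task structure: relative position
within a segment is a phase phi in [0, 2*pi) (0 at segment entry, 2*pi at
the turn), encoded by the orthogonal responses cos(phi) — peaked at each
turn — and -sin(phi) — peaked at three quarters of the segment, i.e. just
before turns.  A linear regression from the z-scored theta amplitudes of
all channels (pooled across participants) to these two responses is fit
under repeated k-fold cross-validation with whole trials assigned to folds
(10 folds x 10 repeats by default).  The decoded phase is the angle of the
predicted resultant vector:

    phi_hat = atan2(-y_nsin_hat, y_cos_hat)  mod 2*pi.

Reconstruction quality is summarized by circular errors eps = wrap(phi_hat
- phi) in (-pi, pi], a 2D density over (actual x estimated) position bins
normalized so a uniform estimate equals 1.0, and a circular-shift
permutation null on the mean resultant length of the errors.

For imagined trials the real-trained model provides an initial estimate,
which is then aligned to the task structure by a +/- 2 s capped DTW learned
on training folds of imagination trials only and applied unchanged to
held-out trials; one alignment path per participant, derived from the
partial response vectors of that participant's channels so that relative
timing between channels is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._circular import TWO_PI, circ_dist, resultant_length, wrap_positive
from .warp import capped_dtw_align

__all__ = ["TaskStructure", "DecoderModel", "ReconstructionResult",
           "build_task_structure", "fit_decoder", "fit_weights",
           "predict_phase", "reconstruction_report", "circular_shift_null",
           "crosscorrelogram_route", "decode_imagined"]


# --------------------------------------------------------------------------
# task structure
# --------------------------------------------------------------------------

@dataclass
class TaskStructure:
    """Circular task phase and its sinusoidal responses on a common timeline."""

    phi: np.ndarray             # (T,) in [0, 2*pi)
    responses: np.ndarray       # (T, 2): [cos phi, -sin phi]
    segment_index: np.ndarray   # (T,)
    n_turns: int
    fs: float                   # samples per second on the common timeline

    @property
    def n_segments(self) -> int:
        return self.n_turns + 1

    @property
    def samples_per_segment(self) -> int:
        return len(self.phi) // self.n_segments


def build_task_structure(anchor_idx: np.ndarray, n_samples: int,
                         fs: float = 50.0) -> TaskStructure:
    """Task structure with phi linear 0 -> 2*pi within each anchor span.

    ``anchor_idx``: sample indices of (start, turns..., end); the end index
    is exclusive and must equal ``n_samples``.
    """
    anchor_idx = np.asarray(anchor_idx, dtype=int)
    if len(anchor_idx) < 2:
        raise ValueError("need at least start and end anchors")
    if np.any(np.diff(anchor_idx) <= 0):
        raise ValueError("anchors must be strictly increasing")
    t = np.arange(n_samples)
    seg = np.clip(np.searchsorted(anchor_idx, t, side="right") - 1, 0,
                  len(anchor_idx) - 2)
    span = (anchor_idx[seg + 1] - anchor_idx[seg]).astype(float)
    phi = (t - anchor_idx[seg]) / span * TWO_PI
    responses = np.column_stack([np.cos(phi), -np.sin(phi)])
    return TaskStructure(phi=phi, responses=responses, segment_index=seg,
                         n_turns=len(anchor_idx) - 2, fs=fs)


# --------------------------------------------------------------------------
# decoder
# --------------------------------------------------------------------------

@dataclass
class DecoderModel:
    """Cross-validated linear decoder with out-of-fold predictions."""

    weights: np.ndarray            # (repeats, folds, C + 1, 2)
    folds: np.ndarray              # (repeats, n_trials) fold id per trial
    oof_pred: np.ndarray           # (repeats, n_trials, T, 2) held-out predictions
    mean_weights: np.ndarray       # (C + 1, 2) fit on all trials
    n_folds: int
    n_repeats: int
    ridge_used: bool = False


def fit_weights(X: np.ndarray, Y: np.ndarray):
    """OLS of Y (N, 2) on [1, X] (N, C); ridge fallback when rank-deficient.

    Returns (W, ridge_used) with W of shape (C + 1, 2).
    """
    design = np.column_stack([np.ones(len(X)), X])
    W, _res, rank, sv = np.linalg.lstsq(design, Y, rcond=None)
    if rank < design.shape[1]:
        import warnings
        warnings.warn("rank-deficient design; falling back to ridge")
        G = design.T @ design
        lam = 1e-6 * np.trace(G) / G.shape[0]
        W = np.linalg.solve(G + lam * np.eye(G.shape[0]), design.T @ Y)
        return W, True
    return W, False


def fit_decoder(theta: np.ndarray, structure: TaskStructure,
                n_folds: int = 10, n_repeats: int = 10,
                seed: int = 0) -> DecoderModel:
    """Cross-validated linear decoder.

    Parameters
    ----------
    theta : (n_trials, C, T) z-scored band amplitudes on the common timeline.
    structure : task structure shared by all trials.

    Trials are assigned whole to folds; within each fold the weights come
    from training trials only, and predictions are emitted only for the
    held-out trials.
    """
    theta = np.asarray(theta, dtype=float)
    n_trials, C, T = theta.shape
    if T != len(structure.phi):
        raise ValueError("theta and task structure timelines differ")
    Y1 = structure.responses
    rng = np.random.default_rng(seed)
    weights = np.empty((n_repeats, n_folds, C + 1, 2))
    folds = np.empty((n_repeats, n_trials), dtype=int)
    oof = np.empty((n_repeats, n_trials, T, 2))
    ridge_any = False
    for r in range(n_repeats):
        assign = np.array_split(rng.permutation(n_trials), n_folds)
        for f, test_idx in enumerate(assign):
            train_idx = np.setdiff1d(np.arange(n_trials), test_idx)
            Xtr = theta[train_idx].transpose(0, 2, 1).reshape(-1, C)
            Ytr = np.tile(Y1, (len(train_idx), 1))
            W, used = fit_weights(Xtr, Ytr)
            ridge_any |= used
            weights[r, f] = W
            folds[r, test_idx] = f
            for ti in test_idx:
                oof[r, ti] = np.column_stack([np.ones(T), theta[ti].T]) @ W
    Xall = theta.transpose(0, 2, 1).reshape(-1, C)
    Yall = np.tile(Y1, (n_trials, 1))
    mean_W, _ = fit_weights(Xall, Yall)
    return DecoderModel(weights=weights, folds=folds, oof_pred=oof,
                        mean_weights=mean_W, n_folds=n_folds,
                        n_repeats=n_repeats, ridge_used=ridge_any)


def predict_phase(pred: np.ndarray) -> np.ndarray:
    """Decoded phase from predicted (y_cos, y_nsin) pairs, in [0, 2*pi).

    Undefined phases (both components zero) become NaN.
    """
    pred = np.asarray(pred, dtype=float)
    y_cos, y_nsin = pred[..., 0], pred[..., 1]
    phi = wrap_positive(np.arctan2(-y_nsin, y_cos))
    bad = (y_cos == 0) & (y_nsin == 0)
    return np.where(bad, np.nan, phi)


# --------------------------------------------------------------------------
# reconstruction summaries
# --------------------------------------------------------------------------

@dataclass
class ReconstructionResult:
    errors: np.ndarray            # (N,) circular errors in (-pi, pi]
    error_hist: np.ndarray        # probability mass per degree bin
    error_bins_deg: np.ndarray    # bin edges in degrees
    density: np.ndarray           # (n_bins, n_bins) actual x estimated, uniform = 1
    mean_abs_error_deg: float
    resultant: float              # mean resultant length of the errors
    mean_error_deg: float
    alignment_flagged: bool = False
    mean_offsets_s: dict = field(default_factory=dict)
    phi_hat: Optional[np.ndarray] = None   # pooled decoded phases
    phi: Optional[np.ndarray] = None       # matching actual phases

    @property
    def diagonal_mass(self) -> float:
        """Mean normalized density on the diagonal (perfect = large)."""
        return float(np.mean(np.diag(self.density)))


def reconstruction_report(phi_hat: np.ndarray, phi: np.ndarray,
                          n_bins: int = 24) -> ReconstructionResult:
    """Circular errors and the normalized (actual x estimated) density."""
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    phi_hat = np.asarray(phi_hat, dtype=float).ravel()
    phi = np.asarray(phi, dtype=float).ravel()
    if phi_hat.shape != phi.shape:
        raise ValueError("series must have equal length")
    ok = np.isfinite(phi_hat) & np.isfinite(phi)
    phi_hat, phi = phi_hat[ok], phi[ok]
    eps = circ_dist(phi_hat, phi)
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    hist, _ = np.histogram(np.rad2deg(eps), bins=edges)
    hist = hist / max(hist.sum(), 1)
    bins2 = np.linspace(0, TWO_PI, n_bins + 1)
    H, _, _ = np.histogram2d(wrap_positive(phi), wrap_positive(phi_hat), bins=[bins2, bins2])
    density = H / (len(phi) / n_bins ** 2) if len(phi) else H
    return ReconstructionResult(
        errors=eps, error_hist=hist, error_bins_deg=edges, density=density,
        mean_abs_error_deg=float(np.rad2deg(np.mean(np.abs(eps)))),
        resultant=float(resultant_length(eps)),
        mean_error_deg=float(np.rad2deg(np.angle(np.mean(np.exp(1j * eps))))),
        phi_hat=phi_hat, phi=phi,
    )


def circular_shift_null(phi_hat: np.ndarray, phi: np.ndarray,
                        n_shifts: int = 10000, seed: int = 0):
    """Shift null for the error concentration.

    Statistic: mean resultant length of the errors.  The null randomly
    rotates phi_hat in time relative to phi (whole-series circular shifts),
    preserving each series' autocorrelation.
    """
    from .stats import PermutationResult
    phi_hat = np.asarray(phi_hat, dtype=float).ravel()
    phi = np.asarray(phi, dtype=float).ravel()
    if len(phi) < 10:
        raise ValueError("series too short for a shift null")
    rng = np.random.default_rng(seed)
    observed = float(resultant_length(circ_dist(phi_hat, phi)))
    null = np.empty(n_shifts)
    n = len(phi)
    for i in range(n_shifts):
        k = rng.integers(1, n)
        null[i] = resultant_length(circ_dist(np.roll(phi_hat, k), phi))
    p = float((1 + np.sum(null >= observed)) / (n_shifts + 1))
    return PermutationResult(observed=observed, null=null, p=p)


def crosscorrelogram_route(series: np.ndarray, structure: TaskStructure):
    """Normalized cross-correlation of a band series with the -sin response.

    The task structure is periodic over the route, so the correlation is
    circular (constant overlap at every lag); lags span half the route in
    both directions.  Returns (lags_in_segments, r); the lag-0 value is the
    structure correlation, side peaks at integer segment lags indicate
    segment-repeating dynamics.
    """
    y = structure.responses[:, 1]
    x = np.asarray(series, dtype=float)
    L = structure.samples_per_segment
    n = len(x)
    max_lag = n // 2
    lags = np.arange(-max_lag, max_lag + 1)
    sx, sy = np.std(x), np.std(y)
    r = np.empty(len(lags))
    for i, k in enumerate(lags):
        if sx > 0 and sy > 0:
            r[i] = np.corrcoef(x, np.roll(y, k))[0, 1]
        else:
            r[i] = 0.0
    return lags / L, r


# --------------------------------------------------------------------------
# imagined-trial decoding with capped alignment
# --------------------------------------------------------------------------

def _partial_vectors(theta_trial: np.ndarray, W: np.ndarray,
                     groups: np.ndarray) -> dict:
    """Per-participant partial response vectors (intercept shared pro rata)."""
    C, T = theta_trial.shape
    out = {}
    for g in np.unique(groups):
        sel = np.where(groups == g)[0]
        share = len(sel) / C
        out[g] = theta_trial[sel].T @ W[1 + sel] + share * W[0]
    return out


def decode_imagined(mean_weights: np.ndarray, theta: np.ndarray,
                    structure: TaskStructure, groups: Optional[np.ndarray] = None,
                    cap_s: float = 2.0, n_folds: int = 10, n_repeats: int = 10,
                    seed: int = 0, align: bool = True) -> ReconstructionResult:
    """Decode imagined (or control) trials with capped DTW alignment.

    Parameters
    ----------
    mean_weights : (C + 1, 2) weights fit on real trials only.
    theta : (n_trials, C, T) z-scored band amplitudes of the imagined
        condition, linearly warped to the condition-mean duration and
        segment-normalized onto the task timeline.
    groups : participant id per channel; one alignment path per participant
        is learned from training folds and applied unchanged to test trials.
    align : when False, skip the DTW stage (used for the zero-distortion
        reduction check and for raw control decoding).
    """
    theta = np.asarray(theta, dtype=float)
    n_trials, C, T = theta.shape
    if groups is None:
        groups = np.zeros(C, dtype=int)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    ugroups = np.unique(groups)

    partial = [_partial_vectors(theta[k], mean_weights, groups)
               for k in range(n_trials)]

    all_phi_hat, all_phi = [], []
    pinned_flags = []
    offsets = {g: [] for g in ugroups}
    for r in range(n_repeats):
        assign = np.array_split(rng.permutation(n_trials), n_folds)
        for test_idx in assign:
            train_idx = np.setdiff1d(np.arange(n_trials), test_idx)
            paths = {}
            if align:
                for g in ugroups:
                    v_train = np.mean([partial[k][g] for k in train_idx], axis=0)
                    est_phase = predict_phase(v_train)
                    paths[g] = capped_dtw_align(est_phase, structure.phi,
                                                cap_s=cap_s, fs=structure.fs)
                    offsets[g].append(paths[g].mean_offset_s)
                    pinned_flags.append(paths[g].edge_pinned_fraction > 0.5)
            for k in test_idx:
                v_sum = np.zeros((T, 2))
                for g in ugroups:
                    v = partial[k][g]
                    if align:
                        src = paths[g].source_time(np.arange(T) / structure.fs)
                        idx = np.clip(np.round(src * structure.fs).astype(int), 0, T - 1)
                        v = v[idx]
                    v_sum += v
                all_phi_hat.append(predict_phase(v_sum))
                all_phi.append(structure.phi)
    result = reconstruction_report(np.concatenate(all_phi_hat),
                                   np.concatenate(all_phi))
    result.alignment_flagged = bool(np.mean(pinned_flags) > 0.5) if pinned_flags else False
    result.mean_offsets_s = {int(g): float(np.mean(v)) for g, v in offsets.items() if v}
    return result
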
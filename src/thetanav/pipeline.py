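"""End-to-end assembly: session bundle -> warped, condition-labeled trials.

This module wires the stages together in dependency order: artifact
rejection, individualized band estimation, band-amplitude extraction,
trial epoching, trajectory-DTW anchor identification, piecewise-linear
warping to the condition-mean timing, and segment-length normalization onto
the common task timeline.  The result is one :class:`TrialSet` per
condition, ready for the consistency, decoding and group-statistics stages.

Band amplitudes are carried at a reduced common rate (50 Hz by default):
theta envelopes have a bandwidth far below 25 Hz, so nothing the decoder or
the consistency statistic sees is lost, while warping and DTW stay cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import artifacts, bouts, spectral, warp
from .decode import TaskStructure, build_task_structure
from .synth import SessionBundle

DEFAULT_FS_COMMON = 50.0

__all__ = ["TrialSet", "PreparedSession", "estimate_bands", "prepare_session"]


@dataclass
class TrialSet:
    """Warped trials of one condition on the common task timeline."""

    condition: str
    trial_ids: list
    data: np.ndarray                 # (n_trials, C, T)
    behavior: dict = field(default_factory=dict)   # name -> (n_trials, T)
    fs: float = DEFAULT_FS_COMMON
    samples_per_segment: int = 0
    n_segments: int = 1

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class PreparedSession:
    """Everything downstream stages need, in one place."""

    trial_sets: dict                 # condition -> TrialSet
    structure: TaskStructure
    bands: dict                      # participant -> BandDefinition
    mask: artifacts.ArtifactMask
    band_series: np.ndarray          # (C, S') z-scored theta amplitude at fs_band
    fs_band: float
    bout_set: Optional[bouts.BoutSet]
    participants: np.ndarray
    mean_anchors_s: np.ndarray       # condition-mean real anchor times (trial-local)
    fs_neural: float
    fs_common: float


def estimate_bands(bundle: SessionBundle, mask, max_seconds: float = 120.0,
                   search=(3.0, 12.0)) -> dict:
    """Individual theta band per participant from mean amplitude spectra.

    Spectra are session means of wavelet amplitude over artifact-free
    real-walk samples; a contiguous chunk covering up to ``max_seconds`` of
    real-trial time keeps the transform small.
    """
    real = bundle.trials[bundle.trials.condition.str.startswith("real")]
    fs = bundle.fs
    chunks = []          # (i0, i1) spans of real trials, up to max_seconds total
    covered = 0.0
    margin = int(fs)     # 1 s trimmed per chunk edge against wavelet edge effects
    for row in real.itertuples():
        i0, i1 = int(row.start_s * fs), int(row.stop_s * fs)
        chunks.append((i0, i1))
        covered += row.stop_s - row.start_s
        if covered >= max_seconds:
            break
    flags = mask.flags if hasattr(mask, "flags") else None
    bands = {}
    freqs = spectral.morse_frequency_grid()
    for p in np.unique(bundle.participant_of_channel):
        chans = np.where(bundle.participant_of_channel == p)[0]
        num = np.zeros(len(freqs))
        den = 0
        for c in chans:
            for i0, i1 in chunks:
                tf = spectral.morse_tf_amplitude(bundle.signals[c, i0:i1], fs,
                                                 freqs=freqs)
                ok = np.ones(i1 - i0, dtype=bool)
                ok[:margin] = ok[-margin:] = False
                if flags is not None:
                    ok &= ~flags[c, i0:i1]
                num += tf.amp[0][:, ok].sum(axis=1)
                den += ok.sum()
        bands[int(p)] = spectral.find_individual_band(num / den, freqs, *search)
    return bands


def _epoch(series_c: np.ndarray, fs: float, start: float, stop: float,
           fs_out: float):
    """Resample one trial's span of a (C, S) array to fs_out."""
    n_out = int(round((stop - start) * fs_out))
    t_out = start + np.arange(n_out) / fs_out
    t_full = np.arange(series_c.shape[-1]) / fs
    if series_c.ndim == 1:
        return np.interp(t_out, t_full, series_c)
    return np.vstack([np.interp(t_out, t_full, row) for row in series_c])


def prepare_session(bundle: SessionBundle, fs_common: float = DEFAULT_FS_COMMON,
                    detect_bout_set: bool = False,
                    bands: Optional[dict] = None,
                    band_max_seconds: float = 120.0) -> PreparedSession:
    """Run the preprocessing chain on a session bundle.

    When ``bands`` is given (participant -> BandDefinition) the expensive
    band-estimation transform is skipped; ``detect_bout_set`` additionally
    runs the full-grid background fit and bout detection (needed only by
    bout-level analyses).
    """
    fs = bundle.fs
    mask = artifacts.detect_ied(bundle.signals, fs, trials=bundle.trials)
    if bands is None:
        bands = estimate_bands(bundle, mask, max_seconds=band_max_seconds)

    C = bundle.signals.shape[0]
    band_series = None
    fs_band = None
    for p, band in bands.items():
        chans = np.where(bundle.participant_of_channel == p)[0]
        series, fs_band = spectral.band_amplitude_series(
            bundle.signals[chans], fs, band, mask=mask.flags[chans],
            fs_out=4.0 * fs_common)
        if band_series is None:
            band_series = np.empty((C, series.shape[1]))
        band_series[chans] = series

    bout_set = None
    if detect_bout_set:
        grid = spectral.morse_frequency_grid()
        tf = spectral.morse_tf_amplitude(bundle.signals, fs, freqs=grid,
                                         dtype=np.float32)
        bg = bouts.fit_background(tf, mask=mask)
        band0 = bands[int(bundle.participant_of_channel[0])]
        bout_set = bouts.detect_bouts(tf, bg, band0, mask=mask)

    # ---- real trials: DTW anchors ---------------------------------------
    trials = bundle.trials
    real = trials[trials.condition.str.startswith("real")
                  & ~trials.trial.isin(mask.excluded_trials)]
    real_ids = list(real.trial)
    trajs = [bundle.trajectories[t] for t in real_ids]
    anchors, _medoid = warp.dtw_align_trajectories(trajs, bundle.route)
    kept = [(tid, a) for tid, a in zip(real_ids, anchors) if a is not None]
    real_ids = [t for t, _ in kept]
    anchors = [a for _, a in kept]
    mean_anchors = np.mean(np.vstack(anchors), axis=0)
    n_segments = len(mean_anchors) - 1
    spans = np.diff(mean_anchors)
    samples_per_segment = int(round(spans.mean() * fs_common))
    T = n_segments * samples_per_segment
    structure = build_task_structure(
        np.arange(n_segments + 1) * samples_per_segment, T, fs=fs_common)

    rel_positions = _relative_positions(mean_anchors, samples_per_segment)

    trial_sets = {}
    # real condition
    data = np.empty((len(real_ids), C, T))
    behavior = {k: np.empty((len(real_ids), T)) for k in
                ("speed", "hip_yaw_vel", "head_yaw_vel")}
    for i, (tid, anch) in enumerate(zip(real_ids, anchors)):
        row = trials[trials.trial == tid].iloc[0]
        ep = _epoch(band_series, fs_band, row.start_s, row.stop_s, fs_common)
        t_loc = np.arange(ep.shape[1]) / fs_common
        warped = warp.piecewise_linear_warp(ep, t_loc, anch, mean_anchors)
        data[i] = warp.normalize_segment_lengths(
            warped, np.arange(warped.shape[1]) / fs_common, mean_anchors,
            samples_per_segment)[:, :T]
        tr = bundle.trajectories[tid]
        beh = {
            "speed": np.interp(t_loc, tr.t, tr.speed),
            "hip_yaw_vel": np.interp(t_loc, tr.t[:-1],
                                     np.abs(np.diff(tr.hip_yaw)) * bundle.config.fs_motion),
            "head_yaw_vel": np.interp(t_loc, tr.t[:-1],
                                      np.abs(np.diff(tr.head_yaw)) * bundle.config.fs_motion),
        }
        for k, v in beh.items():
            wv = warp.piecewise_linear_warp(v, t_loc, anch, mean_anchors)
            behavior[k][i] = warp.normalize_segment_lengths(
                wv, np.arange(len(wv)) / fs_common, mean_anchors,
                samples_per_segment)[:T]
    cond_real = real.condition.iloc[0]
    trial_sets[cond_real] = TrialSet(condition=cond_real, trial_ids=real_ids,
                                     data=data, behavior=behavior, fs=fs_common,
                                     samples_per_segment=samples_per_segment,
                                     n_segments=n_segments)

    # imagined / control: linear warp to condition mean, then the common grid
    for cond in [c for c in trials.condition.unique()
                 if not c.startswith("real")]:
        sub = trials[(trials.condition == cond)
                     & ~trials.trial.isin(mask.excluded_trials)]
        ids = list(sub.trial)
        data = np.empty((len(ids), C, T))
        for i, row in enumerate(sub.itertuples()):
            ep = _epoch(band_series, fs_band, row.start_s, row.stop_s, fs_common)
            dur = row.stop_s - row.start_s
            t_loc = np.arange(ep.shape[1]) / fs_common
            t_sample = rel_positions * dur
            data[i] = np.vstack([np.interp(t_sample, t_loc, r) for r in ep])
        trial_sets[cond] = TrialSet(condition=cond, trial_ids=ids, data=data,
                                    fs=fs_common,
                                    samples_per_segment=samples_per_segment,
                                    n_segments=n_segments)

    return PreparedSession(trial_sets=trial_sets, structure=structure,
                           bands=bands, mask=mask, band_series=band_series,
                           fs_band=fs_band,
                           bout_set=bout_set,
                           participants=bundle.participant_of_channel,
                           mean_anchors_s=mean_anchors, fs_neural=fs,
                           fs_common=fs_common)


def _relative_positions(mean_anchors: np.ndarray, samples_per_segment: int) -> np.ndarray:
    """Relative (0-1) time of each common-timeline sample, segment-normalized
    to the mean real-segment proportions."""
    total = mean_anchors[-1] - mean_anchors[0]
    rel = []
    for a, b in zip(mean_anchors[:-1], mean_anchors[1:]):
        frac = np.arange(samples_per_segment) / samples_per_segment
        rel.append((a - mean_anchors[0] + frac * (b - a)) / total)
    return np.concatenate(rel)


def turn_times_from_trials(trials: pd.DataFrame) -> dict:
    """trial id -> absolute turn times parsed from the trial table."""
    out = {}
    for row in trials.itertuples():
        out[int(row.trial)] = json.loads(row.turn_times)
    return out
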
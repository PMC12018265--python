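"""Oscillatory bout detection (BOSC-style).

The background at each channel is modelled as a colored-noise floor: a
robust linear regression of log10 mean wavelet power on log10 frequency.
Under Gaussian background noise the wavelet power at one frequency is
exponentially distributed (chi-squared with 2 degrees of freedom, scaled to
the fitted mean), so the detection threshold at each frequency is the 0.95
quantile of that distribution.  A bout is a run of supra-threshold power at
a band frequency lasting at least two cycles (duration >= 2 / f).
Artifact-masked samples break runs: a bout cannot span an IED.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .exceptions import InsufficientDataError
from .spectral import BandDefinition, TFAmplitude

MIN_CYCLES = 2.0
THRESHOLD_QUANTILE = 0.95

__all__ = ["BackgroundFit", "BoutSet", "fit_background", "detect_bouts",
           "bout_indicator", "bout_rate_timecourse", "preturn_prevalence"]


@dataclass
class BackgroundFit:
    """Per-channel log-log background fit and detection thresholds.

    ``slope`` is the PSD-equivalent exponent: constant-relative-bandwidth
    wavelets measure power ~ PSD(f) * bandwidth(f) with bandwidth
    proportional to f, so the raw wavelet-power slope is corrected by -1.
    A 1/f^alpha background therefore yields slope ~ -alpha (and white noise
    ~ 0).  Thresholds are computed from the uncorrected wavelet-power fit.
    """

    slope: np.ndarray          # (C,) PSD-equivalent exponent
    wavelet_slope: np.ndarray  # (C,) raw fit on wavelet power
    intercept: np.ndarray      # (C,)
    freqs: np.ndarray          # (F,)
    power_threshold: np.ndarray  # (C, F) at the 0.95 level

    def mean_power(self, c: int) -> np.ndarray:
        return 10.0 ** (self.intercept[c] + self.wavelet_slope[c] * np.log10(self.freqs))


@dataclass
class BoutSet:
    """Detected bout intervals plus per-channel summaries."""

    intervals: pd.DataFrame        # channel, freq, start_s, stop_s, mean_amp
    band_intervals: pd.DataFrame   # channel, start_s, stop_s (per-frequency merged)
    fs: float
    n_samples: int
    n_channels: int

    def prevalence(self, valid: Optional[np.ndarray] = None) -> np.ndarray:
        """Percent of (valid) time inside detected episodes, per channel.

        Pepisode convention: the fraction is computed per frequency bin and
        averaged over the band's bins (the union across bins would inflate
        the nominal false-positive level on pure background).
        """
        n_valid = self.n_samples if valid is None else int(np.sum(valid))
        out = np.zeros(self.n_channels)
        freqs = sorted(self.intervals.freq.unique())
        if not freqs or n_valid == 0:
            return out
        for c in range(self.n_channels):
            sub = self.intervals[self.intervals.channel == c]
            per_bin = []
            for f in freqs:
                sf = sub[sub.freq == f]
                if valid is None:
                    covered = (sf.stop_s - sf.start_s).sum() * self.fs
                else:
                    ind = np.zeros(self.n_samples, dtype=bool)
                    for row in sf.itertuples():
                        ind[int(round(row.start_s * self.fs)):
                            int(round(row.stop_s * self.fs))] = True
                    covered = np.sum(ind & valid)
                per_bin.append(covered / n_valid)
            out[c] = 100.0 * float(np.mean(per_bin))
        return out

    def peak_bin_prevalence(self, freq: float,
                            valid: Optional[np.ndarray] = None) -> np.ndarray:
        """Per-channel episode fraction (%) at the bin nearest ``freq``."""
        freqs = np.array(sorted(self.intervals.freq.unique()))
        if len(freqs) == 0:
            return np.zeros(self.n_channels)
        f = freqs[np.argmin(np.abs(freqs - freq))]
        n_valid = self.n_samples if valid is None else int(np.sum(valid))
        out = np.zeros(self.n_channels)
        for c in range(self.n_channels):
            sf = self.intervals[(self.intervals.channel == c)
                                & (self.intervals.freq == f)]
            if valid is None:
                out[c] = 100.0 * (sf.stop_s - sf.start_s).sum() * self.fs / n_valid
            else:
                ind = np.zeros(self.n_samples, dtype=bool)
                for row in sf.itertuples():
                    ind[int(round(row.start_s * self.fs)):
                        int(round(row.stop_s * self.fs))] = True
                out[c] = 100.0 * np.sum(ind & valid) / n_valid
        return out

    def indicator(self) -> np.ndarray:
        """(C, S) boolean band-level bout indicator."""
        ind = np.zeros((self.n_channels, self.n_samples), dtype=bool)
        for row in self.band_intervals.itertuples():
            a = int(round(row.start_s * self.fs))
            b = int(round(row.stop_s * self.fs))
            ind[int(row.channel), a:b] = True
        return ind

    def mean_duration(self) -> float:
        if len(self.band_intervals) == 0:
            return np.nan
        return float((self.band_intervals.stop_s - self.band_intervals.start_s).mean())

    def mean_amplitude(self) -> float:
        if len(self.intervals) == 0:
            return np.nan
        return float(self.intervals.mean_amp.mean())

    def summary(self) -> pd.DataFrame:
        prev = self.prevalence()
        rows = []
        for c in range(self.n_channels):
            sel = self.band_intervals.channel == c
            self_ = self.intervals.channel == c
            rows.append(dict(
                channel=c, prevalence_pct=prev[c],
                mean_duration_s=float((self.band_intervals.stop_s - self.band_intervals.start_s)[sel].mean())
                if sel.any() else np.nan,
                bout_amplitude=float(self.intervals.mean_amp[self_].mean()) if self_.any() else np.nan,
            ))
        return pd.DataFrame(rows)


def fit_background(tf: TFAmplitude, mask=None,
                   exclude_band: Optional[tuple] = None) -> BackgroundFit:
    """Robust log-log fit of mean wavelet power versus frequency.

    ``exclude_band`` optionally removes a frequency range (e.g. a strong
    oscillatory peak) from the fit without affecting the thresholds, which
    are produced for every frequency of the transform.
    """
    if tf.zscored:
        raise ValueError("background fit requires raw (non z-scored) amplitudes")
    C, F, S = tf.amp.shape
    min_samples = int(10 * tf.fs)
    slope = np.empty(C)
    intercept = np.empty(C)
    thr = np.empty((C, F))
    fit_sel = np.ones(F, dtype=bool)
    if exclude_band is not None:
        fit_sel &= ~((tf.freqs >= exclude_band[0]) & (tf.freqs <= exclude_band[1]))
    logf = np.log10(tf.freqs)
    for c in range(C):
        if mask is not None:
            flags = mask.flags_for(c) if hasattr(mask, "flags_for") else np.asarray(mask)
            if flags.ndim == 2:
                flags = flags[c]
            ok = ~flags
        else:
            ok = np.ones(S, dtype=bool)
        if ok.sum() < min_samples:
            raise InsufficientDataError("need >= 10 s of unmasked data for the background fit")
        meanpow = (tf.amp[c].astype(np.float64) ** 2)[:, ok].mean(axis=1)
        rlm = sm.RLM(np.log10(meanpow[fit_sel]),
                     sm.add_constant(logf[fit_sel]), M=sm.robust.norms.HuberT())
        res = rlm.fit()
        intercept[c], slope[c] = res.params
        mean_bg = 10.0 ** (intercept[c] + slope[c] * logf)
        # power ~ mean_bg * chi2(2) / 2
        thr[c] = mean_bg * chi2.ppf(THRESHOLD_QUANTILE, 2) / 2.0
    return BackgroundFit(slope=slope - 1.0, wavelet_slope=slope,
                         intercept=intercept, freqs=tf.freqs.copy(),
                         power_threshold=thr)


def _runs_bool(mask: np.ndarray):
    d = np.diff(np.concatenate([[0], mask.astype(np.int8), [0]]))
    return zip(np.where(d == 1)[0], np.where(d == -1)[0])


def detect_bouts(tf: TFAmplitude, bg: BackgroundFit, band: BandDefinition,
                 mask=None) -> BoutSet:
    """Detect supra-threshold oscillatory episodes within the band.

    Per-frequency detections lasting >= 2 cycles are kept; per channel, the
    union over band frequencies gives band-level bout intervals.
    """
    if tf.amp.shape[1] != len(bg.freqs) or not np.allclose(tf.freqs, bg.freqs):
        raise ValueError("transform and background fit use different frequency grids")
    C, F, S = tf.amp.shape
    sel = np.where((tf.freqs >= band.f_lo) & (tf.freqs <= band.f_hi))[0]
    rows = []
    band_ind = np.zeros((C, S), dtype=bool)
    for c in range(C):
        if mask is not None:
            flags = mask.flags_for(c) if hasattr(mask, "flags_for") else np.asarray(mask)
            if flags.ndim == 2:
                flags = flags[c]
        else:
            flags = np.zeros(S, dtype=bool)
        for k in sel:
            f = tf.freqs[k]
            power = tf.amp[c, k].astype(np.float64) ** 2
            above = (power > bg.power_threshold[c, k]) & ~flags
            min_len = int(np.ceil(MIN_CYCLES / f * tf.fs))
            for a, b in _runs_bool(above):
                if b - a >= min_len:
                    rows.append(dict(channel=c, freq=f, start_s=a / tf.fs,
                                     stop_s=b / tf.fs,
                                     mean_amp=float(tf.amp[c, k, a:b].mean())))
                    band_ind[c, a:b] = True
    intervals = pd.DataFrame(rows, columns=["channel", "freq", "start_s", "stop_s", "mean_amp"])
    band_rows = []
    for c in range(C):
        for a, b in _runs_bool(band_ind[c]):
            band_rows.append(dict(channel=c, start_s=a / tf.fs, stop_s=b / tf.fs))
    band_intervals = pd.DataFrame(band_rows, columns=["channel", "start_s", "stop_s"])
    return BoutSet(intervals=intervals, band_intervals=band_intervals, fs=tf.fs,
                   n_samples=S, n_channels=C)


def bout_indicator(bouts: BoutSet) -> np.ndarray:
    """Alias for :meth:`BoutSet.indicator` (used by the warping stage)."""
    return bouts.indicator()


def bout_rate_timecourse(warped_indicator: np.ndarray) -> np.ndarray:
    """Percent of trials containing a bout at each warped time point.

    Parameters
    ----------
    warped_indicator : (n_trials, C, T) bout indicator on the common timeline.
    """
    w = np.asarray(warped_indicator)
    if w.ndim != 3 or w.shape[0] == 0:
        raise ValueError("need a (n_trials, channels, time) array with >= 1 trial")
    return 100.0 * (w > 0.5).mean(axis=0)


def preturn_prevalence(indicator: np.ndarray, fs: float, trials: pd.DataFrame,
                       turn_times: dict, window_s: float = 2.0) -> np.ndarray:
    """Fraction of the pre-turn window occupied by bouts, per channel.

    ``turn_times`` maps trial id -> absolute turn times (s).  Windows
    extending before the trial start are clipped (with a warning).
    """
    import warnings
    C, S = indicator.shape
    acc = np.zeros(C)
    n = 0
    for row in trials.itertuples():
        for turn in turn_times.get(int(row.trial), []):
            a = turn - window_s
            if a < row.start_s:
                warnings.warn("pre-turn window clipped at trial start")
                a = row.start_s
            ia, ib = int(round(a * fs)), int(round(turn * fs))
            if ib > ia:
                acc += indicator[:, ia:ib].mean(axis=1)
                n += 1
    if n == 0:
        raise ValueError("no turns available")
    return acc / n
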
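"""End-to-end validation studies on synthetic sessions.

Each function runs one self-contained study — generating sessions with the
``synth`` module, running the analysis chain, and scoring the result
against the generator's ground truth — and returns a flat dict of named
quantities.  The studies are sized for a single desktop CPU; the methods
note documents the problem sizes (trial counts, replicate counts,
cross-validation repeats) used here versus the full-session defaults.

These are the same computations `scripts/acceptance.py` reports and
`tests/test_acceptance.py` asserts on.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import bouts, decode, pipeline, spectral, warp
from .consistency import condition_difference_test, consistency_table, split_half_consistency
from .decode import build_task_structure, circular_shift_null
from .synth import SynthConfig, make_route_template, simulate_session, simulate_trajectory

__all__ = ["decoder_recovery", "imagined_generalization",
           "consistency_calibration", "bout_detector_validation",
           "ied_detector_validation", "warp_validation",
           "oracle_equivalence", "structure_crosscorrelogram"]


def _seeds(seed: int, n: int, salt: int) -> np.ndarray:
    return np.random.SeedSequence([int(seed), salt]).generate_state(n) % (2 ** 31)


def _real_decode(prep, n_folds=10, n_repeats=10, seed=0, shuffle=False):
    rs = next(ts for c, ts in prep.trial_sets.items() if c.startswith("real"))
    structure = prep.structure
    if shuffle:
        rng = np.random.default_rng(seed + 1)
        perm = rng.permutation(len(structure.phi))
        structure = build_task_structure(
            np.arange(structure.n_segments + 1) * structure.samples_per_segment,
            len(structure.phi), fs=structure.fs)
        structure.phi = structure.phi[perm]
        structure.responses = structure.responses[perm]
    model = decode.fit_decoder(rs.data, structure, n_folds=n_folds,
                               n_repeats=n_repeats, seed=seed)
    phi_hat = decode.predict_phase(model.oof_pred).reshape(-1)
    phi = np.tile(structure.phi, model.oof_pred.shape[0] * model.oof_pred.shape[1])
    return decode.reconstruction_report(phi_hat, phi), model


def decoder_recovery(seed: int = 0) -> dict:
    """Cross-validated real-trial decoding at the study defaults
    (18 channels, 24 real trials, SNR 2, 10 x 10 CV), against shuffled
    task labels."""
    cfg = SynthConfig(rng_seed=int(_seeds(seed, 1, 11)[0]), n_imag=0, n_control=0)
    bundle = simulate_session(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prep = pipeline.prepare_session(bundle)
    res, _ = _real_decode(prep, seed=seed)
    res_sh, _ = _real_decode(prep, seed=seed, shuffle=True)
    return {
        "real_decoding_mean_abs_error_deg": dict(value=res.mean_abs_error_deg, n=24),
        "shuffled_decoding_mean_abs_error_deg": dict(value=res_sh.mean_abs_error_deg, n=24),
    }


def imagined_generalization(seed: int = 0, n_replicates: int = 50) -> dict:
    """Held-out imagined-trial decoding with capped DTW alignment.

    Replicate sessions use 12 trials per condition with short segments and
    10 folds x 2 repeats for the alignment cross-validation.
    """
    seeds = _seeds(seed, n_replicates, 23)
    imag_err, ctrl_err, imag_lt_ctrl, ctrl_null_ok = [], [], [], []
    for s in seeds:
        cfg = SynthConfig(rng_seed=int(s), n_real=12, n_imag=12, n_control=12,
                          seg_length_range=(2.2, 3.0))
        bundle = simulate_session(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prep = pipeline.prepare_session(bundle, band_max_seconds=45.0)
        rs = next(ts for c, ts in prep.trial_sets.items() if c.startswith("real"))
        model = decode.fit_decoder(rs.data, prep.structure, n_folds=10,
                                   n_repeats=1, seed=int(s) % 10000)
        imag = next(ts for c, ts in prep.trial_sets.items() if c.startswith("imag"))
        ctrl = prep.trial_sets["control"]
        kw = dict(groups=prep.participants, n_folds=10, n_repeats=2,
                  seed=int(s) % 10000)
        res_i = decode.decode_imagined(model.mean_weights, imag.data,
                                       prep.structure, **kw)
        res_c = decode.decode_imagined(model.mean_weights, ctrl.data,
                                       prep.structure, **kw)
        imag_err.append(res_i.mean_abs_error_deg)
        ctrl_err.append(res_c.mean_abs_error_deg)
        imag_lt_ctrl.append(res_i.mean_abs_error_deg < res_c.mean_abs_error_deg)
        null = circular_shift_null(res_c.phi_hat, res_c.phi, n_shifts=200,
                                   seed=int(s) % 10000)
        ctrl_null_ok.append(null.p > 0.05)
    return {
        "imagined_mean_abs_error_deg": dict(value=float(np.mean(imag_err)), n=n_replicates),
        "control_mean_abs_error_deg": dict(value=float(np.mean(ctrl_err)), n=n_replicates),
        "imagined_better_than_control_pct": dict(
            value=100.0 * float(np.mean(imag_lt_ctrl)), n=n_replicates),
        "control_shift_null_nonsig_pct": dict(
            value=100.0 * float(np.mean(ctrl_null_ok)), n=n_replicates),
    }


def consistency_calibration(seed: int = 0, n_null: int = 400,
                            n_power: int = 25) -> dict:
    """Type-I error and power of the multilevel block permutation test.

    Null simulations draw per-channel consistency values with a participant
    random effect (so within-block dependence is present); power replicates
    run the full pipeline on small structured-vs-control sessions at the
    default SNR.
    """
    parts = np.repeat(np.arange(5), [4, 4, 4, 3, 3])
    rej = 0
    for i, s in enumerate(_seeds(seed, n_null, 31)):
        r = np.random.default_rng(int(s))
        base = r.normal(0.0, 0.05, 5)
        rows = []
        for cond in ("a", "b"):
            vals = base[parts] + r.normal(0.0, 0.1, len(parts))
            for c, v in enumerate(vals):
                rows.append(dict(participant=parts[c], channel=c,
                                 condition=cond, consistency=v))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = condition_difference_test(pd.DataFrame(rows), "a", "b",
                                            n_perm=250, seed=int(s))
        rej += res.p <= 0.05

    power_hits = 0
    for s in _seeds(seed, n_power, 37):
        cfg = SynthConfig(rng_seed=int(s), n_real=4, n_imag=10, n_control=10,
                          seg_length_range=(2.2, 3.0))
        bundle = simulate_session(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prep = pipeline.prepare_session(bundle, band_max_seconds=30.0)
            imag_cond = next(c for c in prep.trial_sets if c.startswith("imag"))
            table = consistency_table(
                {c: prep.trial_sets[c].data for c in (imag_cond, "control")},
                prep.participants, n_splits=300, seed=int(s))
            res = condition_difference_test(table, imag_cond, "control",
                                            n_perm=500, seed=int(s))
        power_hits += res.p <= 0.05
    return {
        "block_permutation_type1_error": dict(value=rej / n_null, n=n_null),
        "consistency_test_power": dict(value=power_hits / n_power, n=n_power),
    }


def bout_detector_validation(seed: int = 0, n_seeds: int = 5,
                             snr: float = 3.0) -> dict:
    """Sensitivity, null false-positive level, and recovery of the
    configured prevalence and duration, at the boundary SNR of 3.

    Recovery is background-corrected: the false-episode floor is measured
    on a paired bout-free session with the same seed, and duration uses the
    median episode length at the peak bin (episode durations are
    right-skewed by merges with background excursions).  Bouts are injected
    at the canonical 8 Hz theta peak, where a 0.5 s bout spans four cycles;
    at the low end of the theta range the transform's temporal resolution
    (sigma_t ~ 1.23/f) approaches the bout length and blurs detected widths
    — an instrument limit, not a detector defect.
    """
    sens, null_prev, prev_err, dur_err = [], [], [], []
    for s in _seeds(seed, n_seeds, 41):
        base = dict(rng_seed=int(s), n_channels=2, n_participants=1, n_real=8,
                    n_imag=0, n_control=0, continuous_mod_snr=0.0,
                    delta_amp_snr=0.0, beta_amp_snr=0.0, ied_rate=0.0,
                    theta_freq=np.array([8.0]),
                    seg_length_range=(2.5, 3.5))
        bundle = simulate_session(SynthConfig(bout_amp_snr=snr,
                                              bout_fraction=0.2, **base))
        null_bundle = simulate_session(SynthConfig(bout_amp_snr=0.0,
                                                   bout_fraction=0.0, **base))
        f0 = bundle.config.theta_freq[0]
        band = spectral.BandDefinition(f_peak=f0, f_lo=f0 - 2.0, f_hi=f0 + 2.0)
        real = bundle.trials[bundle.trials.condition.str.startswith("real")]
        valid = np.zeros(bundle.n_samples, dtype=bool)
        for r in real.itertuples():
            valid[int(r.start_s * bundle.fs):int(r.stop_s * bundle.fs)] = True

        def run(bun):
            tf = spectral.morse_tf_amplitude(bun.signals, bun.fs)
            bg = bouts.fit_background(tf)
            return bouts.detect_bouts(tf, bg, band)

        bs = run(bundle)
        bs_null = run(null_bundle)
        ind = bs.indicator()
        truth = bundle.truth.bout_intervals
        sens.append(np.mean([
            ind[int(r.channel), int(r.start_s * bundle.fs):int(r.stop_s * bundle.fs)].any()
            for r in truth.itertuples()]))
        null_prev.extend(bs_null.prevalence())
        floor = bs_null.peak_bin_prevalence(f0, valid=valid).mean()
        detected = bs.peak_bin_prevalence(f0, valid=valid).mean() - floor
        true_frac = 100.0 * (truth.stop_s - truth.start_s).sum() \
            / ((real.stop_s - real.start_s).sum() * bundle.config.n_channels)
        prev_err.append(abs(detected - true_frac) / true_frac)
        freqs = np.array(sorted(bs.intervals.freq.unique()))
        fpk = freqs[np.argmin(np.abs(freqs - f0))]
        sub = bs.intervals[bs.intervals.freq == fpk]
        dur_det = float((sub.stop_s - sub.start_s).median())
        dur_true = float((truth.stop_s - truth.start_s).mean())
        dur_err.append(abs(dur_det - dur_true) / dur_true)
    return {
        "bout_sensitivity_pct": dict(value=100.0 * float(np.mean(sens)), n=n_seeds),
        "bout_null_prevalence_pct": dict(value=float(np.mean(null_prev)), n=n_seeds),
        "bout_prevalence_recovery_relerr_pct": dict(
            value=100.0 * float(np.mean(prev_err)), n=n_seeds),
        "bout_duration_recovery_relerr_pct": dict(
            value=100.0 * float(np.mean(dur_err)), n=n_seeds),
    }


def ied_detector_validation(seed: int = 0, n_seeds: int = 20) -> dict:
    """Every injected discharge overlapped; flagged fraction matches the
    guard-extended injected fraction to within a percentage point."""
    from .artifacts import EXTEND_S, detect_ied
    overlap, frac_diff = [], []
    for s in _seeds(seed, n_seeds, 43):
        cfg = SynthConfig(rng_seed=int(s), n_channels=4, n_participants=1,
                          n_real=4, n_imag=0, n_control=0, ied_rate=2.0,
                          seg_length_range=(2.5, 3.5))
        bundle = simulate_session(cfg)
        mask = detect_ied(bundle.signals, bundle.fs, trials=bundle.trials)
        truth = bundle.truth.ied_intervals
        hits = [mask.flags[int(r.channel),
                           int(r.start_s * bundle.fs):int(r.stop_s * bundle.fs)].any()
                for r in truth.itertuples()]
        overlap.append(np.mean(hits) if hits else 1.0)
        injected = np.zeros(mask.flags.shape, dtype=bool)
        ext = int(round(EXTEND_S * bundle.fs))
        for r in truth.itertuples():
            a = max(int(r.start_s * bundle.fs) - ext, 0)
            b = min(int(r.stop_s * bundle.fs) + ext, bundle.n_samples)
            injected[int(r.channel), a:b] = True
        frac_diff.append(100.0 * abs(mask.flags.mean() - injected.mean()))
    return {
        "ied_overlap_pct": dict(value=100.0 * float(np.mean(overlap)), n=n_seeds),
        "ied_fraction_abs_diff_pp": dict(value=float(np.mean(frac_diff)), n=n_seeds),
    }


def warp_validation(seed: int = 0) -> dict:
    """Turn-anchor recovery and capped-DTW shift recovery/saturation."""
    cfg = SynthConfig(rng_seed=int(_seeds(seed, 1, 47)[0]),
                      seg_length_range=(3.0, 4.0)).resolve()
    route = make_route_template(4, "left", cfg.rng_seed)
    trajs = [simulate_trajectory(route, cfg, trial_seed=i) for i in range(12)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anchors, _ = warp.dtw_align_trajectories(trajs, route)
    errs = [np.abs(a[1:-1] - tr.turn_times).mean()
            for tr, a in zip(trajs, anchors) if a is not None]

    fs = 50.0
    seg = 5.0
    t = np.arange(int(25 * fs)) / fs
    phi = (t % seg) / seg * 2 * np.pi
    shift_errs = []
    for shift in (0.5, 1.0, 1.5):
        est = np.interp(t - shift, t, phi)
        p = warp.capped_dtw_align(est, phi, cap_s=2.0, fs=fs)
        shift_errs.append(abs(p.mean_offset_s - shift))
    est = np.interp(t - 2.4, t, phi)
    sat = warp.capped_dtw_align(est, phi, cap_s=2.0, fs=fs).mean_offset_s
    return {
        "anchor_recovery_error_s": dict(value=float(np.mean(errs)), n=len(errs)),
        "dtw_shift_recovery_error_s": dict(value=float(np.max(shift_errs)), n=3),
        "dtw_saturated_offset_s": dict(value=float(abs(sat)), n=1),
    }


def oracle_equivalence(seed: int = 0) -> dict:
    """Decoder OLS vs explicit normal equations; split-half consistency vs
    a direct two-group computation with a fixed partition."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((160, 7))
    Y = rng.standard_normal((160, 2))
    W, _ = decode.fit_weights(X, Y)
    D = np.column_stack([np.ones(len(X)), X])
    W_ref = np.linalg.solve(D.T @ D, D.T @ Y)
    ols_dev = float(np.max(np.abs(W - W_ref)))

    trials = rng.standard_normal((8, 60)) + np.sin(np.arange(60) / 5)
    class _FixedRng:
        def permutation(self, n):
            return np.arange(n)
    res = split_half_consistency(trials, n_splits=1, rng=_FixedRng())
    direct = np.corrcoef(trials[:4].mean(axis=0), trials[4:].mean(axis=0))[0, 1]
    split_dev = float(abs(res.value - direct))
    return {
        "ols_oracle_max_abs_dev": dict(value=ols_dev, n=160),
        "splithalf_oracle_abs_dev": dict(value=split_dev, n=8),
    }


def structure_crosscorrelogram(seed: int = 0) -> dict:
    """Side peaks at +/- one segment lag on structured data versus the
    white-noise bound."""
    cfg = SynthConfig(rng_seed=int(_seeds(seed, 1, 53)[0]), n_real=12,
                      n_imag=0, n_control=0, seg_length_range=(2.5, 3.5))
    bundle = simulate_session(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prep = pipeline.prepare_session(bundle, band_max_seconds=45.0)
    rs = next(iter(prep.trial_sets.values()))
    pref = bundle.config.channel_phase_pref
    c = int(np.argmin(np.abs(pref - 3 * np.pi / 2)))   # -sin-like channel
    series = rs.data[:, c, :].mean(axis=0)
    lags, r = decode.crosscorrelogram_route(series, prep.structure)
    L = prep.structure.samples_per_segment
    i0 = len(r) // 2
    side = min(r[i0 + L], r[i0 - L])
    rng = np.random.default_rng(seed)
    noise_max = float(np.mean([
        np.max(np.abs(decode.crosscorrelogram_route(
            rng.standard_normal(len(series)), prep.structure)[1]
            [i0 - L // 2:i0 + L // 2]))
        for _ in range(20)]))
    return {
        "crosscorr_side_peak": dict(value=float(side), n=12),
        "crosscorr_noise_bound": dict(value=noise_max, n=20),
    }
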
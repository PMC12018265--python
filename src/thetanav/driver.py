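"""Pipeline driver: run all stages on a stored session and write reports.

Stages run in dependency order (spectral -> artifacts -> bouts/warp ->
consistency -> decode -> stats).  Every stage writes tidy CSV outputs and
appends to a machine-readable log (stage, parameters, seed, input hash) so
any output can be regenerated from the logged config and seed alone.  The
run is idempotent for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import bouts, decode, io, pipeline, stats
from .config import PipelineConfig
from .consistency import (condition_difference_test, consistency_table,
                          cross_condition_spatial_correlation)

__all__ = ["run_pipeline"]


def _log(log_path: Path, stage: str, seed: int, params: dict, extra: dict = None):
    entry = dict(stage=stage, seed=seed, params=params,
                 wallclock_s=round(time.time(), 3), **(extra or {}))
    with open(log_path, "a") as fh:
        fh.write(json.dumps(entry, default=str) + "\n")


def run_pipeline(config: PipelineConfig, session_dir, out_dir) -> dict:
    """Execute the full analysis on one stored session; returns a report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline_log.jsonl"
    sig_hash = hashlib.sha256(
        (Path(session_dir) / "signals.bin").read_bytes()).hexdigest()[:16]
    cfg_dict = dataclasses.asdict(config)

    bundle = io.load_session(session_dir)
    _log(log_path, "load", config.seed, {"session": str(session_dir)},
         {"signals_sha256": sig_hash})

    prep = pipeline.prepare_session(bundle, fs_common=config.fs_common,
                                    detect_bout_set=config.run_bouts)
    prep.mask.intervals().to_csv(out / "ied_intervals.csv", index=False)
    pd.DataFrame([dict(participant=p, f_peak=b.f_peak, f_lo=b.f_lo, f_hi=b.f_hi)
                  for p, b in prep.bands.items()]).to_csv(
        out / "individual_bands.csv", index=False)
    _log(log_path, "preprocess", config.seed, cfg_dict)

    report = dict(ied_fraction_pct=prep.mask.ied_fraction,
                  excluded_trials=prep.mask.excluded_trials)

    if config.run_bouts and prep.bout_set is not None:
        prep.bout_set.band_intervals.to_csv(out / "bout_intervals.csv", index=False)
        prep.bout_set.summary().to_csv(out / "bout_summary.csv", index=False)
        report["bout_prevalence_pct"] = float(np.mean(prep.bout_set.prevalence()))
        report["bout_mean_duration_s"] = prep.bout_set.mean_duration()
        _log(log_path, "bouts", config.seed, cfg_dict)

    conditions = sorted(prep.trial_sets)
    if config.run_consistency:
        table = consistency_table(
            {c: prep.trial_sets[c].data for c in conditions
             if prep.trial_sets[c].n_trials >= 4},
            prep.participants, n_splits=config.n_splits, seed=config.seed)
        table.to_csv(out / "consistency.csv", index=False)
        tests = []
        cond_real = next((c for c in conditions if c.startswith("real")), None)
        cond_imag = next((c for c in conditions if c.startswith("imag")), None)
        for a, b in [(cond_real, "control"), (cond_imag, "control")]:
            if a and b in conditions:
                res = condition_difference_test(table, a, b,
                                                n_perm=config.n_perm,
                                                seed=config.seed)
                tests.append(dict(contrast=f"{a}>{b}", statistic=res.observed,
                                  p=res.p, cohens_d=res.cohens_d,
                                  ci_lo=res.ci[0], ci_hi=res.ci[1]))
        n_chan = table.channel.nunique()
        if cond_real and cond_imag and n_chan >= 6:
            sp = cross_condition_spatial_correlation(table, cond_real, cond_imag,
                                                     n_perm=config.n_perm,
                                                     seed=config.seed)
            tests.append(dict(contrast=f"spatial_r({cond_real},{cond_imag})",
                              statistic=sp.observed, p=sp.p,
                              cohens_d=None, ci_lo=None, ci_hi=None))
        pd.DataFrame(tests).to_csv(out / "consistency_tests.csv", index=False)
        report["consistency_tests"] = tests
        _log(log_path, "consistency", config.seed, cfg_dict)

    if config.run_decode:
        cond_real = next((c for c in conditions if c.startswith("real")), None)
        real_set = prep.trial_sets[cond_real]
        model = decode.fit_decoder(real_set.data, prep.structure,
                                   n_folds=config.cv_folds,
                                   n_repeats=config.cv_repeats,
                                   seed=config.seed)
        phi_hat = decode.predict_phase(model.oof_pred).reshape(-1)
        phi = np.tile(prep.structure.phi,
                      model.oof_pred.shape[0] * model.oof_pred.shape[1])
        real_res = decode.reconstruction_report(phi_hat, phi)
        report["real_mean_abs_error_deg"] = real_res.mean_abs_error_deg
        np.savetxt(out / "real_density.csv", real_res.density, delimiter=",")
        pd.DataFrame(model.mean_weights,
                     columns=["y_cos", "y_nsin"]).to_csv(out / "decoder_weights.csv",
                                                         index=False)
        for cond in conditions:
            if cond.startswith("real"):
                continue
            ts = prep.trial_sets[cond]
            res = decode.decode_imagined(model.mean_weights, ts.data,
                                         prep.structure,
                                         groups=prep.participants,
                                         cap_s=config.dtw_cap_s,
                                         n_folds=config.cv_folds,
                                         n_repeats=config.cv_repeats,
                                         seed=config.seed)
            report[f"{cond}_mean_abs_error_deg"] = res.mean_abs_error_deg
            np.savetxt(out / f"{cond}_density.csv", res.density, delimiter=",")
        _log(log_path, "decode", config.seed, cfg_dict)

    if config.run_stats:
        cond_real = next((c for c in conditions if c.startswith("real")), None)
        turn_times = [t for ts in pipeline.turn_times_from_trials(bundle.trials).values()
                      for t in ts]
        res = stats.peak_latency_test(prep.band_series, prep.fs_neural,
                                      np.array(turn_times),
                                      window_s=config.preturn_window_s,
                                      participants=prep.participants,
                                      n_perm=config.n_perm, seed=config.seed)
        report["peak_latency_s"] = res.observed
        report["peak_latency_p"] = res.p
        pd.DataFrame([dict(statistic="peak_latency_s", observed=res.observed,
                           p=res.p, ci_lo=res.ci[0], ci_hi=res.ci[1],
                           cohens_d=res.cohens_d)]).to_csv(
            out / "stats_tests.csv", index=False)
        _log(log_path, "stats", config.seed, cfg_dict)

    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
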
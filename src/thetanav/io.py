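"""Session bundle persistence.

The native session format is a directory of plain files:

* ``signals.bin`` — float32, little-endian, row-major (channels x samples)
* ``header.json`` — shape, dtype, sampling rate, channel metadata
* ``trials.csv`` — trial, condition, start_s, stop_s, press_s, turn_times
* ``trajectories.csv`` — long table (trial, t, x, y, hip_yaw, head_yaw, ...)
* ``route.csv`` — route vertices and handedness
* ``truth_*.csv`` — ground-truth annotations (synthetic sessions only)
* ``config.json`` — generator configuration

Ground-truth per-sample phase is not stored; it is reconstructed from the
trajectories (real trials) and warp knots (imagined trials) on load.
Times are seconds, sample indices 0-based, intervals half-open [start, stop).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .synth import (RouteTemplate, SessionBundle, SynthConfig, SynthTruth,
                    Trajectory, _phase_from_anchors, _interp_wrapped_phase)

__all__ = ["save_session", "load_session", "validate_trials"]


def validate_trials(trials: pd.DataFrame, duration: float | None = None) -> None:
    required = {"trial", "condition", "start_s", "stop_s"}
    missing = required - set(trials.columns)
    if missing:
        raise ValidationError(f"trials.csv is missing columns: {sorted(missing)}")
    for i, row in enumerate(trials.itertuples()):
        if not row.stop_s > row.start_s:
            raise ValidationError(
                f"trials.csv row {i} (trial {row.trial}): stop_s <= start_s")
        if duration is not None and row.stop_s > duration + 1e-6:
            raise ValidationError(
                f"trials.csv row {i} (trial {row.trial}): stop_s beyond recording end")


def save_session(bundle: SessionBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sig = np.ascontiguousarray(bundle.signals, dtype="<f4")
    sig.tofile(out / "signals.bin")
    header = dict(shape=list(bundle.signals.shape), dtype="<f4", order="C",
                  fs=bundle.fs, channel_labels=bundle.channel_labels,
                  participant_of_channel=bundle.participant_of_channel.tolist(),
                  phase_pref=bundle.phase_pref.tolist(),
                  theta_freq_of_channel=bundle.theta_freq_of_channel.tolist())
    (out / "header.json").write_text(json.dumps(header, indent=1))
    bundle.trials.to_csv(out / "trials.csv", index=False)

    rows = []
    for tid, tr in bundle.trajectories.items():
        df = pd.DataFrame(dict(trial=tid, t=tr.t, x=tr.xy[:, 0], y=tr.xy[:, 1],
                               hip_yaw=tr.hip_yaw, head_yaw=tr.head_yaw,
                               speed=tr.speed, arc_s=tr.arc_s))
        rows.append(df)
    (pd.concat(rows) if rows else pd.DataFrame(
        columns=["trial", "t", "x", "y", "hip_yaw", "head_yaw", "speed", "arc_s"])
     ).to_csv(out / "trajectories.csv", index=False)
    turn_rows = [dict(trial=tid, turn=i, t=tt)
                 for tid, tr in bundle.trajectories.items()
                 for i, tt in enumerate(tr.turn_times)]
    pd.DataFrame(turn_rows, columns=["trial", "turn", "t"]).to_csv(
        out / "trajectory_turns.csv", index=False)

    route_df = pd.DataFrame(bundle.route.vertices, columns=["x", "y"])
    route_df["handedness"] = bundle.route.handedness
    route_df.to_csv(out / "route.csv", index=False)

    cfg = dataclasses.asdict(bundle.config)
    for k, v in cfg.items():
        if isinstance(v, np.ndarray):
            cfg[k] = v.tolist()
    (out / "config.json").write_text(json.dumps(cfg, indent=1))

    if bundle.truth is not None:
        bundle.truth.bout_intervals.to_csv(out / "truth_bouts.csv", index=False)
        bundle.truth.ied_intervals.to_csv(out / "truth_ieds.csv", index=False)
        wr = [dict(trial=tid, knot=i, nominal_s=n, actual_s=a)
              for tid, (nom, act) in bundle.truth.imag_warps.items()
              for i, (n, a) in enumerate(zip(nom, act))]
        pd.DataFrame(wr, columns=["trial", "knot", "nominal_s", "actual_s"]).to_csv(
            out / "truth_imag_warps.csv", index=False)


def load_session(in_dir) -> SessionBundle:
    src = Path(in_dir)
    header = json.loads((src / "header.json").read_text())
    shape = tuple(header["shape"])
    signals = np.fromfile(src / "signals.bin", dtype=header["dtype"]).reshape(shape)
    signals = signals.astype(np.float64)
    fs = float(header["fs"])
    trials = pd.read_csv(src / "trials.csv")
    validate_trials(trials, duration=shape[1] / fs)

    cfg_raw = json.loads((src / "config.json").read_text())
    for k in ("channel_phase_pref", "theta_freq"):
        if cfg_raw.get(k) is not None:
            cfg_raw[k] = np.array(cfg_raw[k])
    if isinstance(cfg_raw.get("seg_length_range"), list):
        cfg_raw["seg_length_range"] = tuple(cfg_raw["seg_length_range"])
    config = SynthConfig(**cfg_raw).resolve()

    route_df = pd.read_csv(src / "route.csv")
    route = RouteTemplate(vertices=route_df[["x", "y"]].values,
                          handedness=route_df.handedness.iloc[0])

    traj_df = pd.read_csv(src / "trajectories.csv")
    turns_df = pd.read_csv(src / "trajectory_turns.csv")
    trajectories = {}
    for tid, g in traj_df.groupby("trial"):
        tt = turns_df[turns_df.trial == tid].sort_values("turn").t.values
        arc = g.arc_s.values
        # recompute phase from arc length and the turn times
        tr = Trajectory(t=g.t.values, xy=g[["x", "y"]].values,
                        hip_yaw=g.hip_yaw.values, head_yaw=g.head_yaw.values,
                        speed=g.speed.values, turn_times=tt, arc_s=arc,
                        phase=np.zeros(len(g)))
        tr.phase = _interp_wrapped_phase(tr.t, tr)
        trajectories[int(tid)] = tr

    truth = None
    if (src / "truth_bouts.csv").exists():
        warps_df = pd.read_csv(src / "truth_imag_warps.csv")
        imag_warps = {}
        for tid, g in warps_df.groupby("trial"):
            g = g.sort_values("knot")
            imag_warps[int(tid)] = (g.nominal_s.values, g.actual_s.values)
        phase = {}
        for row in trials.itertuples():
            tid = int(row.trial)
            n_t = int(round((row.stop_s - row.start_s) * fs))
            tt = np.arange(n_t) / fs
            if tid in trajectories:
                phi = _interp_wrapped_phase(tt, trajectories[tid])
            elif tid in imag_warps:
                phi = _phase_from_anchors(tt, imag_warps[tid][1])
            else:
                phi = np.full(n_t, np.nan)
            phase[tid] = (row.start_s + tt, phi)
        truth = SynthTruth(bout_intervals=pd.read_csv(src / "truth_bouts.csv"),
                           ied_intervals=pd.read_csv(src / "truth_ieds.csv"),
                           imag_warps=imag_warps, phase=phase)

    return SessionBundle(signals=signals, fs=fs,
                         channel_labels=header["channel_labels"],
                         participant_of_channel=np.array(header["participant_of_channel"]),
                         phase_pref=np.array(header["phase_pref"]),
                         theta_freq_of_channel=np.array(header["theta_freq_of_channel"]),
                         trials=trials, trajectories=trajectories, truth=truth,
                         config=config, route=route)
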
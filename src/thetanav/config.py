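"""Pipeline configuration.

Numeric defaults of the analysis chain, each traceable to the methods of
the study design this package implements or to a documented design choice:
250 Hz neural sampling, Morse wavelets (gamma = 3, P^2 = 60) on ten voices
per octave in 1-90 Hz, IED rejection at 5x the envelope medians with 256 ms
extension and the 50% trial-exclusion rule, bouts of >= 2 cycles above the
0.95 background quantile, 1000 consistency splits, 10 x 10 cross-validation,
a +/- 2 s DTW cap, 10,000 circular shifts, and 0.05 primary/cluster
thresholds.  Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    fs_neural: float = 250.0
    freq_lo: float = 1.0
    freq_hi: float = 90.0
    voices_per_octave: int = 10
    morse_gamma: float = 3.0
    morse_p2: float = 60.0
    theta_search_lo: float = 3.0
    theta_search_hi: float = 12.0
    ied_median_factor: float = 5.0
    ied_extend_s: float = 0.256
    ied_trial_exclude_fraction: float = 0.5
    bout_min_cycles: float = 2.0
    bout_threshold_quantile: float = 0.95
    n_splits: int = 1000
    cv_folds: int = 10
    cv_repeats: int = 10
    dtw_cap_s: float = 2.0
    n_shifts: int = 10000
    n_perm: int = 1000
    p_primary: float = 0.05
    p_cluster: float = 0.05
    fs_common: float = 50.0
    preturn_window_s: float = 2.0
    seed: int = 0
    run_bouts: bool = True
    run_consistency: bool = True
    run_decode: bool = True
    run_stats: bool = True

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
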
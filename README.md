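# thetanav

Analysis pipeline for **intermittent medial-temporal-lobe (MTL) theta
dynamics during real-world and imagined spatial navigation**, built around
ambulatory intracranial EEG (250 Hz field potentials from chronically
implanted electrodes) synchronized with motion capture (120 Hz).  It is
aimed at researchers who want to test whether transient theta bouts are
organized by progress along a route — and whether relative position can be
decoded back from the multichannel theta envelope — on their own
recordings or on fully synthetic sessions.

## What it computes

A walked route of `k + 1` linear segments joined by `k` turns is abstracted
into a circular variable: relative position within a segment is a phase
φ ∈ [0, 2π) (0 at segment entry, 2π at the turn), encoded by the orthogonal
responses cos φ (peaks at turns) and −sin φ (peaks just before turns).  A
cross-validated linear model maps the z-scored theta amplitudes *x(t)* of
all channels to these responses,

    ŷ = W᷆ᵀ [1, x(t)],      φ̂(t) = atan2(−ŷ_nsin, ŷ_cos) mod 2π,

and reconstruction quality is read from the circular errors
ε = wrap(φ̂ − φ) against circular-shift permutation nulls.  Around that
core the package provides:

- Morse-wavelet time–frequency amplitudes (γ = 3, P² = 60, ten
  voices/octave in 1–90 Hz) with per-channel z-scoring and individualized
  theta-band selection from spectral peaks and flanking minima;
- interictal-discharge (IED) rejection at 5× the envelope medians with
  256 ms guards and a 50% trial-exclusion rule;
- BOSC-style oscillatory-bout detection (≥ 2 cycles above the 95%
  background-power quantile) with prevalence, duration, amplitude, and
  turn-locked timing summaries;
- trial alignment: trajectory DTW for turn anchors, piecewise-linear
  warping, segment-length normalization, and ±2 s capped DTW for aligning
  imagined-position estimates to the task structure;
- split-half temporal consistency (1000 random splits) with multilevel
  block permutation tests, cluster bootstrap CIs, and Cohen's d;
- cluster-based sign-flip permutation tests, turn-locked peak-latency
  tests, and behavior–theta lag/regression analyses;
- a synthetic-session generator (`thetanav.synth`) that emulates the whole
  data structure — routes, trajectories with pre-turn slow-downs,
  position-locked theta bouts with channel-specific phase preferences, 1/f
  background, delta/beta components, warped imagined trials, injected
  IEDs — with full ground truth, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from thetanav import pipeline, decode
from thetanav.synth import SynthConfig, simulate_session

bundle = simulate_session(SynthConfig(rng_seed=3, n_imag=0, n_control=0))
prep = pipeline.prepare_session(bundle)          # IEDs, bands, warping
real = next(ts for c, ts in prep.trial_sets.items() if c.startswith("real"))

model = decode.fit_decoder(real.data, prep.structure, seed=0)  # 10x10 CV
phi_hat = decode.predict_phase(model.oof_pred).reshape(-1)
phi = np.tile(prep.structure.phi, 10 * real.n_trials)
report = decode.reconstruction_report(phi_hat, phi)
print(f"bands: { {p: round(b.f_peak, 1) for p, b in prep.bands.items()} }")
print(f"mean |circular error|: {report.mean_abs_error_deg:.1f} deg")
print(f"diagonal density (1 = chance): {report.diagonal_mass:.2f}")
```

Output for this seed:

```
bands: {0: 7.0, 1: 6.1, 2: 6.5, 3: 7.5, 4: 7.0}
mean |circular error|: 35.1 deg
diagonal density (1 = chance): 3.89
```

The five estimated theta peaks land within half an octave of each
synthetic participant's true theta frequency (5.6–6.4 Hz for this seed); a
held-out mean absolute circular error of ~35° (chance is 90°) and a
diagonal density almost four times chance mean the decoder recovers
relative route position from the theta envelopes alone.

A command-line interface wraps the same machinery:

```bash
thetanav simulate --out session/ --seed 1
thetanav run --session session/ --out results/ --plot
```

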
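# Methods

This note documents the models, estimators, and numerical choices behind
`thetanav`, and what the synthetic validation studies do and do not show.

## Scientific setting

Chronically implanted medial-temporal-lobe (MTL) electrodes make it
possible to record field potentials while people physically walk spatial
routes and, on a treadmill, mentally re-walk them.  Human MTL theta
(~3–12 Hz) is intermittent: it appears as short oscillatory bouts rather
than the continuous rhythm familiar from rodents.  The analyses here ask
whether those theta dynamics are organized by *progress through a route* —
a route of `n_turns + 1` linear segments, with each turn acting as a
retrieval landmark — during real walking and during imagination, and
whether relative position can be read back out of the multichannel theta
envelope.

## Relative position as a circular variable

Progress through one segment is mapped to a phase φ ∈ [0, 2π): φ = 0 at
segment entry and φ = 2π at the turn that ends it.  Because every segment
repeats the same pattern, the route abstracts into a sinusoidal task
structure with two orthogonal responses

    y_cos(t) = cos φ(t)      (peaks at each turn)
    y_nsin(t) = −sin φ(t)    (peaks at 3/4 of each segment, i.e. before turns)

Any channel whose theta envelope is modulated as `a + b·cos(φ − ψ_c)` with
site-specific preferred phase ψ_c contributes to both components; with
several channels spanning preferred phases, φ is identifiable as the angle
of the predicted resultant, φ̂ = atan2(−ŷ_nsin, ŷ_cos).

## Pipeline stages

**Time–frequency.** Continuous wavelet transform with analytic generalized
Morse wavelets, symmetry γ = 3 and time–bandwidth P² = βγ = 60 (β = 20), on
ten voices per octave in 1–90 Hz; amplitudes are the transform modulus.
The frequency-domain filter is normalized to peak value 2 so a unit
sinusoid at a bin centre has amplitude 1.  Amplitudes are z-scored per
channel × frequency over artifact-free samples; the first/last 2 s are
treated as cone-of-influence and excluded from the statistics (but still
transformed).  For long sessions the band-amplitude series is produced by
reconstructing each bin's analytic signal from its compactly supported
spectrum at a reduced rate (default 4 × the 50 Hz common rate); this is
exact whenever the output rate exceeds the wavelet's spectral support
(~1.8 × the bin frequency) and envelope statistics are rate-invariant.

**Individual theta band.** Per participant, the mean amplitude spectrum
over artifact-free real-walk samples is searched in 3–12 Hz for its largest
strict local maximum (±1 bin; ties toward lower frequency); the band edges
are the neighbouring spectral minima (grid edge if the spectrum is monotone
beyond the peak).

**Artifact rejection.** Interictal epileptiform discharges are flagged
where the broadband (1–90 Hz) envelope or the 15–80 Hz band-passed
envelope (zero-phase FIR, 2 Hz transitions; envelope = analytic-signal
modulus) exceeds five times its session median, per channel; flagged runs
are extended by 256 ms on both sides, and trials flagged over 50% of their
duration are excluded.  Thresholding is per channel; trial exclusion pools
channels (conservative).

**Bout detection.** The background at each channel is a robust (Huber)
log-log regression of mean wavelet power on frequency; since constant-Q
wavelets measure power ∝ PSD(f)·f, the reported slope is the PSD-equivalent
exponent (raw slope − 1).  Power at one frequency under Gaussian background
is exponential (χ²(2)-scaled), so the detection threshold is the 0.95
quantile of that law around the fitted mean.  Bouts are supra-threshold
runs of at least two cycles (≥ 2/f); artifact samples break runs.
Prevalence follows the Pepisode convention — per frequency bin, averaged
over band bins — because a union across the oversampled 10-voice grid
would structurally inflate the ~5% chance floor.  Band-level union
intervals are still used for trial-level timing (bout-rate timecourse,
pre-turn prevalence).

**Trial alignment.** Real trials are aligned by DTW on 2D positions
(symmetric unit steps, Euclidean distance, resampled to 40 Hz) to the
medoid trial; route turn vertices located on the medoid map through each
warp path to per-trial turn anchors.  Behavioral variables and band
amplitudes are then piecewise-linearly warped to the condition-mean anchor
timing and every inter-anchor span resampled to a common length
(segment-length normalization), giving one timeline of
`n_segments × samples_per_segment` points at 50 Hz.  Imagined and control
trials, which lack motion anchors, are linearly warped to their
condition-mean duration and sampled at the same relative positions.

**Temporal consistency.** Per channel and condition, trials are randomly
split into halves (odd counts: the larger half takes the extra trial), the
two half-mean time courses are Pearson-correlated, and the mean over 1000
splits is the consistency.  Conditions are compared with a multilevel
block permutation test: the statistic is the difference of channel-mean
consistencies and the null re-assigns condition labels only within each
participant's block of observations.  Within-block *label permutation* is
used (rather than participant-level flips) because five participants admit
only 2⁵ sign-flip permutations — too coarse for p ≤ 0.01 decisions.
Effect sizes are the raw mean difference and paired Cohen's d
((A − B)/SD of differences); confidence intervals come from a cluster
bootstrap over participants.  Spatial correlation of consistency between
conditions is tested by permuting channel pairings within participant
blocks (blocks under 3 channels merge into a common pool).

**Decoder.** Ordinary least squares from the pooled, z-scored theta
amplitudes of all channels (plus intercept) to (y_cos, y_nsin), under
10-fold cross-validation repeated 10 times with whole trials assigned to
folds; weights come from training trials only and predictions are emitted
only for held-out trials.  Rank-deficient designs fall back to ridge with
λ = 10⁻⁶ × tr(XᵀX)/p.  Reconstruction is summarized by circular errors
ε = wrap(φ̂ − φ) ∈ (−π, π], a 2D density over actual × estimated phase
bins normalized so a uniform estimate equals 1.0, and a permutation null
that circularly shifts φ̂ against φ (10,000 shifts by default), preserving
autocorrelation.

**Imagined decoding.** The model fit on all real trials provides initial
imagined-position estimates.  A Sakoe–Chiba-banded DTW on squared circular
phase distance, band = ±2 s, aligns the training-trial-average estimate to
the task structure; the learned path is applied unchanged to held-out
trials (10 × 10 CV over imagination trials).  One path per participant is
learned from that participant's *partial response vectors* — the
contribution of their channels' rows of the pooled weight matrix, with the
intercept shared pro rata — so relative timing between a participant's
channels is preserved.  Paths pinned to the band edge over half the
timeline flag alignment divergence.

**Group statistics.** Turn-aligned averaging (time 0 = turn), cluster-based
sign-flip permutation tests (flip a random half of the channels, 1000
permutations; pointwise primary threshold p = 0.05 from the null
percentiles; clusters scored by size against the max-cluster null,
4-connectivity in 2D; `p_cluster = 1` reduces to the pointwise test),
per-channel peak-latency tests (latency of the turn-locked maximum, ties
toward earlier; group null flips channel latencies' signs),
joint single-trial regressions of band amplitude on behavioral variables
with channel-level sign-flip inference and max-statistic correction
across variables, and route RMSE (perpendicular distance to the ideal
polyline).

## Synthetic sessions

The generator emulates the study's data structure so every stage is
testable without any recording: five participants, 18 channels dealt to
them (4/4/4/3/3), one route of four turns (configurable; a five-turn
variant mirrors a participant who habitually added a turn), 24 trials per
condition, field potentials at 250 Hz, motion capture at 120 Hz.

Per channel the signal is: Gaussian 1/f^1.5 background (spectral shaping,
unit SD); a continuous theta carrier at the participant's theta frequency
(drawn in 4.5–8.5 Hz) with envelope `0.5·s·σ_band·(1 + d_c·cos(φ − ψ_c))`
where s is `continuous_mod_snr` (defaults to `bout_amp_snr` = 2), σ_band
the background's theta-band SD and d_c the per-channel modulation depth
(default 1; `graded_mod_depth` emulates site-specific structure); discrete
Hann-windowed theta bouts (mean 0.5 s, occupying ~20% of trial time) whose
centre phases concentrate von Mises-style around ψ_c and whose amplitude
is expressed in wavelet-response units (peak wavelet amplitude = SNR ×
background RMS wavelet amplitude at the theta bin — compensating the
P² = 60 wavelet's attenuation of short bouts, which would otherwise make
SNR values incomparable across durations); position-neutral delta (2 Hz)
and beta (20 Hz) components with slow random amplitude modulation, which
produce the spectral minima that bound the individual theta band; and
biphasic IEDs (70 ms spike + 300 ms slow wave, both 8 × background SD,
Poisson 1/min/channel).

Default phase preferences form a uniform grid interleaved across
participants (coprime stride), so each participant's channels span the
circle — without this, per-participant partial phase estimates are
degenerate.

Imagined trials follow the same φ but under a monotone piecewise-linear
time warp with knots at the turns: a *shared* condition-level shift per
knot (SD 0.75 s, truncated ±1.5 s) plus per-trial jitter (SD 0.25 s,
truncated ±0.5 s), keeping the total within the ±2 s alignment cap.  The
shared component models participant-level imagination-timing bias — the
part a cross-validated alignment can legitimately learn; the jitter is
irreducible.  Control trials carry matched mean theta power, uniformly
timed bouts, and no φ-locked structure.

What the generator does **not** emulate: volume conduction and channel
cross-correlation, nonstationary background spectra, behavioral
variability beyond speed dips and lateral jitter, theta frequency drift,
asymmetric bout shapes, and real IED morphology diversity.  Passing tests
therefore demonstrate the correctness and calibration of the estimators
under the stated generative assumptions, not performance on real
recordings.

## Validation studies and problem sizes

The `benchmarks` module (reported by `scripts/acceptance.py`, asserted by
`tests/test_acceptance.py`) uses these sizes, chosen to keep each study in
the minutes range on one CPU:

- **Decoder recovery**: one default session (24 real trials, 18 channels,
  SNR 2, segments 3–5 m), 10 × 10 CV, against time-shuffled task labels.
- **Imagined generalization**: 50 replicate sessions of 12 trials per
  condition with 2.2–3.0 m segments; alignment CV 10 folds × 2 repeats;
  control shift null with 200 shifts per replicate.
- **Consistency calibration**: 400 null draws with participant random
  effects (250 permutations each); power over 25 replicate sessions
  (10 imagination + 10 control trials, 300 splits, 500 permutations).
- **Bout detector**: 5 seeds of two-channel, bouts-only sessions at SNR 3
  with a paired bout-free session per seed; bouts are injected at the
  canonical 8 Hz theta peak (a 0.5 s bout = four cycles); prevalence
  recovery is background-corrected by the paired floor, duration recovery
  uses the median episode length at the peak bin.  At the low end of the
  theta range the transform's temporal resolution (σ_t ≈ 1.23/f, ~0.26 s
  at 4.7 Hz) approaches the bout length and blurs detected widths — an
  instrument limit documented under limitations, not a detector defect.
- **IED detector**: 20 seeds of four-channel sessions at 2 events/min;
  injected fractions are guard-extended (±256 ms) before comparison.
- **Warp**: anchor recovery on 12 trajectories; capped-DTW shift recovery
  at 0.5/1.0/1.5 s and saturation at 2.4 s (the probe avoids shifts equal
  to a multiple of the segment period, which alias under a periodic task
  structure).

## Numerical choices and degenerate inputs

- Ties in spectral extrema break toward lower frequency; ties in peak
  latency toward the earlier lag.
- Zero-variance channels raise degenerate-input errors in z-scoring;
  constant split-half means skip the split with a warning; constant
  behavioral variables are dropped with a warning.
- All permutation engines take explicit seeds; identical seeds give
  identical p-values.  Session synthesis is bit-reproducible from its
  config.
- Permutation p-values are (1 + #{null ≥ obs})/(n_perm + 1), never zero.
- Times are seconds, sample indices 0-based, intervals half-open
  [start, stop).

## Known limitations

- The P² = 60 wavelet trades temporal for spectral resolution: below
  ~6 Hz its temporal spread is a substantial fraction of a 0.5 s bout, so
  detected episode widths (and hence occupancy) are blurred upward there.
  Bout-duration estimates near the low theta edge should be read as upper
  bounds.
- The trajectory DTW locates template turns from the route geometry
  (nearest approach of the medoid to each turn vertex); with extreme
  lateral jitter the template turn index can shift by a few motion
  samples.
- The per-participant alignment assumes each participant's channels span
  enough preferred phases for a partial resultant; a participant whose
  channels cluster at one phase would get a noisy path (the divergence
  flag reports this).
- Cross-correlogram inference uses the circular (periodic) convention,
  appropriate for the repeating task structure but not for aperiodic
  references.
- The mixed-effects models used descriptively in the original analyses
  are replaced throughout by block-aware permutation inference with the
  same exchangeability structure; parametric effect sizes (β) are not
  reproduced.
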
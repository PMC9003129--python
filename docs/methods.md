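# Methods

## The problem

A single abdominal ECG (aECG) channel records the superposition of a
large-amplitude maternal ECG (mECG), a smaller and faster fetal ECG (fECG),
baseline wander, powerline interference, broadband noise, and — outside the
clinic — motion artifacts. Extracting the fetal R-peak train from that one
channel is what this package does. Fetal heart rate and rhythm follow
directly from the recovered fQRS times.

## The dynamic ECG model

Each heart is modelled as motion around a phase limit cycle. The state is
`x_k = [theta_k, z_k]`: `theta` is the cardiac phase in [0, 2π) and `z` the
ECG amplitude. Five Gaussian bumps in phase — one per P, Q, R, S, T wave,
each with amplitude `alpha_i` (signal units), width `b_i` (rad) and centre
`theta_i` (rad) — define the noise-free waveform

    G(theta) = Σ_i alpha_i exp(−(theta − theta_i)² / (2 b_i²)).

The discrete dynamics advance the phase by `omega·delta` per sample
(`omega` = angular velocity, `delta` = sampling period) and move `z` along
the derivative of `G`, plus additive state noise `eta_k` (variance
`eta_var`) on `z` only. Angle differences `theta − theta_i` are wrapped into
[−π, π) so each wave acts locally around its own centre. The observation is
`[phi_k, s_k]`: the phase obtained by linearly wrapping each R-R interval
onto [0, 2π), and the measured amplitude, each with additive noise.

The first-order discretization makes the generated trace deviate from
`G(theta)` by O(delta); at `delta = 1e-4 s` the worst deviation is below
0.33 % of the R amplitude (checked against the closed form in the tests).

### Default wave parameters

The canonical parameter set (alpha = 1.2, −5, 30, −7.5, 0.75; b = 0.25,
0.1, 0.1, 0.1, 0.4 rad; theta = −π/3, −π/12, 0, π/12, π/2 for P…T) is used
for initialization and for the simulator, rescaled so the maternal R peak
has unit amplitude. Fetal morphology uses the same family with all widths
halved and amplitudes scaled by the fetal-to-maternal ratio (sign flips for
reversed electrode polarity). These are modelling choices — real fetal wave
parameters vary — and all are configurable.

## Filters

Three filters operate on the same state-space abstraction:

- **KF** — exact, linear-Gaussian models only; used as the oracle in tests.
- **EKF** — Jacobian linearization of the transition map (the Jacobian of
  the Gaussian-derivative sum is analytic); the comparison baseline.
- **EnKF** — the stochastic (perturbed-observation) ensemble filter.
  Members are propagated through the full nonlinear dynamics with
  independent state-noise draws; the gain is built from the ensemble's 1/N
  sample covariances; each member is updated toward the observation plus an
  independent zero-mean perturbation with the measurement-noise covariance
  `Qw`.

Two numerical points matter in the EnKF:

1. **`Qw` belongs in the gain denominator.** The observation-error
   covariance is that of the *noisy* measurement, so the gain is
   `Pxy (Pyy_sample + Qw + eps·I)^-1` with `eps = 1e-8·trace/Dy` guarding
   near-singular small-ensemble covariances. Omitting `Qw` makes the gain
   collapse to the identity and the filter simply copies the observation.
2. **Centred, variance-matched noise draws.** Per step, the state-noise and
   perturbation draws are recentred to an exactly zero sample mean and
   rescaled to the exact sample variance. This standard variance-reduction
   device removes the O(1/√N) sampling error that a nonzero draw mean
   injects directly into the ensemble-mean estimate; with it, the N = 70
   pipeline tracks the EKF on model-matched data, and ensemble sizes down
   to 5 remain usable.

The cardiac phase is an angle: ensemble means and innovations for the phase
component are computed with wrapped differences so a tight ensemble
straddling 0/2π is never averaged to π.

Process noise is `diag(1e-6, eta_var)`: the model's phase equation is
noise-free, and the tiny phase jitter exists only to keep covariances well
conditioned.

## The two-pass extraction pipeline

1. **Preprocess** (all stages zero-phase, forward-backward): baseline
   estimate by 4th-order Butterworth lowpass at 1 Hz, subtracted; IIR notch
   at 50 Hz (Q = 30). A stationary-wavelet denoiser (coif5, 10 levels
   capped by record length, universal soft threshold on the 4 finest detail
   levels) is available but **off by default**: aggressive wavelet
   thresholding can remove the low-amplitude fetal complexes along with the
   noise, and thresholding coarse levels distorts the ECG waves themselves.
2. **Maternal pass**: Pan-Tompkins (5–15 Hz band, 250 ms refractory,
   150 ms integration window) finds maternal R peaks; each R-R interval is
   wrapped onto [0, 2π); the record's own maternal morphology is fitted as
   a Gaussian sum to the phase-averaged beat (median over 250 phase bins —
   the median resists fetal contamination of individual cycles); the
   chosen filter tracks `[phi, s]` with a per-sample `omega = 2π/RR`. The
   filtered `z` trace is the mECG estimate.
3. **Subtract**: `residual = preprocessed − mecg_hat`, exactly.
4. **Fetal pass**: the same machinery on the residual with fetal settings
   (10–70 Hz band, 200 ms refractory, 80 ms integration window, half-width
   initialization). The residual is treated as fECG plus Gaussian noise.
   If no usable fetal rhythm or morphology fit is found the residual passes
   through unchanged (flagged in diagnostics).
5. **fQRS detection** on the denoised fetal waveform.

### Record-driven noise variances

- amplitude measurement noise = variance of the signal inside the
  isoelectric phase window (from `theta_T + 0.6` to `theta_P − 0.3` rad),
  i.e. the part of the cycle where the tracked heart is electrically
  silent and whatever remains is, for this pass, noise;
- state noise `eta_var` = 10 × the Gaussian-sum fit residual variance —
  morphology the fit cannot explain must be absorbed by the state noise;
- phase measurement noise: 0.01 rad² (detected R-peak jitter of a few
  milliseconds maps to phase errors of this order).

All three are overridable in `PipelineConfig`.

### Detector choices

The Pan-Tompkins thresholds are initialized from robust whole-record
statistics (90th percentile / median of the integrated waveform) rather
than the first two seconds — this is an offline detector, and a single
start-up transient must not pin the running signal-level estimate. Peak
updates are clipped at 4× the running level for the same reason. Peaks are
refined to the extremum of the bandpassed signal within ±40 ms, after a
majority vote fixes one dominant polarity — mixing crest and trough anchors
across beats would smear the phase-averaged morphology. Squaring makes
detection polarity-insensitive, so reversed fetal complexes cost nothing.

The fetal band default (10–70 Hz) is wider than a clinical fetal band
because the simulator's half-width fetal complexes are ~14 ms long with
spectral energy near 50 Hz; on real recordings with ~40 ms fetal QRS a
10–30 Hz band is reasonable, and the band is a config field.

### Morphology fitting

The 15-parameter Gaussian-sum fit is label-degenerate: two waves can trade
places while fitting the waveform equally well. Wave centres are therefore
parameterized as offsets from the initialization, bounded to 45 % of the
gap to the neighbouring wave. The fitted centres must preserve the
P,Q,R,S,T cyclic order (any rotation of the circle is accepted — the phase
origin is wherever the detector anchored); violations raise an error, which
the fetal pass converts into a pass-through.

## Synthetic data

`make_mixture` sums two generated beat trains (maternal unit R amplitude at
80 bpm; fetal at 140 bpm, amplitude ratio 0.25, half-width waves), white
Gaussian noise at 12 dB SNR **relative to the fetal component** (the harder
signal — referencing noise to the fetus keeps the difficulty axes
orthogonal), a 0.3-amplitude 0.25 Hz baseline term and a 0.05-amplitude
50 Hz powerline term, with per-beat R-R jitter of 0.02 s on both hearts.
Records are 500 Hz by default; at coarser rates the ~14 ms fetal complexes
span too few samples for stable template alignment. Both trains start at
seed-drawn offsets inside their first R-R interval. Components are stored
alongside the mixture and sum to it bit-exactly; fetal R-peak ground truth
comes from the generator's phase crossings.

`make_overlap_stressor` adjusts the fetal R-R series so a requested
fraction of fetal peaks lands within 30 ms of a maternal peak (snapping
beats onto maternal peaks, or pushing colliding beats away, under a
minimum-RR constraint); the achieved fraction is verified within ±0.05.

What the simulator does **not** emulate: electrode-geometry projection,
morphology change over time, ectopy, uterine EMG, real motion artifacts.
Passing tests show the method's internal consistency and its behaviour
under the stated mixture model — not clinical performance.

`synthetic_motion_template` stands in for activity-recording-derived
artifact templates with three morphologies: slow large lobes, enveloped
band-limited bursts, and decaying step changes ("electrode pops"), scaled
to unit peak. `extract_motion_noise` builds templates from any real ECG
CSV by the normalize → model-filter → subtract route.

## Scoring

Detected fetal peaks are matched one-to-one to reference annotations within
±50 ms (configurable), using earliest-available greedy matching in time
order — the maximum-cardinality matching for points on a line, symmetric
under swapping the two trains. SE = TP/(TP+FN), PPV = TP/(TP+FP),
F1 = 2TP/(2TP+FN+FP), in percent. Degenerate denominators (maternal-only
records) report NaN with a flag instead of raising.

## Problem sizes

The shipped checks use: 60 s single-record extraction at the reference
difficulty; 20 overlap-stressed 30 s records for the EnKF-vs-EKF
comparison; 4 records × 3 motion gains; ensemble sizes {5, 35, 70, 150,
350} on one fixed record. Ensemble size defaults to 70 throughout.

## Known limitations

- The maternal filter partially absorbs fetal spikes when `eta_var` is
  large (adaptive morphology vs. fetal preservation is a real trade-off);
  the default 10× fit-residual rule favours adaptivity.
- On data generated by the model family itself the EKF is near-optimal, so
  the EnKF's advantage appears as parity, not superiority; its robustness
  margin is expected on signals that violate the linearization (real
  recordings, heavy artifacts).
- The second pass assumes the residual is fetal ECG plus Gaussian noise;
  structured maternal residue violates this and shows up as extra false
  positives at small ensemble sizes.
- No real-recording I/O beyond single-channel CSV; no multi-channel fusion;
  no streaming operation.
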
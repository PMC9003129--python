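# fekf — single-channel fetal ECG extraction with the ensemble Kalman filter

Non-invasive fetal heart monitoring records the fetal ECG through electrodes
on the mother's abdomen. A single abdominal channel — all a compact wearable
patch provides — superimposes the large maternal ECG, the small and faster
fetal ECG (sometimes with reversed polarity), baseline wander, powerline
interference, broadband noise, and motion artifacts. `fekf` recovers the
fetal QRS train from that one channel, for signal-processing researchers and
engineers building fetal-monitoring pipelines.

## Method

The heart's cycle is modelled on a phase limit cycle with state
x_k = [θ_k, z_k] (cardiac phase, ECG amplitude). Five Gaussian waves in
phase (P, Q, R, S, T) shape the waveform:

    θ_k = (θ_{k−1} + ωΔ) mod 2π
    z_k = z_{k−1} − Σ_i (α_i ωΔ / b_i²) Δθ_i exp(−Δθ_i²/(2b_i²)) + η_k

with Δθ_i = θ_k − θ_i wrapped into [−π, π). The observation is [φ_k, s_k]:
the phase from linearly wrapping each R-R interval onto [0, 2π), and the
measured amplitude.

Extraction is two filter passes. First, maternal R peaks (Pan-Tompkins)
define the maternal phase; the record's own maternal morphology is fitted as
a Gaussian sum to the phase-averaged beat; an ensemble Kalman filter (EnKF,
default N = 70 members; an EKF baseline is one flag away) tracks the
maternal amplitude, and the tracked waveform is subtracted. Second, the same
machinery denoises the fetal residual. Fetal QRS complexes are detected on
the result and scored against reference annotations with
SE = TP/(TP+FN), PPV = TP/(TP+FP), F1 = 2TP/(2TP+FN+FP) at a ±50 ms
matching window.

A synthetic mixture simulator with exact fetal ground truth, a motion
artifact generator/injector, and CSV record I/O make the whole chain
testable without clinical recordings. See `docs/methods.md` for the model,
parameter defaults, and limitations.

## Worked example

```python
import fekf

# a 60 s abdominal mixture: maternal 80 bpm, fetal 140 bpm at a quarter of
# the maternal R amplitude, 12 dB noise, baseline + powerline interference
rec = fekf.make_mixture(fekf.MixtureSpec(duration=60.0, seed=11))

model = fekf.SingleChannelFetalECG(rec.aecg)
res = model.fit(method="enkf", seed=1)
print(res.summary())
m = res.score(rec.fetal_peaks)
print(f"SE={m.se:.2f}%  PPV={m.ppv:.2f}%  F1={m.f1:.2f}%")
```

prints

```
Single-channel fetal ECG extraction
========================================
method                       ENKF
ensemble size                70
record length (s)            60.0
sampling rate (Hz)           500
maternal beats               80
maternal fit residual (RMS)  0.007962
fetal denoising              applied
fetal QRS detected           139
fetal heart rate (bpm)       140.2 (median)
SE=100.00%  PPV=100.00%  F1=100.00%
```

The summary reports what the pipeline actually did: 80 maternal beats were
detected and their morphology fitted (residual RMS in units of the maternal
R amplitude), the fetal denoising pass ran, and 139 fetal QRS complexes were
found at a median rate of 140 bpm. Scored against the simulator's ground
truth, every fetal beat is recovered despite the 4× larger maternal ECG on
top of it.

The same flow from a shell:

```bash
fekf simulate --seed 11 --duration 60 --out rec/
fekf extract --input rec/aecg.csv --method enkf --seed 1 --out out/
fekf evaluate rec/aecg.csv --method both
```

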
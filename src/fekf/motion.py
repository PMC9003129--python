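"""Motion-artifact templates and their injection into clean records.

A motion-noise template is built from an ECG recorded during activity:
normalize the recording to [-1, 1], track its ECG content with the
model-based EKF, and keep the difference — whatever the dynamic ECG model
cannot explain is, by construction, artifact.  Templates (from real CSV
recordings or the bundled synthetic motion generator) are then tiled with a
random circular shift and added, with a gain, to a normalized abdominal
record.  Ground-truth fetal annotations pass through untouched: corruption
changes detectability, never the truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .extraction import ExtractionError, PipelineConfig, _model_filter_pass
from .preprocess import normalize_unit
from .signals import AnnotatedSignal

__all__ = [
    "NoiseTemplate",
    "extract_motion_noise",
    "add_motion_noise",
    "synthetic_motion_template",
]


@dataclass(frozen=True)
class NoiseTemplate:
    """A motion-noise waveform in normalized units, with provenance."""

    samples: np.ndarray
    fs: float
    provenance: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if np.max(np.abs(samples), initial=0.0) > 2.0 + 1e-9:
            raise ValueError("template amplitude out of the [-2, 2] range")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# fs={self.fs}\n# provenance={self.provenance}\n")
            pd.DataFrame({"amplitude": self.samples}).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "NoiseTemplate":
        fs = None
        provenance = ""
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if "fs=" in line:
                    fs = float(line.split("fs=")[1].strip())
                elif "provenance=" in line:
                    provenance = line.split("provenance=")[1].strip()
        if fs is None:
            raise ValueError(f"{path}: missing '# fs=' header")
        df = pd.read_csv(path, comment="#")
        return cls(df["amplitude"].to_numpy(dtype=float), fs=fs, provenance=provenance)


def extract_motion_noise(
    recorded_ecg: AnnotatedSignal,
    cfg: PipelineConfig | None = None,
    provenance: str = "recorded activity",
) -> NoiseTemplate:
    """Build a motion-noise template from an ECG recorded during activity.

    Steps: normalize to [-1, 1]; EKF-filter the ECG content with the dynamic
    ECG model (peaks -> phase -> fitted morphology -> filter); the template
    is the normalized input minus the filtered ECG.  The filter itself runs
    on the preprocessed (baseline/notch-cleaned) copy of the normalized
    signal so it tracks the cardiac waveform and not the artifact — the
    subtraction then leaves both the slow and the broadband artifact
    content in the template.
    """
    cfg = cfg or PipelineConfig()
    from .preprocess import preprocess  # local import avoids a cycle

    normalized, _ = normalize_unit(recorded_ecg)
    cleaned = preprocess(normalized, cfg.preprocess)
    try:
        z_hat, _, _, _ = _model_filter_pass(
            cleaned,
            cfg.maternal_band,
            cfg.maternal_refractory,
            cfg,
            method="ekf",
            seed=cfg.seed,
        )
    except Exception as exc:
        raise ExtractionError(f"extract_motion_noise: rhythm undetectable ({exc})") from exc
    template = normalized.samples - z_hat
    template = template - template.mean()  # drop the normalization offset
    return NoiseTemplate(samples=template, fs=recorded_ecg.fs, provenance=provenance)


def add_motion_noise(
    aecg: AnnotatedSignal,
    template: NoiseTemplate,
    gain: float = 1.0,
    seed: int | None = None,
    resample: bool = False,
) -> AnnotatedSignal:
    """Corrupt a record with motion noise.

    The record is normalized to [-1, 1] (so record and template share the
    amplitude convention); the template is tiled to the record length with a
    seed-drawn circular offset and added with the given ``gain``.  Peak
    annotations are carried through unchanged.
    """
    if template.fs != aecg.fs:
        if not resample:
            raise ValueError(
                f"template fs {template.fs} != record fs {aecg.fs}; pass resample=True"
            )
        up, down = int(round(aecg.fs)), int(round(template.fs))
        tpl = sps.resample_poly(template.samples, up, down)
    else:
        tpl = template.samples
    normalized, _ = normalize_unit(aecg)
    n = normalized.n_samples
    rng = np.random.default_rng(seed)
    shift = int(rng.integers(tpl.size)) if tpl.size else 0
    tiled = np.resize(np.roll(tpl, shift), n)
    return normalized.with_samples(normalized.samples + gain * tiled)


def synthetic_motion_template(
    duration: float = 60.0,
    fs: float = 250.0,
    seed: int | None = None,
    provenance: str = "synthetic motion library",
) -> NoiseTemplate:
    """Synthetic stand-in for an activity-recording-derived template.

    Mixes the three artifact morphologies seen in ambulatory ECG: slow
    large-amplitude lobes (body sway/respiration coupling), band-limited
    noise bursts (muscle/electrode friction transients), and smoothed step
    changes (electrode pops).  Output is scaled to unit peak amplitude.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)

    # slow lobes: a few windowed low-frequency sinusoid bursts
    for _ in range(max(3, int(duration / 12))):
        f0 = rng.uniform(0.3, 1.2)
        center = rng.uniform(0, duration)
        width = rng.uniform(2.0, 6.0)
        env = np.exp(-((t - center) ** 2) / (2 * (width / 2) ** 2))
        x += rng.uniform(0.3, 0.8) * env * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))

    # friction bursts: enveloped band-limited noise
    sos = sps.butter(2, [5 / (fs / 2), min(25.0, 0.45 * fs) / (fs / 2)], "band", output="sos")
    for _ in range(max(2, int(duration / 20))):
        center = rng.uniform(0, duration)
        width = rng.uniform(0.3, 1.5)
        env = np.exp(-((t - center) ** 2) / (2 * (width / 2) ** 2))
        x += 0.5 * env * sps.sosfiltfilt(sos, rng.standard_normal(n))

    # electrode pops: rare smoothed steps that decay back to baseline
    for _ in range(max(1, int(duration / 30))):
        start = rng.uniform(0, duration * 0.9)
        amp = rng.choice([-1, 1]) * rng.uniform(0.4, 0.8)
        tau = rng.uniform(0.5, 2.0)
        step = np.where(t >= start, amp * np.exp(-(t - start) / tau), 0.0)
        x += sps.sosfiltfilt(
            sps.butter(2, min(10.0, 0.4 * fs) / (fs / 2), "low", output="sos"), step
        )

    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    return NoiseTemplate(samples=x, fs=fs, provenance=provenance)
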
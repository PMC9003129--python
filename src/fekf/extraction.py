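"""Two-pass fetal ECG extraction from a single abdominal channel.

Pass 1 estimates the maternal ECG: maternal R peaks are detected on the
preprocessed abdominal signal, each R-R interval is wrapped onto [0, 2*pi)
to give the observed phase, the record's own maternal morphology is fitted
as a Gaussian sum to the phase-averaged beat, and the chosen filter (EnKF by
default, EKF as the comparison baseline) tracks the maternal amplitude.
Subtracting the tracked maternal waveform leaves a noisy fetal residual.

Pass 2 repeats the same machinery on the residual — preliminary fetal peaks,
fetal phase, fetal morphology fit, filter — treating the residual as fetal
ECG plus Gaussian noise.  Fetal QRS complexes are finally detected on the
denoised fetal waveform.

The public surface is statsmodels-shaped: build a
:class:`SingleChannelFetalECG` model from the data, call :meth:`fit`, and
inspect the returned :class:`FetalECGResults` (waveforms, detected fetal
peaks, per-stage diagnostics, ``summary()``, ``score()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import Metrics, compute_metrics, match_peaks
from .model import (
    ECGModelParams,
    FitError,
    fit_beat_params,
    gaussian_sum,
    make_ecg_model,
    mcsharry_params,
    phase_average,
    wrap_diff,
)
from .filters import run_filter
from .preprocess import PreprocessConfig, preprocess
from .qrs import (
    FETAL_DETECTOR,
    MATERNAL_DETECTOR,
    PeakTrain,
    PhaseSeries,
    assign_phase,
    pan_tompkins,
)
from .signals import AnnotatedSignal

__all__ = [
    "PipelineConfig",
    "ExtractionError",
    "FetalECGResults",
    "ExtractionResult",
    "SingleChannelFetalECG",
    "estimate_mecg",
    "denoise_fecg",
    "extract",
]


class ExtractionError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything the two-pass pipeline needs beyond the data itself.

    Noise variances default to record-driven estimates: the amplitude
    measurement noise is the signal variance inside the isoelectric phase
    window (between the end of the T wave and the start of the P wave), and
    the state noise on the amplitude is 10x the Gaussian-sum fit residual
    variance.  Both can be overridden.
    """

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    maternal_band: tuple[float, float] = MATERNAL_DETECTOR["band"]
    maternal_refractory: float = MATERNAL_DETECTOR["refractory"]
    maternal_mwi: float = MATERNAL_DETECTOR["mwi_window"]
    fetal_band: tuple[float, float] = FETAL_DETECTOR["band"]
    fetal_refractory: float = FETAL_DETECTOR["refractory"]
    fetal_mwi: float = FETAL_DETECTOR["mwi_window"]
    n_ensemble: int = 70
    method: str = "enkf"
    seed: int = 0
    phase_bins: int = 250
    phase_var: float = 1e-2
    theta_jitter: float = 1e-6
    eta_var: float | None = None  # None -> 10x fit residual variance
    amplitude_var: float | None = None  # None -> isoelectric-window variance
    min_beats: int = 10
    refine_fetal: bool = False
    perturbation_mean: str = "zero"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pp = PreprocessConfig(**raw.pop("preprocess", {}))
        for key in ("maternal_band", "fetal_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "enabled_stages" in raw:  # tolerate flat layout
            pp.enabled_stages = tuple(raw.pop("enabled_stages"))
        return cls(preprocess=pp, **raw)


def _isoelectric_variance(
    samples: np.ndarray, phi: np.ndarray, params: ECGModelParams
) -> float:
    """Variance of the signal in the isoelectric phase window (after the T
    wave, before the P wave) — the record-driven measurement-noise proxy."""
    a = params.waves["T"].theta + 0.6
    b = params.waves["P"].theta - 0.3
    span = np.mod(b - a, 2 * np.pi)
    mask = np.mod(phi - a, 2 * np.pi) <= span
    if mask.sum() < 10:
        return float(np.var(samples))
    return float(np.var(samples[mask]))


def _model_filter_pass(
    signal: AnnotatedSignal,
    band: tuple[float, float],
    refractory: float,
    cfg: PipelineConfig,
    method: str,
    seed: int,
    init_params: ECGModelParams | None = None,
    init_width_scale: float = 1.0,
    mwi_window: float = 0.150,
) -> tuple[np.ndarray, ECGModelParams, PhaseSeries, dict]:
    """Detect peaks, fit the record's Gaussian-sum morphology, and run the
    chosen filter on [phase, amplitude] observations.

    Returns (filtered amplitude trace, fitted params, phase series,
    diagnostics).  Raises ExtractionError when the rhythm cannot support a
    morphology fit.
    """
    peaks = pan_tompkins(signal, band=band, refractory=refractory, mwi_window=mwi_window)
    if len(peaks) < cfg.min_beats:
        raise ExtractionError(
            f"only {len(peaks)} beats detected; need >= {cfg.min_beats} to fit morphology"
        )
    phase = assign_phase(peaks, signal.n_samples)
    grid, mean_beat = phase_average(signal.samples, phase.phi, n_bins=cfg.phase_bins)

    if init_params is None:
        # initialize at the canonical wave set scaled to the observed R
        # amplitude (signed, so reversed-polarity complexes fit too)
        near_r = np.abs(wrap_diff(grid)) < 0.3
        r_amp = mean_beat[near_r][np.argmax(np.abs(mean_beat[near_r]))]
        init_params = mcsharry_params(
            fs=signal.fs, amplitude_scale=float(r_amp) / 30.0, width_scale=init_width_scale
        )
    fitted = fit_beat_params(mean_beat, init_params, phase_grid=grid)
    fit_resid = gaussian_sum(grid, fitted.alphas, fitted.bs, fitted.thetas) - mean_beat
    eta_var = cfg.eta_var if cfg.eta_var is not None else 10.0 * float(np.var(fit_resid))
    amp_var = (
        cfg.amplitude_var
        if cfg.amplitude_var is not None
        else _isoelectric_variance(signal.samples, phase.phi, fitted)
    )
    amp_var = max(amp_var, 1e-12)
    params = replace(
        fitted,
        eta_var=eta_var,
        obs_noise=type(fitted.obs_noise)(cfg.phase_var, amp_var),
    )
    ss = make_ecg_model(params, omega_series=phase.omega(), theta_jitter=cfg.theta_jitter)
    obs = np.stack([phase.phi, signal.samples], axis=-1)
    est = run_filter(
        obs,
        ss,
        method=method,
        n_ensemble=cfg.n_ensemble,
        seed=seed,
        perturbation_mean=cfg.perturbation_mean,
    )
    diagnostics = {
        "n_beats": len(peaks),
        "fit_residual_rms": float(np.sqrt(np.mean(fit_resid**2))),
        "eta_var": eta_var,
        "amplitude_var": amp_var,
    }
    return est[:, 1], params, phase, diagnostics


def estimate_mecg(
    aecg: AnnotatedSignal, cfg: PipelineConfig | None = None, method: str | None = None
) -> tuple[AnnotatedSignal, ECGModelParams, PhaseSeries, dict]:
    """Estimate the maternal ECG waveform buried in the abdominal signal.

    Expects a preprocessed record with a detectable maternal rhythm; returns
    the maternal waveform estimate, the fitted maternal model parameters,
    the maternal phase series and diagnostics.
    """
    cfg = cfg or PipelineConfig()
    if aecg.n_samples == 0:
        raise ExtractionError("estimate_mecg: empty input")
    try:
        z_hat, params, phase, diag = _model_filter_pass(
            aecg,
            cfg.maternal_band,
            cfg.maternal_refractory,
            cfg,
            method or cfg.method,
            seed=cfg.seed,
            mwi_window=cfg.maternal_mwi,
        )
    except (ExtractionError, FitError, ValueError) as exc:
        raise ExtractionError(f"estimate_mecg: {exc}") from exc
    return aecg.with_samples(z_hat).with_peaks(None), params, phase, diag


def denoise_fecg(
    residual: AnnotatedSignal, cfg: PipelineConfig | None = None, method: str | None = None
) -> tuple[AnnotatedSignal, dict]:
    """Denoise the fetal residual with a second model-based filter pass.

    The residual (abdominal minus estimated maternal) is treated as fetal
    ECG plus Gaussian noise.  If no usable preliminary fetal rhythm can be
    detected or the fetal morphology fit fails, the residual is passed
    through unchanged and the skip is flagged in the diagnostics.
    """
    cfg = cfg or PipelineConfig()
    try:
        z_hat, params, phase, diag = _model_filter_pass(
            residual,
            cfg.fetal_band,
            cfg.fetal_refractory,
            cfg,
            method or cfg.method,
            seed=cfg.seed + 1,
            init_width_scale=0.5,  # fetal complexes are narrower in phase
            mwi_window=cfg.fetal_mwi,
        )
        diag["skipped"] = False
        return residual.with_samples(z_hat).with_peaks(None), diag
    except (ExtractionError, FitError, ValueError) as exc:
        warnings.warn(f"fetal denoising skipped: {exc}")
        return residual, {"skipped": True, "reason": str(exc)}


@dataclass
class FetalECGResults:
    """Result of a fitted single-channel extraction.

    ``residual == preprocessed - mecg_hat`` holds sample-exactly; all
    waveforms share the input's length and sampling rate.
    """

    preprocessed: AnnotatedSignal
    mecg_hat: AnnotatedSignal
    residual: AnnotatedSignal
    fecg_hat: AnnotatedSignal
    fqrs: PeakTrain
    diagnostics: dict
    method: str
    config: PipelineConfig

    @property
    def fs(self) -> float:
        return self.preprocessed.fs

    def fetal_heart_rate(self) -> np.ndarray:
        """Instantaneous fetal heart rate (bpm) from detected fQRS."""
        rr = self.fqrs.rr_intervals
        return 60.0 / rr if rr.size else np.array([])

    def score(self, reference: PeakTrain, window: float = 0.05) -> Metrics:
        """SE/PPV/F1 of the detected fetal peaks against a reference train."""
        return compute_metrics(match_peaks(self.fqrs, reference, window=window))

    def summary(self) -> str:
        d = self.diagnostics
        hr = self.fetal_heart_rate()
        rows = [
            ("method", self.method.upper()),
            ("ensemble size", self.config.n_ensemble if self.method == "enkf" else "-"),
            ("record length (s)", f"{self.preprocessed.duration:.1f}"),
            ("sampling rate (Hz)", f"{self.fs:.0f}"),
            ("maternal beats", d["maternal"]["n_beats"]),
            ("maternal fit residual (RMS)", f"{d['maternal']['fit_residual_rms']:.4g}"),
            ("fetal denoising", "skipped" if d["fetal"].get("skipped") else "applied"),
            ("fetal QRS detected", len(self.fqrs)),
            (
                "fetal heart rate (bpm)",
                f"{np.median(hr):.1f} (median)" if hr.size else "n/a",
            ),
        ]
        width = max(len(str(k)) for k, _ in rows)
        lines = ["Single-channel fetal ECG extraction", "=" * 40]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.mecg_hat.to_csv(out / "mecg_hat.csv")
        self.residual.to_csv(out / "residual.csv")
        self.fecg_hat.to_csv(out / "fecg_hat.csv")
        self.fqrs.to_csv(out / "fqrs.csv")

    def plot(self, ax=None):
        """Stacked view of preprocessed input, maternal estimate, and the
        denoised fetal waveform with detected fQRS."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(3, 1, sharex=True, figsize=(10, 6))
        t = self.preprocessed.times
        ax[0].plot(t, self.preprocessed.samples, lw=0.6)
        ax[0].set_ylabel("aECG")
        ax[1].plot(t, self.mecg_hat.samples, lw=0.6)
        ax[1].set_ylabel("mECG est.")
        ax[2].plot(t, self.fecg_hat.samples, lw=0.6)
        if len(self.fqrs):
            ax[2].plot(
                self.fqrs.times, self.fecg_hat.samples[self.fqrs.indices], "r*", ms=6
            )
        ax[2].set_ylabel("fECG est.")
        ax[2].set_xlabel("time (s)")
        return ax


#: alias for callers who prefer the pipeline-flavoured name
ExtractionResult = FetalECGResults


class SingleChannelFetalECG:
    """Model object for fetal ECG extraction from one abdominal channel.

    Parameters
    ----------
    signal : AnnotatedSignal or array-like
        The raw abdominal recording (annotations, if present, are treated as
        fetal ground truth for scoring, never used by the fit).
    fs : float, required when ``signal`` is a bare array.
    config : PipelineConfig, optional.

    Examples
    --------
    >>> model = SingleChannelFetalECG(record.aecg)
    >>> res = model.fit(method="enkf", seed=1)
    >>> print(res.summary())
    """

    def __init__(
        self,
        signal: AnnotatedSignal | np.ndarray,
        fs: float | None = None,
        config: PipelineConfig | None = None,
    ):
        if isinstance(signal, AnnotatedSignal):
            self.data = signal
        else:
            if fs is None:
                raise ValueError("fs is required for array input")
            self.data = AnnotatedSignal(np.asarray(signal, dtype=float), fs=fs)
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        fs: float | None = None,
        column: str = "amplitude",
        time_column: str | None = None,
        config: PipelineConfig | None = None,
    ) -> "SingleChannelFetalECG":
        """Build the model from a DataFrame with an amplitude column.

        ``fs`` may instead be inferred from a uniformly sampled
        ``time_column`` (seconds).
        """
        if fs is None:
            if time_column is None:
                raise ValueError("give fs or a time column")
            dt = np.diff(df[time_column].to_numpy(dtype=float))
            if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("time column is not uniformly sampled")
            fs = 1.0 / dt[0]
        return cls(df[column].to_numpy(dtype=float), fs=fs, config=config)

    def fit(
        self,
        method: str | None = None,
        n_ensemble: int | None = None,
        seed: int | None = None,
    ) -> FetalECGResults:
        """Run preprocessing, maternal cancellation, fetal denoising and
        fetal QRS detection; deterministic for a fixed seed."""
        cfg = self.config
        if method is not None or n_ensemble is not None or seed is not None:
            cfg = replace(
                cfg,
                method=method or cfg.method,
                n_ensemble=n_ensemble or cfg.n_ensemble,
                seed=cfg.seed if seed is None else seed,
            )
        if cfg.method not in ("enkf", "ekf"):
            raise ValueError("method must be 'enkf' or 'ekf'")

        try:
            pre = preprocess(self.data, cfg.preprocess)
        except Exception as exc:
            raise ExtractionError(f"preprocess: {exc}") from exc

        mecg_hat, m_params, m_phase, m_diag = estimate_mecg(pre, cfg)
        residual = pre.with_samples(pre.samples - mecg_hat.samples).with_peaks(None)
        fecg_hat, f_diag = denoise_fecg(residual, cfg)
        if cfg.refine_fetal and not f_diag.get("skipped"):
            # one refinement iteration: re-detect fetal rhythm on the
            # denoised trace and re-run the fetal pass on the residual
            fecg_hat2, f_diag2 = denoise_fecg(
                residual.with_samples(fecg_hat.samples), cfg
            )
            if not f_diag2.get("skipped"):
                fecg_hat, f_diag = fecg_hat2, f_diag2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fqrs = pan_tompkins(
                fecg_hat,
                band=cfg.fetal_band,
                refractory=cfg.fetal_refractory,
                mwi_window=cfg.fetal_mwi,
            )
        diagnostics = {
            "maternal": m_diag,
            "fetal": f_diag,
            "n_ensemble": cfg.n_ensemble,
            "maternal_params": m_params,
        }
        return FetalECGResults(
            preprocessed=pre,
            mecg_hat=mecg_hat,
            residual=residual,
            fecg_hat=fecg_hat,
            fqrs=fqrs,
            diagnostics=diagnostics,
            method=cfg.method,
            config=cfg,
        )


def extract(
    aecg: AnnotatedSignal,
    method: str = "enkf",
    cfg: PipelineConfig | None = None,
    n_ensemble: int | None = None,
    seed: int | None = None,
) -> FetalECGResults:
    """Functional entry point: build the model and fit in one call."""
    model = SingleChannelFetalECG(aecg, config=cfg)
    return model.fit(method=method, n_ensemble=n_ensemble, seed=seed)
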
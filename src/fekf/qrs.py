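"""R-peak detection (Pan-Tompkins) and R-R phase assignment.

The detector follows the classic stage chain — bandpass, derivative,
squaring, moving-window integration, adaptive dual thresholds with
search-back — and is polarity-insensitive by construction (the squaring
stage), which matters because fetal QRS complexes can be reversed by
electrode placement.

Phase assignment linearly time-wraps each R-R interval onto [0, 2*pi),
producing the observed-phase channel of the dynamic ECG model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signals import AnnotatedSignal

__all__ = ["PeakTrain", "PhaseSeries", "pan_tompkins", "assign_phase"]

#: detector defaults: bandpass (Hz), refractory (s), integration window (s)
MATERNAL_DETECTOR = {"band": (5.0, 15.0), "refractory": 0.25, "mwi_window": 0.150}
FETAL_DETECTOR = {"band": (10.0, 70.0), "refractory": 0.2, "mwi_window": 0.080}


@dataclass(frozen=True)
class PeakTrain:
    """Detected (or ground-truth) R-peak sample indices at a sampling rate,
    with the dominant QRS polarity."""

    indices: np.ndarray
    fs: float
    polarity: int = 1

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.fs

    @property
    def rr_intervals(self) -> np.ndarray:
        """Beat-to-beat intervals in seconds."""
        return np.diff(self.indices) / self.fs

    def to_csv(self, path) -> None:
        np.savetxt(path, self.indices[:, None], fmt="%d", header="peak_index", comments="")


@dataclass(frozen=True)
class PhaseSeries:
    """Per-sample phase in [0, 2*pi), zero exactly at each source peak and
    linear in between (wrapping at 2*pi)."""

    phi: np.ndarray
    source_peaks: PeakTrain

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        object.__setattr__(self, "phi", phi)

    def omega(self) -> np.ndarray:
        """Per-sample angular velocity (rad/s): 2*pi over the local R-R
        interval, extended with the nearest interval at the edges."""
        peaks = self.source_peaks.indices
        fs = self.source_peaks.fs
        rr = np.diff(peaks) / fs
        om = np.empty(self.phi.size)
        om[: peaks[0]] = 2 * np.pi / rr[0]
        for j in range(rr.size):
            om[peaks[j] : peaks[j + 1]] = 2 * np.pi / rr[j]
        om[peaks[-1] :] = 2 * np.pi / rr[-1]
        return om


def _moving_integration(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def pan_tompkins(
    signal: AnnotatedSignal,
    band: tuple[float, float] = (5.0, 15.0),
    refractory: float = 0.25,
    mwi_window: float = 0.150,
) -> PeakTrain:
    """Detect R peaks with the Pan-Tompkins stage chain.

    All linear stages are zero-phase so detected locations can be compared
    against ground truth within tens of milliseconds.  Returned peaks are
    refined to the local absolute-amplitude extremum of the bandpassed
    signal within +/-40 ms of each integrator peak.  An empty train (with a
    warning) is returned when nothing crosses the adaptive thresholds.
    """
    fs = signal.fs
    low, high = band
    if fs < 2 * high:
        raise ValueError(f"sampling rate {fs} Hz too low for band {band}")
    if signal.duration < 2.0:
        raise ValueError("need at least 2 s of signal")
    x = signal.samples

    sos = sps.butter(2, [low / (fs / 2), high / (fs / 2)], btype="band", output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    squared = deriv**2
    integ = _moving_integration(squared, max(int(round(mwi_window * fs)), 1))

    if not np.any(integ > 0):
        warnings.warn("no QRS candidates found; returning empty peak train")
        return PeakTrain(indices=np.array([], dtype=int), fs=fs)

    ref_samp = max(int(round(refractory * fs)), 1)
    cand, _ = sps.find_peaks(integ, distance=ref_samp)
    if cand.size == 0:
        warnings.warn("no QRS candidates found; returning empty peak train")
        return PeakTrain(indices=np.array([], dtype=int), fs=fs)

    # adaptive dual thresholds over the integrated waveform; initialized
    # from robust whole-record statistics so one initialization transient
    # cannot pin the signal level (this is an offline detector)
    spki = 0.25 * np.percentile(integ[cand], 90)
    npki = 0.5 * np.median(integ[cand])
    spki_cap = 4.0 * spki
    qrs: list[int] = []
    rr_history: list[float] = []
    last_qrs = -np.inf
    for c in cand:
        thr1 = npki + 0.25 * (spki - npki)
        if integ[c] > thr1 and c - last_qrs >= ref_samp:
            # search-back: a long gap since the last beat suggests a missed
            # low-amplitude QRS between the two
            if qrs and rr_history:
                rr_avg = np.mean(rr_history[-8:])
                if (c - last_qrs) > 1.66 * rr_avg:
                    gap = cand[(cand > last_qrs + ref_samp) & (cand < c - ref_samp // 2)]
                    if gap.size:
                        thr2 = 0.5 * thr1
                        above = gap[integ[gap] > thr2]
                        if above.size:
                            back = above[np.argmax(integ[above])]
                            rr_history.append(back - last_qrs)
                            qrs.append(int(back))
                            last_qrs = back
            if qrs:
                rr_history.append(c - last_qrs)
            # clip outlier peaks so one artifact cannot raise the threshold
            spki = 0.125 * min(integ[c], spki_cap) + 0.875 * spki
            qrs.append(int(c))
            last_qrs = c
        else:
            npki = 0.125 * integ[c] + 0.875 * npki

    if not qrs:
        warnings.warn("no peaks above adaptive threshold; returning empty train")
        return PeakTrain(indices=np.array([], dtype=int), fs=fs)

    # refine to the extremum of the bandpassed signal within +/-40 ms.  The
    # dominant polarity is decided first (majority vote over the signed
    # absolute extrema) so every beat anchors on the same crest — mixing
    # crest and trough anchors would smear the phase-averaged morphology.
    half = max(int(round(0.040 * fs)), 1)
    windows = [(max(c - half, 0), min(c + half + 1, x.size)) for c in qrs]
    signed = [bp[lo + int(np.argmax(np.abs(bp[lo:hi])))] for lo, hi in windows]
    polarity = 1 if np.median(np.sign(signed)) >= 0 else -1
    refined = [lo + int(np.argmax(polarity * bp[lo:hi])) for lo, hi in windows]
    refined = np.array(sorted(set(refined)), dtype=int)
    # enforce the refractory period after refinement, keeping the stronger peak
    keep = []
    for idx in refined:
        if keep and idx - keep[-1] < ref_samp:
            if np.abs(bp[idx]) > np.abs(bp[keep[-1]]):
                keep[-1] = idx
        else:
            keep.append(idx)
    refined = np.array(keep, dtype=int)
    return PeakTrain(indices=refined, fs=fs, polarity=polarity)


def assign_phase(peaks: PeakTrain, n_samples: int) -> PhaseSeries:
    """Linear time-wrapping of each R-R interval onto [0, 2*pi).

    For samples k between consecutive peaks r_j and r_{j+1}:
    ``phi_k = 2*pi * (k - r_j) / (r_{j+1} - r_j)``; before the first and
    after the last peak the nearest R-R interval is extrapolated.
    """
    idx = peaks.indices
    if idx.size < 2:
        raise ValueError("assign_phase requires at least 2 peaks")
    k = np.arange(n_samples, dtype=float)
    # unwrapped phase: 2*pi*j at peak j, linear in between
    theta = np.interp(k, idx.astype(float), 2 * np.pi * np.arange(idx.size))
    rr_first = idx[1] - idx[0]
    rr_last = idx[-1] - idx[-2]
    before = k < idx[0]
    after = k > idx[-1]
    theta[before] = -2 * np.pi * (idx[0] - k[before]) / rr_first
    theta[after] = 2 * np.pi * (idx.size - 1 + (k[after] - idx[-1]) / rr_last)
    phi = np.mod(theta, 2 * np.pi)
    phi[idx[(idx >= 0) & (idx < n_samples)]] = 0.0  # exact anchors
    return PhaseSeries(phi=phi, source_peaks=peaks)
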
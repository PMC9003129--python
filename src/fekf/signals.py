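"""Core signal container shared by every stage of the toolkit.

An :class:`AnnotatedSignal` is a uniformly sampled single-channel waveform
together with its sampling rate and, optionally, ground-truth R-peak sample
indices (used by the simulator and by scoring).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AnnotatedSignal"]


@dataclass(frozen=True)
class AnnotatedSignal:
    """A sampled waveform plus sampling rate and optional R-peak annotations.

    Parameters
    ----------
    samples : ndarray of float, shape (n,)
        The waveform, in arbitrary signal units.
    fs : float
        Sampling rate in Hz.
    peaks : ndarray of int, optional
        Ground-truth R-peak sample indices, strictly increasing.
    """

    samples: np.ndarray
    fs: float
    peaks: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "samples", samples)
        if self.peaks is not None:
            peaks = np.asarray(self.peaks, dtype=int)
            if peaks.size and (np.any(np.diff(peaks) <= 0)):
                raise ValueError("peak indices must be strictly increasing")
            if peaks.size and (peaks[0] < 0 or peaks[-1] >= samples.size):
                raise ValueError("peak indices out of range")
            object.__setattr__(self, "peaks", peaks)

    # -- basic descriptors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def with_samples(self, samples: np.ndarray) -> "AnnotatedSignal":
        """Return a copy carrying new samples but the same fs/annotations."""
        return replace(self, samples=np.asarray(samples, dtype=float))

    def with_peaks(self, peaks: np.ndarray | None) -> "AnnotatedSignal":
        return replace(self, peaks=peaks)

    # -- CSV serialization -------------------------------------------------

    def to_csv(self, path: str | Path, peaks_path: str | Path | None = None) -> None:
        """Write samples as CSV (sample_index, amplitude) plus a peak sidecar.

        The sidecar (one ``peak_index`` column) is written only when the
        signal carries annotations and ``peaks_path`` is given or derivable
        (``<stem>.peaks.csv``).
        """
        path = Path(path)
        df = pd.DataFrame(
            {"sample_index": np.arange(self.n_samples), "amplitude": self.samples}
        )
        df.attrs["fs"] = self.fs
        with open(path, "w") as fh:
            fh.write(f"# fs={self.fs}\n")
            df.to_csv(fh, index=False)
        if self.peaks is not None:
            if peaks_path is None:
                peaks_path = path.with_suffix("").with_suffix(".peaks.csv")
            pd.DataFrame({"peak_index": self.peaks}).to_csv(peaks_path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        fs: float | None = None,
        peaks_path: str | Path | None = None,
    ) -> "AnnotatedSignal":
        """Read a signal written by :meth:`to_csv`.

        ``fs`` may be omitted when the file carries the ``# fs=`` header line.
        """
        path = Path(path)
        header_fs = None
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#") and "fs=" in first:
            header_fs = float(first.split("fs=")[1].strip())
        if fs is None:
            fs = header_fs
        if fs is None:
            raise ValueError(f"{path}: sampling rate not in header and not given")
        try:
            df = pd.read_csv(path, comment="#")
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ValueError(f"{path}: cannot parse CSV record: {exc}") from exc
        if "amplitude" not in df.columns:
            raise ValueError(f"{path}: missing 'amplitude' column")
        peaks = None
        if peaks_path is None:
            candidate = path.with_suffix("").with_suffix(".peaks.csv")
            if candidate.exists():
                peaks_path = candidate
        if peaks_path is not None:
            pdf = pd.read_csv(peaks_path)
            peaks = pdf["peak_index"].to_numpy(dtype=int)
        return cls(df["amplitude"].to_numpy(dtype=float), fs=fs, peaks=peaks)
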
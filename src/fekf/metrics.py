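"""Beat-detection scoring: SE, PPV and F1 from matched R-peak trains.

Detected fetal R peaks are matched one-to-one against reference annotations
within a tolerance window (default +/-50 ms, the PhysioNet/CinC 2013 scoring
convention), and the counts feed

    SE  = TP / (TP + FN)
    PPV = TP / (TP + FP)
    F1  = 2 TP / (2 TP + FN + FP)

reported in percent.  F1 is the harmonic mean of SE and PPV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qrs import PeakTrain

__all__ = ["DetectionCounts", "Metrics", "match_peaks", "compute_metrics"]


@dataclass(frozen=True)
class DetectionCounts:
    """True-positive / false-positive / false-negative counts at a matching
    window (seconds)."""

    tp: int
    fp: int
    fn: int
    window: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class Metrics:
    """Detection metrics in percent; NaN entries mark degenerate cases
    (empty reference or empty detection set)."""

    se: float
    ppv: float
    f1: float
    degenerate: bool = False


def match_peaks(
    detected: PeakTrain, reference: PeakTrain, window: float = 0.05
) -> DetectionCounts:
    """One-to-one greedy matching of detected peaks to reference peaks.

    Detected peaks are scanned in increasing time order; each claims the
    earliest unmatched reference peak within ``+/-window`` seconds.  For
    points on a line this earliest-available rule attains the maximum
    one-to-one matching, which also makes the counts symmetric under
    swapping the two trains.  Matched pairs are TP; unmatched detected peaks
    are FP; unmatched reference peaks are FN.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    det_t = detected.times
    ref_t = reference.times
    matched = np.zeros(ref_t.size, dtype=bool)
    tp = 0
    for t in det_t:
        ok = np.flatnonzero(~matched & (np.abs(ref_t - t) <= window + 1e-12))
        if ok.size:
            matched[ok[0]] = True
            tp += 1
    fp = det_t.size - tp
    fn = ref_t.size - tp
    return DetectionCounts(tp=tp, fp=fp, fn=fn, window=window)


def compute_metrics(counts: DetectionCounts) -> Metrics:
    """SE / PPV / F1 in percent from detection counts.

    Degenerate denominators give NaN for the affected metric (flagged via
    ``degenerate``) instead of raising — maternal-only records legitimately
    produce empty detection or reference sets.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    se = 100.0 * tp / (tp + fn) if tp + fn > 0 else float("nan")
    ppv = 100.0 * tp / (tp + fp) if tp + fp > 0 else float("nan")
    f1 = 100.0 * 2 * tp / (2 * tp + fn + fp) if 2 * tp + fn + fp > 0 else float("nan")
    degenerate = (tp + fn == 0) or (tp + fp == 0)
    return Metrics(se=se, ppv=ppv, f1=f1, degenerate=degenerate)
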
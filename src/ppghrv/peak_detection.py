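"""Systolic (P) peak detection and PP-interval construction.

The detector is a slope tracker: while successive samples rise the running
maximum is updated; the first falling sample after a rising run declares a
candidate peak.  The candidate is then refined to the highest sample within
a trailing buffer (default 0.2 s), guarding against locally noisy maxima.
Candidates closer to the previous accepted peak than a refractory period
(default 0.27 s, i.e. a 220 bpm ceiling) are merged: the later candidate
replaces the earlier one only if it is strictly higher.

An optional relative prominence threshold rejects low-amplitude candidates
such as the dicrotic bump (about 30% of systolic amplitude); it is off by
default so the bare slope-tracking behaviour is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .signal_io import IntervalSeries, PeakList, SampledSignal

__all__ = [
    "DetectorConfig",
    "detect_peaks",
    "peaks_to_intervals",
    "match_peaks",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Peak-detector parameters.

    buffer_s: trailing refinement window (s); refractory_s: minimum
    inter-peak spacing (s); min_prominence: candidate height threshold as a
    fraction of the signal's full amplitude range (0 disables it).
    """

    buffer_s: float = 0.2
    refractory_s: float = 0.27
    min_prominence: float = 0.0

    def __post_init__(self) -> None:
        if not self.buffer_s > 0:
            raise ValueError("buffer_s must be positive")
        if self.refractory_s < 0:
            raise ValueError("refractory_s must be non-negative")
        if not (0 <= self.min_prominence < 1):
            raise ValueError("min_prominence must lie in [0, 1)")


def detect_peaks(signal: SampledSignal, config: DetectorConfig = DetectorConfig()) -> PeakList:
    """Detect systolic peaks by slope tracking with buffer refinement."""
    x = signal.samples
    if len(x) < 2:
        raise ValueError("signal too short for peak detection (need >= 2 samples)")
    buf_n = int(round(config.buffer_s * signal.fs))
    if buf_n < 2:
        raise ValueError(
            f"refinement buffer of {config.buffer_s} s holds fewer than 2 "
            f"samples at fs={signal.fs} Hz"
        )
    if config.min_prominence > 0:
        lo, hi = float(np.min(x)), float(np.max(x))
        height_floor = lo + config.min_prominence * (hi - lo)
    else:
        height_floor = -np.inf

    peaks: list[int] = []
    rising = False
    for i in range(1, len(x)):
        if x[i] > x[i - 1]:
            rising = True
            continue
        if x[i] < x[i - 1] and rising:
            rising = False
            cand = i - 1
            w_lo = max(0, cand - buf_n + 1)
            refined = w_lo + int(np.argmax(x[w_lo: cand + 1]))  # earliest on ties
            if x[refined] < height_floor:
                continue
            if peaks and refined <= peaks[-1]:
                continue
            if peaks and (refined - peaks[-1]) / signal.fs < config.refractory_s:
                # later wins only if strictly higher
                if x[refined] > x[peaks[-1]]:
                    peaks[-1] = refined
                continue
            peaks.append(refined)
    return PeakList(np.asarray(peaks, dtype=np.int64), fs=signal.fs,
                    t0=signal.t0, n_samples=len(x))


def peaks_to_intervals(peaks: PeakList) -> IntervalSeries:
    """Pulse-to-pulse intervals: PPI[i] = (T[i+1] - T[i]) in ms."""
    if len(peaks) < 2:
        raise ValueError("insufficient beats: need at least 2 peaks")
    times = peaks.times
    intervals = np.diff(times) * 1000.0
    return IntervalSeries(intervals, times[1:], kind="PP")


def match_peaks(
    truth_times: np.ndarray,
    detected_times: np.ndarray,
    tol_s: float = 0.02,
    align: bool = False,
) -> Tuple[float, float, float]:
    """Greedy one-to-one matching of detected against true peak times.

    Returns (sensitivity, positive predictive value, applied offset in s).
    With ``align=True`` the median detected-minus-truth offset of nearest
    pairs is removed first, discounting any constant latency (causal filter
    delay, pulse transit time) so only timing *jitter* is scored.
    """
    truth = np.sort(np.asarray(truth_times, dtype=float))
    det = np.sort(np.asarray(detected_times, dtype=float))
    offset = 0.0
    if align and truth.size and det.size:
        j = np.searchsorted(truth, det)
        j = np.clip(j, 1, truth.size - 1) if truth.size > 1 else np.zeros_like(j)
        lower = truth[np.maximum(j - 1, 0)]
        upper = truth[np.minimum(j, truth.size - 1)]
        nearest = np.where(np.abs(det - lower) <= np.abs(det - upper), lower, upper)
        offset = float(np.median(det - nearest))
        det = det - offset
    used = np.zeros(truth.size, dtype=bool)
    tp = 0
    for d in det:
        k = np.searchsorted(truth, d)
        best, best_err = -1, np.inf
        for c in (k - 1, k):
            if 0 <= c < truth.size and not used[c]:
                err = abs(truth[c] - d)
                if err < best_err:
                    best, best_err = c, err
        if best >= 0 and best_err <= tol_s:
            used[best] = True
            tp += 1
    sens = tp / truth.size if truth.size else np.nan
    ppv = tp / det.size if det.size else np.nan
    return sens, ppv, offset
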
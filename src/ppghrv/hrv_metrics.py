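"""Linear heart-rate-variability analysis of a beat-interval series.

Time domain: SDNN (SD of all intervals), SDANN (SD of 5-min segment
means), SDindex (mean of 5-min segment SDs), RMSSD (root mean square of
successive differences).  Geometric: the interval histogram on the
standard 1/128 s (7.8125 ms) grid, the HRV triangular index (total count
over modal bin count), TINN (base width of the least-squares triangular
fit to the histogram), and Poincaré SD1/SD2.  Frequency domain: VLF
(0.0033-0.04 Hz), LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) band powers of
the tachogram, by cubic resampling onto a uniform 4 Hz grid followed by a
Welch periodogram (default) or by a Lomb-Scargle periodogram on the
irregular beat times.

All variances are sample variances (N-1 divisor).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import interpolate as spi
from scipy import signal as sps

from .signal_io import IntervalSeries

__all__ = [
    "DEFAULT_BANDS",
    "BIN_MS_DEFAULT",
    "Histogram",
    "TimeDomainMetrics",
    "GeometricMetrics",
    "SpectralMetrics",
    "HRVReport",
    "nn_filter",
    "time_domain",
    "interval_histogram",
    "hrv_triangular_index",
    "tinn",
    "poincare",
    "band_powers",
    "analyze",
]

#: Standard short/long-term frequency bands, Hz (half-open [lo, hi)).
DEFAULT_BANDS: Dict[str, Tuple[float, float]] = {
    "vlf": (0.0033, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.4),
}

#: Standard histogram bin width: 1/128 s.
BIN_MS_DEFAULT = 7.8125

_POWER_FLOOR_MS2 = 1e-6


@dataclass(frozen=True)
class Histogram:
    """Interval histogram on bins aligned to multiples of ``bin_ms``."""

    centers_ms: np.ndarray
    counts: np.ndarray
    bin_ms: float

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TimeDomainMetrics:
    sdnn_ms: float
    rmssd_ms: float
    sdann_ms: Optional[float] = None
    sdindex_ms: Optional[float] = None


@dataclass(frozen=True)
class GeometricMetrics:
    hrvti: float
    tinn_ms: float
    sd1_ms: float
    sd2_ms: float
    histogram_centers_ms: np.ndarray
    histogram_counts: np.ndarray


@dataclass(frozen=True)
class SpectralMetrics:
    power_vlf_ms2: float
    power_lf_ms2: float
    power_hf_ms2: float
    pct_vlf: float
    pct_lf: float
    pct_hf: float
    lf_hf_ratio: Optional[float]
    vlf_reliable: bool = True
    method: str = "resample_welch"


@dataclass(frozen=True)
class HRVReport:
    time: Optional[TimeDomainMetrics]
    geometric: Optional[GeometricMetrics]
    spectral: Optional[SpectralMetrics]
    meta: dict


def nn_filter(intervals: IntervalSeries, max_rel_dev: float = 0.2) -> IntervalSeries:
    """Reject artifact/ectopic intervals against a running median.

    An interval is accepted if it deviates from the median of the last
    five *accepted* intervals by at most ``max_rel_dev`` (fraction).  The
    first interval is always accepted.  Returns an NN-tagged series.
    """
    if not (0 < max_rel_dev <= 1):
        raise ValueError("max_rel_dev must lie in (0, 1]")
    iv = intervals.intervals_ms
    t = intervals.times_s
    keep = np.zeros(len(iv), dtype=bool)
    accepted: list[float] = []
    for i, v in enumerate(iv):
        if not accepted:
            keep[i] = True
            accepted.append(v)
            continue
        med = float(np.median(accepted[-5:]))
        if abs(v - med) / med <= max_rel_dev:
            keep[i] = True
            accepted.append(v)
    if not keep.any():
        raise ValueError("nn_filter removed every interval")
    return IntervalSeries(iv[keep], t[keep], kind="NN")


def _complete_segments(intervals: IntervalSeries, segment_s: float):
    """Group intervals into consecutive full segments by occurrence time.

    Segment k spans [t_start + k*segment_s, t_start + (k+1)*segment_s);
    the final partial segment is dropped.
    """
    t0 = intervals.times_s[0] - intervals.intervals_ms[0] / 1000.0
    rel = intervals.times_s - t0
    duration = rel[-1]
    n_seg = int(duration // segment_s)
    segs = []
    for k in range(n_seg):
        mask = (rel > k * segment_s) & (rel <= (k + 1) * segment_s)
        if mask.sum() >= 2:
            segs.append(intervals.intervals_ms[mask])
    return segs


def time_domain(intervals: IntervalSeries, segment_s: float = 300.0) -> TimeDomainMetrics:
    """SDNN, RMSSD, and (duration permitting) SDANN and SDindex."""
    iv = intervals.intervals_ms
    if len(iv) < 2:
        raise ValueError("time-domain metrics need at least 2 intervals")
    sdnn = float(np.std(iv, ddof=1))
    rmssd = float(np.sqrt(np.mean(np.diff(iv) ** 2)))
    sdann: Optional[float] = None
    sdindex: Optional[float] = None
    if intervals.duration_s >= segment_s:
        segs = _complete_segments(intervals, segment_s)
        if len(segs) >= 2:
            sdann = float(np.std([s.mean() for s in segs], ddof=1))
        else:
            warnings.warn(
                "fewer than 2 complete segments: SDANN not computed", stacklevel=2
            )
        if segs:
            sdindex = float(np.mean([np.std(s, ddof=1) for s in segs]))
    else:
        warnings.warn(
            f"recording shorter than one {segment_s:.0f} s segment: "
            "SDANN/SDindex not computed",
            stacklevel=2,
        )
    return TimeDomainMetrics(sdnn_ms=sdnn, rmssd_ms=rmssd,
                             sdann_ms=sdann, sdindex_ms=sdindex)


def interval_histogram(intervals: IntervalSeries, bin_ms: float = BIN_MS_DEFAULT) -> Histogram:
    """Histogram of intervals on half-open bins [k*bin_ms, (k+1)*bin_ms).

    A value exactly on a bin edge belongs to the upper bin.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    iv = intervals.intervals_ms
    if len(iv) == 0:
        raise ValueError("cannot histogram an empty interval series")
    k = np.floor(iv / bin_ms).astype(np.int64)
    k_lo, k_hi = int(k.min()), int(k.max())
    counts = np.bincount(k - k_lo, minlength=k_hi - k_lo + 1)
    centers = (np.arange(k_lo, k_hi + 1) + 0.5) * bin_ms
    return Histogram(centers_ms=centers, counts=counts, bin_ms=bin_ms)


def hrv_triangular_index(hist: Histogram) -> float:
    """Total interval count divided by the modal bin count."""
    if hist.counts.size == 0 or hist.n == 0:
        raise ValueError("empty histogram")
    return hist.n / float(hist.counts.max())


def _triangle(centers: np.ndarray, n_pos: float, m_pos: float,
              x_pos: float, height: float) -> np.ndarray:
    q = np.zeros_like(centers, dtype=float)
    up = (centers > n_pos) & (centers <= x_pos)
    down = (centers > x_pos) & (centers < m_pos)
    if x_pos > n_pos:
        q[up] = height * (centers[up] - n_pos) / (x_pos - n_pos)
    down_w = m_pos - x_pos
    if down_w > 0:
        q[down] = height * (m_pos - centers[down]) / down_w
    q[np.isclose(centers, x_pos)] = height
    return q


def tinn(hist: Histogram) -> float:
    """Base width (M - N, ms) of the best least-squares triangular fit.

    The triangle is zero outside [N, M], rises linearly to the modal bin's
    height at the mode position X, and falls linearly to zero at M.  N and
    M are searched exhaustively on the bin-center grid left/right of the
    mode (one bin of margin beyond the occupied span); squared error is
    accumulated over all bins of the padded span.  Fits whose errors agree
    to within a relative 1e-9 are treated as tied; ties prefer the
    narrower, then the more leftward triangle.  A single-bin histogram
    degenerates to one bin width.
    """
    counts = np.asarray(hist.counts, dtype=float)
    occupied = np.nonzero(counts)[0]
    if occupied.size == 0:
        raise ValueError("empty histogram")
    if occupied.size == 1:
        return hist.bin_ms
    mode_i = int(np.argmax(counts))
    height = counts[mode_i]
    # pad one empty bin either side so N/M may sit just outside the data
    centers = np.concatenate((
        [hist.centers_ms[0] - hist.bin_ms],
        hist.centers_ms,
        [hist.centers_ms[-1] + hist.bin_ms],
    ))
    padded = np.concatenate(([0.0], counts, [0.0]))
    x_pos = centers[mode_i + 1]
    n_cands = centers[: mode_i + 1]
    m_cands = centers[mode_i + 2:]
    best_err = np.inf
    best_nm = (n_cands[0], m_cands[-1])
    for n_pos in n_cands:
        for m_pos in m_cands:
            q = _triangle(centers, n_pos, m_pos, x_pos, height)
            err = float(np.sum((padded - q) ** 2))
            if err < best_err * (1 - 1e-9):
                better = True
            elif err <= best_err * (1 + 1e-9):  # tie at float precision
                key = (m_pos - n_pos, n_pos)
                better = key < (best_nm[1] - best_nm[0], best_nm[0])
            else:
                better = False
            if better:
                best_err = min(err, best_err)
                best_nm = (n_pos, m_pos)
    return float(best_nm[1] - best_nm[0])


def poincare(intervals: IntervalSeries) -> Tuple[float, float, np.ndarray]:
    """Poincaré plot dispersions SD1 (anti-diagonal) and SD2 (diagonal).

    The cloud is the set of points (interval_i, interval_{i+1}); SD1/SD2
    are the sample SDs of the rotated coordinates (y-x)/sqrt(2) and
    (y+x)/sqrt(2).  Returns (sd1_ms, sd2_ms, cloud) with cloud of shape
    (N-1, 2).
    """
    iv = intervals.intervals_ms
    if len(iv) < 3:
        raise ValueError("Poincaré analysis needs at least 3 intervals")
    x, y = iv[:-1], iv[1:]
    sd1 = float(np.std((y - x) / np.sqrt(2), ddof=1))
    sd2 = float(np.std((y + x) / np.sqrt(2), ddof=1))
    return sd1, sd2, np.column_stack((x, y))


def _welch_psd(intervals: IntervalSeries, resample_hz: float,
               segment_s: float) -> Tuple[np.ndarray, np.ndarray]:
    t = intervals.times_s
    y = intervals.intervals_ms
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    f_interp = spi.interp1d(t, y, kind="cubic", assume_sorted=True)
    yu = f_interp(grid)
    yu = yu - yu.mean()
    nperseg = min(len(yu), int(segment_s * resample_hz))
    freqs, psd = sps.welch(
        yu, fs=resample_hz, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant",
    )
    return freqs, psd


def _lombscargle_psd(intervals: IntervalSeries,
                     f_max: float) -> Tuple[np.ndarray, np.ndarray]:
    t = intervals.times_s
    y = intervals.intervals_ms - intervals.intervals_ms.mean()
    span = t[-1] - t[0]
    df = 1.0 / (4.0 * span)  # 4x oversampled grid
    freqs = np.arange(df, f_max + df, df)
    pgram = sps.lombscargle(t, y, 2 * np.pi * freqs)
    # unnormalised LS equals |X(f)|^2 / N; one-sided density = 2|X|^2/(N*fs)
    # with mean rate fs = N/span, hence psd = 2 * pgram * span / N
    psd = 2.0 * pgram * span / len(t)
    return freqs, psd


def band_powers(
    intervals: IntervalSeries,
    method: str = "resample_welch",
    bands: Dict[str, Tuple[float, float]] = DEFAULT_BANDS,
    resample_hz: float = 4.0,
    welch_segment_s: float = 120.0,
) -> SpectralMetrics:
    """VLF/LF/HF band powers (ms²) of the interval tachogram.

    Default path: cubic interpolation onto a uniform ``resample_hz`` grid,
    mean removal, Welch periodogram (Hann window, ``welch_segment_s``
    segments, 50% overlap); band power is the PSD integral over each band.
    ``method='lombscargle'`` computes the periodogram directly on the
    irregular beat times instead.  Percent powers are relative to the
    VLF+LF+HF total; the LF/HF ratio is omitted when HF power is at the
    numeric floor.
    """
    if len(intervals) < 4:
        raise ValueError("spectral analysis needs at least 4 intervals")
    duration = intervals.times_s[-1] - intervals.times_s[0]
    if duration < 120:
        raise ValueError(
            f"record of {duration:.0f} s too short for LF/HF analysis (need 120 s)"
        )
    vlf_reliable = duration >= 300
    if not vlf_reliable:
        warnings.warn("record shorter than 300 s: VLF power unreliable", stacklevel=2)
    f_max = max(hi for _, hi in bands.values())
    if method == "resample_welch":
        freqs, psd = _welch_psd(intervals, resample_hz, welch_segment_s)
    elif method == "lombscargle":
        freqs, psd = _lombscargle_psd(intervals, f_max)
    else:
        raise ValueError(f"unknown spectral method {method!r}")
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 0.0
    powers = {}
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs < hi)
        powers[name] = float(np.sum(psd[mask]) * df)
    total = powers["vlf"] + powers["lf"] + powers["hf"]
    if total > _POWER_FLOOR_MS2:
        pct = {k: 100.0 * v / total for k, v in powers.items()}
    else:
        pct = {k: float("nan") for k in powers}
    ratio = (powers["lf"] / powers["hf"]
             if powers["hf"] > _POWER_FLOOR_MS2 else None)
    return SpectralMetrics(
        power_vlf_ms2=powers["vlf"],
        power_lf_ms2=powers["lf"],
        power_hf_ms2=powers["hf"],
        pct_vlf=pct["vlf"],
        pct_lf=pct["lf"],
        pct_hf=pct["hf"],
        lf_hf_ratio=ratio,
        vlf_reliable=vlf_reliable,
        method=method,
    )


def analyze(
    intervals: IntervalSeries,
    record_id: str = "",
    segment_s: float = 300.0,
    bin_ms: float = BIN_MS_DEFAULT,
    spectral_method: str = "resample_welch",
    bands: Dict[str, Tuple[float, float]] = DEFAULT_BANDS,
) -> HRVReport:
    """Full linear HRV report; a failing metric group is reported as null
    rather than aborting the others."""
    meta = {
        "record_id": record_id,
        "n_intervals": len(intervals),
        "duration_s": intervals.duration_s,
        "kind": intervals.kind,
        "config": {
            "segment_s": segment_s,
            "bin_ms": bin_ms,
            "spectral_method": spectral_method,
            "bands": {k: list(v) for k, v in bands.items()},
        },
        "warnings": [],
    }
    time_m = geom_m = spec_m = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            time_m = time_domain(intervals, segment_s=segment_s)
        except ValueError as exc:
            meta["warnings"].append(f"time_domain: {exc}")
        try:
            hist = interval_histogram(intervals, bin_ms=bin_ms)
            sd1, sd2, _ = poincare(intervals)
            geom_m = GeometricMetrics(
                hrvti=hrv_triangular_index(hist),
                tinn_ms=tinn(hist),
                sd1_ms=sd1,
                sd2_ms=sd2,
                histogram_centers_ms=hist.centers_ms,
                histogram_counts=hist.counts,
            )
        except ValueError as exc:
            meta["warnings"].append(f"geometric: {exc}")
        try:
            spec_m = band_powers(intervals, method=spectral_method, bands=bands)
        except ValueError as exc:
            meta["warnings"].append(f"spectral: {exc}")
    meta["warnings"].extend(str(w.message) for w in caught)
    return HRVReport(time=time_m, geometric=geom_m, spectral=spec_m, meta=meta)
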
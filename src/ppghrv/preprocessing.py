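"""Four-stage PPG preprocessing chain.

The chain mirrors the firmware-style pipeline of low-cost PPG devices:

1. **Averaging** — accumulate W raw samples and emit their mean (a
   decimating block average; a non-decimating sliding mean is also offered).
2. **DC removal** — the first-order IIR DC-blocking filter
   ``y[n] = x[n] - x[n-1] + R*y[n-1]`` with leakage parameter R (default
   0.95); only the pulsatile (AC) component of the optical signal carries
   beat information.
3. **Median filtering** — a causal running median over the last n samples
   to suppress large spike deviations; for an even window the mean of the
   two middle order statistics is used.
4. **Low-pass filtering** — a first-order bilinear-transform design
   ``y[n] = k1*(x[n] + x[n-1]) + k2*y[n-1]`` with -3 dB cut-off fc
   (default 10 Hz at fs = 100 Hz), removing content above the cardiac band.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .signal_io import SampledSignal

__all__ = [
    "FilterConfig",
    "averaging_filter",
    "remove_dc",
    "median_filter",
    "lowpass",
    "lowpass_coefficients",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the four preprocessing stages."""

    avg_window: int = 2
    avg_mode: str = "block"
    R: float = 0.95
    median_window: int = 3
    lowpass_fc: float = 10.0

    def __post_init__(self) -> None:
        if self.avg_window < 1:
            raise ValueError("avg_window must be >= 1")
        if self.avg_mode not in ("block", "sliding"):
            raise ValueError("avg_mode must be 'block' or 'sliding'")
        if self.median_window < 1:
            raise ValueError("median_window must be >= 1")
        if not (0 < self.R < 1):
            raise ValueError("R must lie in (0, 1)")
        if not (0.9 <= self.R < 1):
            warnings.warn(
                f"R={self.R} outside the recommended [0.9, 1) range",
                stacklevel=2,
            )
        if self.lowpass_fc <= 0:
            raise ValueError("lowpass_fc must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def averaging_filter(signal: SampledSignal, W: int, mode: str = "block") -> SampledSignal:
    """Average over W samples.

    ``block`` accumulates W consecutive samples and emits one mean, so the
    output rate is fs/W (a trailing partial block is dropped).  ``sliding``
    emits the mean of the last W samples at every input sample (the first
    W-1 outputs average the available prefix), leaving fs unchanged.
    """
    if W < 1:
        raise ValueError("averaging window W must be >= 1")
    x = signal.samples
    if W == 1:
        return signal
    if mode == "block":
        n_blocks = len(x) // W
        out = x[: n_blocks * W].reshape(n_blocks, W).mean(axis=1) if n_blocks else x[:0]
        return SampledSignal(out, fs=signal.fs / W, t0=signal.t0)
    if mode == "sliding":
        if len(x) == 0:
            return signal
        csum = np.concatenate(([0.0], np.cumsum(x)))
        idx = np.arange(len(x))
        lo = np.maximum(0, idx - W + 1)
        out = (csum[idx + 1] - csum[lo]) / (idx + 1 - lo)
        return SampledSignal(out, fs=signal.fs, t0=signal.t0)
    raise ValueError(f"unknown averaging mode {mode!r}")


def remove_dc(
    signal: SampledSignal,
    R: float = 0.95,
    x_prev: float | None = None,
    y_prev: float = 0.0,
) -> SampledSignal:
    """DC-blocking filter ``y[n] = x[n] - x[n-1] + R*y[n-1]``.

    Default initial conditions ``x[-1] = x[0]``, ``y[-1] = 0`` suppress the
    startup transient: a constant input maps to identically zero output.
    Pass ``x_prev``/``y_prev`` to continue from a known filter state.
    """
    if not (0 < R < 1):
        raise ValueError("R must lie in (0, 1)")
    if not (0.9 <= R < 1):
        warnings.warn(f"R={R} outside the recommended [0.9, 1) range", stacklevel=2)
    x = signal.samples
    if len(x) == 0:
        return signal
    if x_prev is None:
        x_prev = x[0]
    b = [1.0, -1.0]
    a = [1.0, -R]
    # direct-form II transposed state: z[-1] = b1*x[-1] - a1*y[-1]
    zi = np.array([-x_prev + R * y_prev])
    y, _ = sps.lfilter(b, a, x, zi=zi)
    return SampledSignal(y, fs=signal.fs, t0=signal.t0)


def median_filter(signal: SampledSignal, n: int = 3) -> SampledSignal:
    """Causal running median over the last ``n`` samples.

    The first ``n-1`` outputs use the available shorter prefix window.  An
    even (effective) window yields the mean of the two middle sorted values.
    """
    if n < 1:
        raise ValueError("median window n must be >= 1")
    x = signal.samples
    if n == 1 or len(x) == 0:
        return signal
    out = np.empty_like(x)
    head = min(n - 1, len(x))
    for i in range(head):
        out[i] = np.median(x[: i + 1])
    if len(x) >= n:
        out[n - 1:] = np.median(sliding_window_view(x, n), axis=1)
    return SampledSignal(out, fs=signal.fs, t0=signal.t0)


def lowpass_coefficients(fc: float, fs: float) -> Tuple[float, float]:
    """First-order bilinear-transform low-pass coefficients (k1, k2).

    With ``a = tan(pi*fc/fs)``: ``k1 = a/(1+a)``, ``k2 = (1-a)/(1+a)``.
    The design has unit DC gain (2*k1/(1-k2) = 1) and its -3 dB point falls
    exactly at fc because the bilinear transform pre-warps the analogue
    cut-off.
    """
    if not (0 < fc < fs / 2):
        raise ValueError(f"cut-off {fc} Hz must lie in (0, fs/2) = (0, {fs / 2})")
    a = np.tan(np.pi * fc / fs)
    return a / (1 + a), (1 - a) / (1 + a)


def lowpass(
    signal: SampledSignal,
    fc: float = 10.0,
    x_prev: float | None = None,
    y_prev: float | None = None,
) -> SampledSignal:
    """First-order low-pass ``y[n] = k1*(x[n] + x[n-1]) + k2*y[n-1]``.

    Default initial conditions ``x[-1] = y[-1] = x[0]``: a constant input
    passes through unchanged from the first sample.  Pass ``x_prev`` /
    ``y_prev`` to continue from a known filter state.
    """
    k1, k2 = lowpass_coefficients(fc, signal.fs)
    x = signal.samples
    if len(x) == 0:
        return signal
    if x_prev is None:
        x_prev = x[0]
    if y_prev is None:
        y_prev = x[0]
    b = [k1, k1]
    a = [1.0, -k2]
    # z[-1] = b1*x[-1] - a1*y[-1]
    zi = np.array([k1 * x_prev + k2 * y_prev])
    y, _ = sps.lfilter(b, a, x, zi=zi)
    return SampledSignal(y, fs=signal.fs, t0=signal.t0)


def preprocess_pipeline(signal: SampledSignal, config: FilterConfig = FilterConfig()) -> SampledSignal:
    """Apply averaging -> DC removal -> median -> low-pass in order.

    Block averaging changes the effective sampling rate; the rate is
    carried on the returned signal so downstream stages (e.g. the 0.2 s
    peak-refinement buffer) adapt automatically.
    """
    out = averaging_filter(signal, config.avg_window, config.avg_mode)
    if out.fs != signal.fs:
        logger.info("averaging stage changed fs: %g -> %g Hz", signal.fs, out.fs)
    if config.lowpass_fc >= out.fs / 2:
        raise ValueError(
            f"lowpass_fc={config.lowpass_fc} Hz is not below the post-averaging "
            f"Nyquist frequency {out.fs / 2} Hz"
        )
    out = remove_dc(out, config.R)
    out = median_filter(out, config.median_window)
    out = lowpass(out, config.lowpass_fc)
    return out
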
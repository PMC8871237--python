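"""Data model and on-disk formats for PPG/HRV processing.

Three containers flow through the toolkit:

* :class:`SampledSignal` — a uniformly sampled amplitude stream with its
  sampling rate (the raw and filtered PPG waveform);
* :class:`PeakList` — detected systolic (P) or ECG R-peak positions on the
  source signal's sample grid;
* :class:`IntervalSeries` — the beat-to-beat interval tachogram (PP, RR or
  artifact-cleaned NN intervals, in milliseconds), the substrate of every
  HRV computation.

On disk, signals are single-column CSV with an optional ``# fs=<Hz>``
comment header; interval series use the plain one-value-per-line RR-file
convention (milliseconds) so they interoperate with standard HRV tools;
reports are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import numpy as np

__all__ = [
    "SampledSignal",
    "PeakList",
    "IntervalSeries",
    "read_signal_csv",
    "write_signal_csv",
    "read_intervals",
    "write_intervals",
    "write_report",
    "read_report",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled signal: amplitude units are arbitrary.

    The time of sample ``i`` is ``t0 + i / fs`` seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("samples must all be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(len(self)) / self.fs

    def replace(self, **changes: Any) -> "SampledSignal":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class PeakList:
    """Detected peak positions as sample indices on a source signal."""

    indices: np.ndarray
    fs: float
    t0: float = 0.0
    n_samples: Optional[int] = None  # source length, for bounds checking

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if idx.size:
            if np.any(np.diff(idx) <= 0):
                raise ValueError("peak indices must be strictly increasing")
            if idx[0] < 0:
                raise ValueError("peak indices must be non-negative")
            if self.n_samples is not None and idx[-1] >= self.n_samples:
                raise ValueError("peak index beyond source signal bounds")

    def __len__(self) -> int:
        return self.indices.size

    @property
    def times(self) -> np.ndarray:
        """Peak times in seconds."""
        return self.t0 + self.indices / self.fs


@dataclass(frozen=True)
class IntervalSeries:
    """Beat-to-beat intervals in milliseconds.

    ``times_s[i]`` is the occurrence time (s) of the beat that *closes*
    interval ``i``.  ``kind`` tags the series as PP (PPG-derived), RR
    (ECG-derived) or NN (artifact-filtered normal-to-normal).
    """

    intervals_ms: np.ndarray
    times_s: np.ndarray
    kind: str = "RR"

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals_ms, dtype=float)
        t = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "intervals_ms", iv)
        object.__setattr__(self, "times_s", t)
        if iv.shape != t.shape or iv.ndim != 1:
            raise ValueError("intervals_ms and times_s must be 1-d and equal length")
        if iv.size:
            if np.any(iv <= 0) or not np.all(np.isfinite(iv)):
                raise ValueError("all intervals must be finite and positive")
            if np.any(np.diff(t) <= 0):
                raise ValueError("interval times must be strictly increasing")
        if self.kind not in ("PP", "RR", "NN"):
            raise ValueError(f"kind must be PP, RR or NN, got {self.kind!r}")

    def __len__(self) -> int:
        return self.intervals_ms.size

    @property
    def duration_s(self) -> float:
        """Total covered duration: sum of the intervals, in seconds."""
        return float(self.intervals_ms.sum()) / 1000.0

    @classmethod
    def from_intervals(
        cls, intervals_ms: Sequence[float], kind: str = "RR", t_start_s: float = 0.0
    ) -> "IntervalSeries":
        """Build a series from intervals alone; times are the cumulative sum."""
        iv = np.asarray(intervals_ms, dtype=float)
        times = t_start_s + np.cumsum(iv) / 1000.0
        return cls(iv, times, kind=kind)

    def replace(self, **changes: Any) -> "IntervalSeries":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# readers / writers


def read_signal_csv(path: PathLike, fs_override: Optional[float] = None) -> SampledSignal:
    """Read a one-column amplitude CSV with an optional ``# fs=<Hz>`` header.

    ``fs_override``, when given, wins over the header.  A file with neither
    header nor override is an error.
    """
    path = Path(path)
    fs_header: Optional[float] = None
    values: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("fs"):
                    try:
                        fs_header = float(body.split("=", 1)[1])
                    except (IndexError, ValueError) as exc:
                        raise ValueError(
                            f"{path}:{lineno}: malformed fs header {line!r}"
                        ) from exc
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric sample value {line!r}"
                ) from exc
    fs = fs_override if fs_override is not None else fs_header
    if fs is None:
        raise ValueError(
            f"{path}: no sampling rate: file has no '# fs=' header and no "
            "override was given"
        )
    return SampledSignal(np.asarray(values, dtype=float), fs=float(fs))


def write_signal_csv(signal: SampledSignal, path: PathLike) -> None:
    """Write a signal as one-column CSV with a ``# fs=`` header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={signal.fs:g}\n")
        for v in signal.samples:
            fh.write(f"{v:.9g}\n")


def read_intervals(path: PathLike, kind: str = "RR") -> IntervalSeries:
    """Read a plain-text interval file: one interval in ms per line.

    Occurrence times are reconstructed as the cumulative sum of the
    intervals (first beat of the recording taken as time zero).
    """
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                v = float(line)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric interval {line!r}"
                ) from exc
            if v <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive interval {v}")
            values.append(v)
    return IntervalSeries.from_intervals(values, kind=kind)


def write_intervals(series: IntervalSeries, path: PathLike, decimals: int = 3) -> None:
    """Write one interval (ms) per line, the de-facto RR-file convention."""
    path = Path(path)
    with path.open("w") as fh:
        for v in series.intervals_ms:
            fh.write(f"{v:.{decimals}f}\n")


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(report: Any, path: PathLike) -> None:
    """Serialise a report (any toolkit dataclass or plain dict) to JSON.

    Every metric is written together with the configuration that produced
    it; NaN/inf become JSON null.
    """
    path = Path(path)
    payload = _jsonable(report)
    with path.open("w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_report(path: PathLike) -> dict:
    with Path(path).open() as fh:
        return json.load(fh)
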
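"""Synthetic paired ECG/PPG generation with known ground truth.

The generator follows a light-weight integral-pulse model: beat-to-beat
intervals are a mean level plus sinusoidal oscillations in the VLF/LF/HF
autonomic bands plus white jitter, evaluated at cumulative beat time.  A
PPG waveform is then rendered from the beat times as a sum of two-Gaussian
pulses (systolic peak plus a delayed dicrotic bump), and realistic noise —
baseline wander, white noise, motion spikes, DC offset — is layered on top.

Because the exact beat times and intervals are retained, every downstream
stage (filters, peak detector, HRV metrics, synchrony statistics) can be
validated against exact ground truth without any external recordings.

Two cohort presets are provided: ``HEALTHY_PRESET`` (mean PP 829 ms, SDNN
around 140 ms) and ``SYNCOPE_PRESET`` (mean PP 734 ms, reduced overall
variability and strongly reduced LF power), mirroring the magnitudes and,
above all, the *direction* of healthy-vs-syncope HRV differences.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .signal_io import IntervalSeries, PeakList, SampledSignal

__all__ = [
    "CohortConfig",
    "NoiseConfig",
    "PairedRecording",
    "HEALTHY_PRESET",
    "SYNCOPE_PRESET",
    "generate_interval_series",
    "render_ppg",
    "generate_paired_recordings",
    "generate_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the beat-interval model for one cohort.

    intervals_ms(t) = mean_rr_ms
                      + ulf_amp·sin(2π·ulf_freq·t + φ_ulf)
                      + vlf_amp·sin(2π·vlf_freq·t + φ_vlf)
                      + lf_amp·sin(2π·lf_freq·t + φ_lf)
                      + hf_amp·sin(2π·hf_freq·t + φ_hf)
                      + ε,   ε ~ N(0, noise_sd_ms²)

    with t the cumulative beat time.  Phases default to zero; cohort
    sampling randomises them per subject.  The ULF drift (period longer
    than a 5-min segment) is what drives SDANN, the between-segment
    variability; VLF/LF/HF feed the spectral bands.
    """

    n_subjects: int = 20
    duration_s: float = 1200.0
    mean_rr_ms: float = 850.0
    sd_rr_ms: float = 100.0  # informational target, not enforced
    ulf_amp_ms: float = 0.0
    ulf_freq_hz: float = 0.001
    vlf_amp_ms: float = 0.0
    vlf_freq_hz: float = 0.005
    lf_amp_ms: float = 50.0
    lf_freq_hz: float = 0.1
    hf_amp_ms: float = 30.0
    hf_freq_hz: float = 0.25
    noise_sd_ms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_rr_ms > 0:
            raise ValueError("mean_rr_ms must be positive")
        if not self.duration_s >= 60:
            raise ValueError("duration_s must be at least 60 s")
        for name in ("ulf_freq_hz", "vlf_freq_hz", "lf_freq_hz", "hf_freq_hz"):
            f = getattr(self, name)
            if not (0 < f < 0.5):
                raise ValueError(f"{name} must lie in (0, 0.5) Hz, got {f}")
        for name in ("ulf_amp_ms", "vlf_amp_ms", "lf_amp_ms", "hf_amp_ms",
                     "noise_sd_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")

    def replace(self, **changes) -> "CohortConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class NoiseConfig:
    """Additive PPG measurement-noise model.

    baseline wander: a slow sinusoid (respiration / sensor-motion drift);
    white noise: broadband sensor noise; spikes: sparse motion artifacts of
    one-sample amplitude ``spike_amp`` at Poisson rate ``spike_rate_hz``;
    dc_offset: the constant (quasi-DC) component of the optical signal.
    """

    baseline_amp: float = 0.0
    baseline_freq_hz: float = 0.25
    white_sd: float = 0.0
    spike_rate_hz: float = 0.0
    spike_amp: float = 0.0
    dc_offset: float = 0.0

    def __post_init__(self) -> None:
        for name in ("baseline_amp", "baseline_freq_hz", "white_sd",
                     "spike_rate_hz", "spike_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# Presets mirroring the magnitudes of the study's two groups: healthy
# controls (mean PP 829 ms, SDNN ~143 ms) and syncope patients (mean PP
# 734 ms, SDNN ~87 ms, LF power reduced roughly in proportion to the
# ~1800 -> ~830 ms^2 drop seen clinically).  Sinusoid amplitudes are set so
# that the summed component variances (amp^2/2 per oscillator plus the
# jitter variance) match the SDNN target.
HEALTHY_PRESET = CohortConfig(
    n_subjects=20,
    duration_s=1200.0,
    mean_rr_ms=829.0,
    sd_rr_ms=143.0,
    ulf_amp_ms=120.0,
    ulf_freq_hz=0.001,
    vlf_amp_ms=140.0,
    vlf_freq_hz=0.005,
    lf_amp_ms=60.0,
    lf_freq_hz=0.1,
    hf_amp_ms=40.0,
    hf_freq_hz=0.25,
    noise_sd_ms=25.0,
    seed=0,
)

SYNCOPE_PRESET = CohortConfig(
    n_subjects=20,
    duration_s=1200.0,
    mean_rr_ms=734.0,
    sd_rr_ms=87.0,
    ulf_amp_ms=70.0,
    ulf_freq_hz=0.001,
    vlf_amp_ms=90.0,
    vlf_freq_hz=0.005,
    lf_amp_ms=40.0,
    lf_freq_hz=0.1,
    hf_amp_ms=30.0,
    hf_freq_hz=0.25,
    noise_sd_ms=15.0,
    seed=0,
)


def generate_interval_series(
    config: CohortConfig,
    rng: Optional[np.random.Generator] = None,
    phases: Tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0),
    amp_scale: float = 1.0,
    kind: str = "RR",
) -> IntervalSeries:
    """Generate one beat-interval series from the cohort model.

    ``phases`` are the (ULF, VLF, LF, HF) oscillator phases in radians;
    ``amp_scale`` multiplies all oscillation amplitudes and the jitter SD
    (used for between-subject spread).  Draws whose interval would be
    non-positive are redrawn rather than clipped, so the mean is unbiased.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p_ulf, p_vlf, p_lf, p_hf = phases
    a_ulf = config.ulf_amp_ms * amp_scale
    a_vlf = config.vlf_amp_ms * amp_scale
    a_lf = config.lf_amp_ms * amp_scale
    a_hf = config.hf_amp_ms * amp_scale
    sd = config.noise_sd_ms * amp_scale
    intervals: list[float] = []
    times: list[float] = []
    t = 0.0
    while True:
        det = (
            config.mean_rr_ms
            + a_ulf * np.sin(2 * np.pi * config.ulf_freq_hz * t + p_ulf)
            + a_vlf * np.sin(2 * np.pi * config.vlf_freq_hz * t + p_vlf)
            + a_lf * np.sin(2 * np.pi * config.lf_freq_hz * t + p_lf)
            + a_hf * np.sin(2 * np.pi * config.hf_freq_hz * t + p_hf)
        )
        iv = det + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        while iv <= 0:  # redraw, don't clip: clipping would bias the mean
            if det <= 0 and sd == 0:
                raise ValueError("deterministic interval non-positive; "
                                 "oscillation amplitudes exceed the mean")
            iv = det + rng.normal(0.0, sd)
        t_next = t + iv / 1000.0
        if t_next > config.duration_s:
            break
        intervals.append(iv)
        times.append(t_next)
        t = t_next
    return IntervalSeries(np.asarray(intervals), np.asarray(times), kind=kind)


def _beat_times(intervals: IntervalSeries) -> np.ndarray:
    """All beat times including the opening beat of the first interval."""
    first = intervals.times_s[0] - intervals.intervals_ms[0] / 1000.0
    return np.concatenate(([first], intervals.times_s))


def _render_from_beats(
    beat_times: np.ndarray,
    fs: float,
    noise: NoiseConfig,
    rng: np.random.Generator,
    duration_s: Optional[float] = None,
) -> Tuple[SampledSignal, np.ndarray]:
    if fs < 50:
        raise ValueError("fs must be at least 50 Hz to render pulse waveforms")
    if beat_times.size == 0:
        raise ValueError("cannot render PPG from an empty beat list")
    local = np.diff(beat_times)
    tail = local[-1] if local.size else 0.8
    if duration_s is None:
        # leave room for the last pulse's dicrotic tail
        duration_s = beat_times[-1] + tail
    # lead-in before the first beat so its rising edge is rendered
    t_start = beat_times[0] - tail
    n = int(np.ceil((duration_s - t_start) * fs)) + 1
    t = t_start + np.arange(n) / fs
    x = np.zeros(n)
    # local interval per beat: the following interval, last beat reuses the
    # previous one (pulse width tracks the instantaneous rate)
    diffs = np.diff(beat_times)
    if diffs.size == 0:
        local_iv = np.array([0.8])
    else:
        local_iv = np.concatenate((diffs, [diffs[-1]]))
    for b, T in zip(beat_times, local_iv):
        sig_w = 0.08 * T
        dic_w = 0.12 * T
        # restrict to a +-6 sigma neighbourhood for speed
        lo = max(0, int((b - 6 * sig_w - t_start) * fs))
        hi = min(n, int((b + 0.3 * T + 6 * dic_w - t_start) * fs) + 1)
        tt = t[lo:hi]
        x[lo:hi] += np.exp(-0.5 * ((tt - b) / sig_w) ** 2)
        x[lo:hi] += 0.3 * np.exp(-0.5 * ((tt - b - 0.3 * T) / dic_w) ** 2)
    if noise.baseline_amp > 0:
        x += noise.baseline_amp * np.sin(2 * np.pi * noise.baseline_freq_hz * t)
    if noise.white_sd > 0:
        x += rng.normal(0.0, noise.white_sd, size=n)
    if noise.spike_rate_hz > 0 and noise.spike_amp > 0:
        n_spikes = rng.poisson(noise.spike_rate_hz * duration_s)
        pos = rng.integers(0, n, size=n_spikes)
        signs = rng.choice([-1.0, 1.0], size=n_spikes)
        x[pos] += signs * noise.spike_amp
    x += noise.dc_offset
    return SampledSignal(x, fs=fs, t0=t_start), beat_times.copy()


def render_ppg(
    intervals: IntervalSeries,
    fs: float,
    noise: NoiseConfig = NoiseConfig(),
    rng: Optional[np.random.Generator] = None,
) -> Tuple[SampledSignal, np.ndarray]:
    """Render a PPG waveform from a beat-interval series.

    Each beat is a unit-amplitude Gaussian systolic peak (width 8% of the
    local interval) plus a dicrotic bump of amplitude 0.3 delayed by 30% of
    the interval.  Returns the signal and the exact systolic apex times
    (seconds) as ground truth.
    """
    if len(intervals) == 0:
        raise ValueError("cannot render PPG from an empty interval series")
    if rng is None:
        rng = np.random.default_rng(0)
    return _render_from_beats(_beat_times(intervals), fs, noise, rng)


@dataclass(frozen=True)
class PairedRecording:
    """Simultaneous synthetic ECG annotation + PPG recording pair."""

    ppg: SampledSignal
    ecg_peaks: PeakList
    truth: IntervalSeries            # RR truth driving both channels
    pp_truth: IntervalSeries         # exact PPG-side intervals (post desync)
    ppg_apex_times: np.ndarray       # exact systolic apex times (s)
    transit_delay_s: float
    desync_fraction: float


def generate_paired_recordings(
    config: CohortConfig,
    fs: float = 100.0,
    noise: NoiseConfig = NoiseConfig(),
    transit_delay_s: float = 0.2,
    desync_fraction: float = 0.0,
    desync_jitter_s: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> PairedRecording:
    """Generate a synchronous ECG-annotation / PPG pair from one beat train.

    ECG R peaks sit at the underlying beat times; PPG pulses at the same
    times plus a fixed pulse-transit delay.  ``desync_fraction`` of the PPG
    beats are randomly jittered (SD ``desync_jitter_s``) to mimic the
    pathological loss of ECG-PPG synchrony seen in syncope patients.
    """
    if not (0.0 <= desync_fraction <= 1.0):
        raise ValueError("desync_fraction must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = generate_interval_series(config, rng=rng)
    beats = _beat_times(truth)
    ecg_idx = np.round(beats * fs).astype(np.int64)
    ecg_idx = np.unique(ecg_idx)
    ecg_peaks = PeakList(ecg_idx, fs=fs)

    ppg_beats = beats + transit_delay_s
    if desync_fraction > 0:
        n_pert = int(round(desync_fraction * ppg_beats.size))
        pick = rng.choice(ppg_beats.size, size=n_pert, replace=False)
        min_gap = 0.25  # keep the perturbed train physiological
        for j in np.sort(pick):
            lo = ppg_beats[j - 1] + min_gap if j > 0 else 0.0
            hi = ppg_beats[j + 1] - min_gap if j + 1 < ppg_beats.size else np.inf
            b = ppg_beats[j] + rng.normal(0.0, desync_jitter_s)
            while not (lo < b < hi):
                b = ppg_beats[j] + rng.normal(0.0, desync_jitter_s)
            ppg_beats[j] = b
    pp_iv = np.diff(ppg_beats) * 1000.0
    pp_truth = IntervalSeries(pp_iv, ppg_beats[1:], kind="PP")
    ppg, apex = _render_from_beats(
        ppg_beats, fs, noise, rng,
        duration_s=config.duration_s + transit_delay_s + 1.0,
    )
    return PairedRecording(
        ppg=ppg,
        ecg_peaks=ecg_peaks,
        truth=truth,
        pp_truth=pp_truth,
        ppg_apex_times=apex,
        transit_delay_s=transit_delay_s,
        desync_fraction=desync_fraction,
    )


def generate_cohort(
    config: CohortConfig,
    subject_sd: float = 0.12,
    kind: str = "PP",
) -> list[IntervalSeries]:
    """Sample ``config.n_subjects`` interval series for one cohort.

    Between-subject spread: each subject gets independent oscillator phases
    (uniform on [0, 2π)) and a common amplitude factor drawn from
    N(1, subject_sd²) clipped to [0.5, 1.5] applied to all oscillation
    amplitudes and the white jitter.
    """
    rng = np.random.default_rng(config.seed)
    subjects = []
    for _ in range(config.n_subjects):
        phases = tuple(rng.uniform(0, 2 * np.pi, size=4))
        scale = float(np.clip(rng.normal(1.0, subject_sd), 0.5, 1.5))
        subjects.append(
            generate_interval_series(
                config, rng=rng, phases=phases, amp_scale=scale, kind=kind
            )
        )
    return subjects
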
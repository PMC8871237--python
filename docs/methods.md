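# Methods

This note documents the models, conventions and numerical choices behind
`ppghrv`, in the spirit of the methods documentation of mature scientific
packages: what each stage assumes, which parameters matter, and what the
synthetic validation does and does not demonstrate.

## Signal model and preprocessing

A raw PPG stream is treated as a uniformly sampled amplitude sequence with
a known sampling rate (`SampledSignal`); amplitudes are dimensionless
because sensor ADC scaling varies between devices and cancels out of every
downstream quantity. Sample `i` occurs at `t0 + i/fs`.

The preprocessing chain applies four causal stages in a fixed order,
mirroring the accumulate-and-filter loop of embedded PPG firmware:

1. **Averaging** (`avg_window` W, default 2). The faithful reading of an
   accumulate-W-then-divide loop is a *decimating block average*, so
   `mode="block"` emits one mean per W samples and divides the sampling
   rate by W. The effective rate is carried on the signal, so later stages
   (e.g. the 0.2 s refinement buffer) adapt automatically. A
   non-decimating `mode="sliding"` running mean is available when rate
   preservation matters; its first W−1 outputs average the available
   prefix.
2. **DC blocking** `y_n = x_n − x_{n−1} + R·y_{n−1}` with leakage
   `R = 0.95` (warned outside [0.9, 1)). This one-pole high-pass has its
   corner near `fs(1−R)/2π` ≈ 0.8 Hz at 100 Hz; only the pulsatile (AC)
   component of the optical signal survives. Default initial conditions
   `x_{−1} = x_0`, `y_{−1} = 0` make a constant input map to exactly zero
   with no startup transient (both are overridable for streaming
   continuation); a constant tail decays geometrically with ratio R.
3. **Median filter** over the last `n` samples (default 3), causal, with
   shorter prefix windows at the start; an even effective window yields
   the mean of the two middle order statistics. The median suppresses
   isolated motion spikes that linear filters would smear.
4. **Low-pass** `y_n = k₁(x_n + x_{n−1}) + k₂·y_{n−1}`. The `(x_n +
   x_{n−1})` numerator identifies this as the first-order bilinear
   transform design, the only standard design with that topology, so the
   coefficients are `a = tan(π f_c/fs)`, `k₁ = a/(1+a)`,
   `k₂ = (1−a)/(1+a)`. DC gain is exactly 1 (`2k₁/(1−k₂) = 1`) and the
   −3 dB point falls exactly at `f_c` (default 10 Hz) because the bilinear
   transform pre-warps the analogue corner. Initial conditions
   `x_{−1} = y_{−1} = x_0` pass a constant through unchanged.

All four stages are causal by design — the chain must be implementable in
streaming firmware — so each filter contributes a frequency-dependent
delay. This matters for peak timing (below). Zero-phase forward–backward
filtering is deliberately out of scope.

## Peak detection

The detector tracks the slope: a rising run followed by a falling sample
declares a candidate, which is then refined to the argmax over the
trailing `buffer_s` window (default 0.2 s; earliest index wins ties).
Candidates within `refractory_s` of the last accepted peak are merged,
the later one winning only if strictly higher. The default refractory
period of 0.27 s is the beat spacing of the physiological ceiling of
220 bpm.

Slope tracking alone fires on any local maximum, including the dicrotic
bump (≈30% of systolic amplitude, ≈30% of the beat interval after the
systolic peak). At high heart rates the refractory period absorbs it; at
low rates it does not, so the detector offers `min_prominence`, a
candidate-height floor expressed as a fraction of the signal's amplitude
range. It defaults to 0 (off) to preserve the bare algorithm; accuracy
validation enables it (0.45–0.5), which cleanly separates unit-amplitude
systolic peaks from 0.3-amplitude dicrotic bumps. The floor is computed
from the global range, which assumes an amplitude-stabilised (preprocessed
or synthetic) signal; it is not an adaptive threshold.

Peak times are reported at sample resolution — no sub-sample
interpolation. Timing accuracy is therefore bounded below by half a
sample (5 ms at 100 Hz).

When detection runs on a causally filtered signal, every peak inherits
the filter chain's group delay (≈45–100 ms for the smoothing used in the
noisy-signal tests). That delay is constant across beats, so it cancels
in every PP interval; the evaluation helper `match_peaks(..., align=True)`
removes the median detected-minus-truth offset before applying the
±20 ms match tolerance, scoring jitter rather than latency — the same
reasoning that makes pulse-transit delay irrelevant to PP-interval
validity.

## Interval series and artifact filtering

`IntervalSeries` stores intervals in ms with the occurrence time of each
closing beat; PP/RR/NN tags distinguish PPG-derived, ECG-derived and
artifact-filtered series. The optional NN filter accepts an interval when
it deviates from the median of the last five accepted intervals by at most
`max_rel_dev` (the first interval seeds the filter). It is off by default
in every pipeline: artifact filtering changes the series being analysed
and should be an explicit analyst decision.

## HRV metrics

All variances use the sample (N−1) divisor.

* **SDNN** — SD of all intervals. **RMSSD** — root mean square of
  successive differences. **SDANN** / **SDindex** — SD of segment means /
  mean of segment SDs over consecutive complete 5-minute segments
  (`segment_s = 300`, the standard choice); a trailing partial segment is
  dropped, segments need ≥2 intervals, SDANN needs ≥2 complete segments.
  Records shorter than one segment report these as absent with a warning
  rather than a misleading number.
* **Histogram** — half-open bins `[k·Δ, (k+1)·Δ)` aligned to multiples of
  `Δ = 1/128 s = 7.8125 ms`, the conventional discretisation of
  interval-counting hardware; an edge value belongs to the upper bin.
* **HRV triangular index** — total count divided by the modal bin count
  (≥1 by construction).
* **TINN** — base width `M − N` of the least-squares triangle fitted to
  the histogram: zero outside `[N, M]`, linear up to the modal height at
  the mode position, linear down to `M`. `N` and `M` are searched
  exhaustively on the bin-centre grid (one empty bin of margin beyond the
  occupied span). Fits whose errors agree within a relative 1e−9 are
  treated as tied — squared-error sums are order-sensitive in floating
  point — and ties prefer the narrower, then more leftward triangle. A
  single-bin histogram degenerates to one bin width.
* **Poincaré SD1/SD2** — sample SDs of the rotated coordinates
  `(x_{i+1} − x_i)/√2` and `(x_{i+1} + x_i)/√2` of the lag-1 scatter
  cloud; the cloud itself is returned for plotting ("comet" vs "torpedo"
  shapes are left to visual inspection, not classified).
* **Band powers** — the tachogram (interval vs beat time) is cubically
  interpolated onto a uniform 4 Hz grid, mean-removed, and analysed with
  a Welch periodogram (Hann window, 120 s segments, 50% overlap); band
  power is the PSD integral over VLF [0.0033, 0.04), LF [0.04, 0.15) and
  HF [0.15, 0.4) Hz, in ms². 4 Hz comfortably oversamples any plausible
  beat rate; 120 s segments resolve the LF band's lower edge while still
  averaging several segments on a 10–20 min record. A Lomb–Scargle path
  evaluates the periodogram directly on the irregular beat times
  (normalised to one-sided power density via the mean sampling rate) for
  cross-checking and gappy series. Percent powers are taken over the
  VLF+LF+HF total, the convention under which the three percent rows of a
  standard HRV table sum to 100. Records shorter than 120 s are rejected;
  shorter than 300 s flag VLF as unreliable. The LF/HF ratio is omitted
  when HF power sits at the numeric floor (10⁻⁶ ms²).

Statistical caveat: spectral band powers of a 5–20 min record estimate the
oscillatory content of *that record*; they are not denoised estimates of a
subject's long-run autonomic state.

## Synchrony and discrimination statistics

* **MSE** between an RR and a PP series is computed on second-scaled
  intervals, paired index-by-index after truncating to the shorter series
  (no alignment convention is assumed beyond a shared start; the dropped
  count is logged). On this scale, synchronous healthy recordings produce
  values of order 10⁻² s² and desynchronised pathological ones roughly
  ten-fold larger.
* **Relative error** is `100·|ECG − PPG| / PPG` — the PPG value is the
  denominator. This is the only convention that reproduces all eight
  published healthy/syncope error cells from their printed group means at
  two decimals; `|Δ|/ECG` does not. It is asymmetric, so the report
  records which series was which.
* **Welch's t-test** (unequal variances, Welch–Satterthwaite df) rather
  than the pooled test: observed HRV group variances differ several-fold,
  and Welch is valid either way.
* **ROC/AUC** — the curve sweeps all distinct thresholds; the trapezoidal
  area equals the midrank Mann–Whitney `U/(n₁n₂)`, which is how ties are
  handled. The standard error uses the Hanley–McNeil exponential
  approximation and the "asymptotic 95% CI" is `AUC ± 1.96·SE` clipped to
  [0, 1]. With `orient="auto"` the score sign is flipped when AUC < 0.5
  and the flip is recorded. No multiple-testing correction is applied to
  the per-metric table by default, matching common practice in small HRV
  cohort studies; Benjamini–Hochberg can be layered on by the caller.

## Synthetic data generator

The generator is an interval-domain construction (an "IPFM-lite"): the
i-th interval is the mean plus sinusoids evaluated at the cumulative beat
time plus Gaussian jitter,

```
PP_i = μ + Σ_b A_b·sin(2π f_b t_i + φ_b) + ε_i,   ε_i ~ N(0, σ²)
```

with one oscillator per band: ULF (default 0.001 Hz — slow drift with a
period longer than a 5-min segment, the component that generates SDANN),
VLF (0.005 Hz), LF (0.1 Hz) and HF (0.25 Hz). Interval-domain modulation
is analytically tractable: a single oscillator of amplitude A contributes
variance A²/2, so SDNN² ≈ ΣA²_b/2 + σ² and band powers are predictable in
closed form, which is what makes the spectral-recovery and
SDNN-convergence tests exact. Draws that would produce a non-positive
interval are redrawn, not clipped — clipping would bias the mean.

PPG rendering places, at each beat time, a unit-amplitude Gaussian
systolic peak (σ = 8% of the local interval) plus a 0.3-amplitude dicrotic
bump delayed by 30% of the interval (σ = 12%); any unimodal systolic shape
with a subordinate dicrotic feature suffices for detector validation, and
this one has analytically known apex times (pulse overlap at physiological
rates is below 10⁻⁷ of peak amplitude). A lead-in of one interval is
rendered before the first beat so its rising edge exists. Noise is layered
per `NoiseConfig`: baseline-wander sinusoid, white noise, Poisson motion
spikes, DC offset.

Paired recordings drive an ECG annotation track and the PPG from the same
beat train, the PPG side shifted by a fixed pulse-transit delay (default
0.2 s, irrelevant to intervals). A `desync_fraction` jitters that fraction
of PPG beat times (SD 50 ms, re-drawn to keep ≥0.25 s gaps), mimicking
pathological ECG–PPG desynchronisation; the exact post-perturbation PP
series is returned as ground truth.

**Cohort presets.** The healthy preset (mean PP 829 ms; ULF/VLF/LF/HF
amplitudes 120/140/60/40 ms, jitter 25 ms) targets SDNN ≈ 143 ms and LF
power ≈ 1800 ms²; the syncope-like preset (mean 734 ms; 70/90/40/30 ms,
jitter 15 ms) targets SDNN ≈ 87 ms and LF ≈ 800 ms² — the group means and,
above all, the *direction* of the healthy-vs-syncope contrast (reduced
overall variability and LF power). Cohort sampling draws uniform random
phases per subject and a common N(1, 0.12²) amplitude factor (clipped to
[0.5, 1.5]) for between-subject spread. Four sinusoids cannot reproduce a
real broadband tachogram spectrum simultaneously in every metric: with
SDNN and LF power matched, RMSSD and the VLF/SDANN magnitudes deviate
from typical clinical values. Passing cohort tests therefore demonstrates
that the chain *orders and separates* the groups correctly under known
ground truth, not that it reproduces any particular clinical cohort's
absolute values — which require the original recordings.

A published-scale caveat of the same kind: clinical tables report TINN
values near 3·10⁵ ms, three orders of magnitude above the standard
`M − N` definition's range; this package implements the standard
definition (tens to hundreds of ms) and makes no attempt to
reverse-engineer that scaling.

## Problem sizes and determinism

Validation uses 2-minute records for clean detector accuracy (40–180 bpm),
5-minute records for noise robustness and synchrony, 20-minute records
(the standard minimum for geometric HRV methods) for metric and spectral
checks, and n = 20 + 20 subjects for cohort discrimination — the group
size at which the published healthy/syncope contrasts were reported. All
randomness flows through `numpy.random.default_rng` seeds; every
simulation, test and the acceptance script is reproducible bit-for-bit
from its seed.

## Known limitations

* The prominence threshold is global, not adaptive; strongly amplitude-
  modulated real PPG (e.g. respiration-coupled) needs preprocessing first.
* Peak times are sample-resolution; at 100 Hz this contributes up to
  ±5 ms of quantisation to every interval.
* The generator does not model respiration-coupled amplitude modulation,
  ectopic-beat morphology, or realistic broadband (1/f) interval spectra.
* Geometric metrics need ≥20 min of data to be meaningful; the package
  computes them on shorter records without refusing, leaving the judgement
  to the analyst.
* No beat classification (normal vs ectopic) beyond the running-median NN
  filter; no nonlinear, wavelet or fractal HRV methods.
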
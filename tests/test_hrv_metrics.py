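import math
import warnings

import numpy as np
import pytest

from ppghrv import (
    CohortConfig,
    HEALTHY_PRESET,
    IntervalSeries,
    analyze,
    band_powers,
    generate_interval_series,
    hrv_triangular_index,
    interval_histogram,
    nn_filter,
    poincare,
    time_domain,
    tinn,
)
from ppghrv.hrv_metrics import BIN_MS_DEFAULT, Histogram

from conftest import random_interval_series


# ---------------------------------------------------------------------------
# independent brute-force oracles (defining formulas, plain python)

def oracle_sdnn(iv):
    m = sum(iv) / len(iv)
    return math.sqrt(sum((v - m) ** 2 for v in iv) / (len(iv) - 1))


def oracle_rmssd(iv):
    d = [iv[i + 1] - iv[i] for i in range(len(iv) - 1)]
    return math.sqrt(sum(x * x for x in d) / len(d))


def oracle_segments(series, seg_s=300.0):
    t0 = series.times_s[0] - series.intervals_ms[0] / 1000.0
    rel = [t - t0 for t in series.times_s]
    n_seg = int(rel[-1] // seg_s)
    segs = []
    for k in range(n_seg):
        vals = [v for v, t in zip(series.intervals_ms, rel)
                if k * seg_s < t <= (k + 1) * seg_s]
        if len(vals) >= 2:
            segs.append(vals)
    return segs


def oracle_sdann_sdindex(series, seg_s=300.0):
    segs = oracle_segments(series, seg_s)
    means = [sum(s) / len(s) for s in segs]
    sdann = oracle_sdnn(means) if len(means) >= 2 else None
    sdindex = (sum(oracle_sdnn(s) for s in segs) / len(segs)) if segs else None
    return sdann, sdindex


def oracle_poincare(iv):
    x = iv[:-1]
    y = iv[1:]
    d1 = [(b - a) / math.sqrt(2) for a, b in zip(x, y)]
    d2 = [(b + a) / math.sqrt(2) for a, b in zip(x, y)]
    return oracle_sdnn(d1), oracle_sdnn(d2)


def oracle_tinn(hist):
    """Exhaustive least-squares triangle search, plain loops."""
    counts = list(hist.counts)
    centers = list(hist.centers_ms)
    occupied = [i for i, c in enumerate(counts) if c > 0]
    if len(occupied) == 1:
        return hist.bin_ms
    mode_i = max(range(len(counts)), key=lambda i: counts[i])
    height = counts[mode_i]
    centers = ([centers[0] - hist.bin_ms] + centers
               + [centers[-1] + hist.bin_ms])
    counts = [0.0] + counts + [0.0]
    x_pos = centers[mode_i + 1]
    best_err = None
    best_nm = None
    for n_pos in centers[: mode_i + 1]:
        for m_pos in centers[mode_i + 2:]:
            err = 0.0
            for c, d in zip(centers, counts):
                if n_pos < c <= x_pos:
                    q = height * (c - n_pos) / (x_pos - n_pos)
                elif x_pos < c < m_pos:
                    q = height * (m_pos - c) / (m_pos - x_pos)
                else:
                    q = height if c == x_pos else 0.0
                err += (d - q) ** 2
            if best_err is None or err < best_err * (1 - 1e-9):
                better = True
            elif err <= best_err * (1 + 1e-9):
                # errors tied at float precision: narrower, then leftmost
                better = (m_pos - n_pos, n_pos) < (best_nm[1] - best_nm[0],
                                                   best_nm[0])
            else:
                better = False
            if better:
                best_err = err if best_err is None else min(err, best_err)
                best_nm = (n_pos, m_pos)
    return best_nm[1] - best_nm[0]


# ---------------------------------------------------------------------------


class TestNNFilter:
    def test_clean_series_unchanged(self):
        s = random_interval_series(1)
        out = nn_filter(s, 0.5)
        assert len(out) == len(s)
        assert out.kind == "NN"

    def test_running_median_rejects_ectopic_interval(self):
        s = IntervalSeries.from_intervals([800.0] * 5 + [1600.0] + [800.0] * 5)
        out = nn_filter(s, 0.2)
        assert len(out) == 10
        assert np.all(out.intervals_ms == 800.0)

    def test_max_dev_one_keeps_everything(self):
        s = IntervalSeries.from_intervals([500, 900, 700, 1000, 600])
        assert len(nn_filter(s, 1.0)) == 5

    def test_first_interval_seeds_the_running_median(self):
        # the first interval is always accepted; later outliers are judged
        # against the median of what has been accepted so far
        s = IntervalSeries.from_intervals([800.0, 1600.0, 810.0])
        out = nn_filter(s, 0.02)
        assert out.intervals_ms.tolist() == [800.0, 810.0]

    def test_invalid_threshold(self):
        s = IntervalSeries.from_intervals([800.0, 820.0])
        with pytest.raises(ValueError):
            nn_filter(s, 0.0)


class TestTimeDomain:
    def test_constant_series_all_zero(self):
        s = IntervalSeries.from_intervals([800.0] * 800)
        td = time_domain(s)
        assert td.sdnn_ms == 0 and td.rmssd_ms == 0
        assert td.sdann_ms == 0 and td.sdindex_ms == 0

    def test_small_series_matches_direct_formulas(self):
        iv = [800.0, 810.0, 790.0, 805.0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            td = time_domain(IntervalSeries.from_intervals(iv))
        assert td.sdnn_ms == pytest.approx(oracle_sdnn(iv), rel=1e-12)
        assert td.rmssd_ms == pytest.approx(oracle_rmssd(iv), rel=1e-12)

    def test_alternating_series_rmssd_exact(self):
        s = IntervalSeries.from_intervals([750.0, 850.0] * 400)
        td = time_domain(s)
        assert td.rmssd_ms == pytest.approx(100.0)

    def test_short_record_lacks_segment_metrics(self):
        s = IntervalSeries.from_intervals([900.0] * 100)  # 90 s
        with pytest.warns(UserWarning):
            td = time_domain(s)
        assert td.sdann_ms is None and td.sdindex_ms is None

    def test_too_few_intervals(self):
        with pytest.raises(ValueError):
            time_domain(IntervalSeries.from_intervals([800.0]))


class TestHistogram:
    def test_single_bin(self):
        s = IntervalSeries.from_intervals([800.0] * 25)
        h = interval_histogram(s)
        assert (h.counts > 0).sum() == 1
        assert h.counts.sum() == 25

    def test_counts_conserved(self):
        s = random_interval_series(3)
        h = interval_histogram(s)
        assert h.counts.sum() == len(s)

    def test_edge_value_goes_to_upper_bin(self):
        b = BIN_MS_DEFAULT
        s = IntervalSeries.from_intervals([100 * b, 100 * b + b / 2, 101 * b])
        h = interval_histogram(s)
        assert h.counts.tolist() == [2, 1]
        assert h.centers_ms[0] == pytest.approx(100.5 * b)


class TestGeometric:
    def test_hrvti_identical_series_is_one(self):
        s = IntervalSeries.from_intervals([812.0] * 40)
        assert hrv_triangular_index(interval_histogram(s)) == 1.0

    def test_hrvti_uniform_over_k_bins(self):
        b = BIN_MS_DEFAULT
        iv = [(100 + k) * b + b / 2 for k in range(5)] * 8
        h = interval_histogram(IntervalSeries.from_intervals(iv))
        assert hrv_triangular_index(h) == pytest.approx(5.0)

    def test_triangular_histogram_recovers_base_width(self):
        b = BIN_MS_DEFAULT
        counts = np.array([1, 2, 3, 4, 3, 2, 1])
        centers = (np.arange(100, 107) + 0.5) * b
        h = Histogram(centers_ms=centers, counts=counts, bin_ms=b)
        # ideal triangle spans one bin beyond each occupied end
        assert tinn(h) == pytest.approx(8 * b, abs=b)

    def test_single_bin_histogram_degenerates_to_bin_width(self):
        h = interval_histogram(IntervalSeries.from_intervals([812.0] * 10))
        assert tinn(h) == BIN_MS_DEFAULT

    def test_poincare_constant_series(self):
        s = IntervalSeries.from_intervals([800.0] * 10)
        sd1, sd2, cloud = poincare(s)
        assert sd1 == 0 and sd2 == 0
        assert cloud.shape == (9, 2)

    def test_poincare_rotation_identity(self):
        s = random_interval_series(4)
        sd1, sd2, cloud = poincare(s)
        x, y = cloud[:, 0], cloud[:, 1]
        assert sd1 ** 2 + sd2 ** 2 == pytest.approx(
            np.var(x, ddof=1) + np.var(y, ddof=1), rel=1e-9)
        assert sd2 ** 2 - sd1 ** 2 == pytest.approx(
            2 * np.cov(x, y, ddof=1)[0, 1], rel=1e-9)

    def test_poincare_alternating_series(self):
        d = 50.0
        s = IntervalSeries.from_intervals([800 - d, 800 + d] * 50)
        sd1, sd2, _ = poincare(s)
        assert sd1 == pytest.approx(np.sqrt(2) * d, rel=0.01)
        assert sd2 == pytest.approx(0.0, abs=1.0)

    def test_poincare_needs_three_intervals(self):
        with pytest.raises(ValueError):
            poincare(IntervalSeries.from_intervals([800.0, 820.0]))


@pytest.mark.parametrize("seed", range(100))
def test_metrics_match_brute_force_oracles(seed):
    """Closed-form metrics agree with direct implementations of their
    defining formulas on random series; TINN agrees with an independent
    exhaustive search."""
    series = random_interval_series(seed, n=500)
    iv = list(series.intervals_ms)
    td = time_domain(series)
    assert td.sdnn_ms == pytest.approx(oracle_sdnn(iv), rel=1e-9)
    assert td.rmssd_ms == pytest.approx(oracle_rmssd(iv), rel=1e-9)
    sdann_o, sdindex_o = oracle_sdann_sdindex(series)
    if sdann_o is None:
        assert td.sdann_ms is None
    else:
        assert td.sdann_ms == pytest.approx(sdann_o, rel=1e-9)
    assert td.sdindex_ms == pytest.approx(sdindex_o, rel=1e-9)
    sd1, sd2, _ = poincare(series)
    sd1_o, sd2_o = oracle_poincare(iv)
    assert sd1 == pytest.approx(sd1_o, rel=1e-9)
    assert sd2 == pytest.approx(sd2_o, rel=1e-9)
    h = interval_histogram(series)
    assert hrv_triangular_index(h) == len(iv) / h.counts.max()
    assert tinn(h) == pytest.approx(oracle_tinn(h), rel=1e-12)


class TestSpectral:
    def test_constant_series_has_negligible_power(self):
        s = IntervalSeries.from_intervals([800.0] * 800)
        sm = band_powers(s)
        for p in (sm.power_vlf_ms2, sm.power_lf_ms2, sm.power_hf_ms2):
            assert p < 1e-6
        assert sm.lf_hf_ratio is None

    def test_lf_tone_power_recovery(self, lf_only_config):
        s = generate_interval_series(lf_only_config)
        sm = band_powers(s)
        lf_hf = sm.power_lf_ms2 + sm.power_hf_ms2
        assert sm.power_lf_ms2 / lf_hf >= 0.9
        assert lf_hf == pytest.approx(50 ** 2 / 2, rel=0.25)

    def test_lombscargle_agrees_on_tone_power(self, lf_only_config):
        s = generate_interval_series(lf_only_config)
        sm = band_powers(s, method="lombscargle")
        assert sm.power_lf_ms2 == pytest.approx(50 ** 2 / 2, rel=0.25)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_percent_powers_sum_to_100(self, seed):
        cfg = CohortConfig(mean_rr_ms=850, duration_s=400, ulf_amp_ms=0,
                           vlf_amp_ms=20, lf_amp_ms=30, hf_amp_ms=25,
                           noise_sd_ms=15, seed=seed)
        sm = band_powers(generate_interval_series(cfg))
        assert sm.pct_vlf + sm.pct_lf + sm.pct_hf == pytest.approx(100.0, abs=0.01)
        assert sm.lf_hf_ratio == pytest.approx(
            sm.power_lf_ms2 / sm.power_hf_ms2)

    def test_band_powers_additive_over_disjoint_bands(self):
        s = random_interval_series(9, n=600)
        sm = band_powers(s)
        merged = band_powers(s, bands={"vlf": (0.0033, 0.04),
                                       "lf": (0.04, 0.4), "hf": (0.4, 0.5)})
        assert merged.power_lf_ms2 == pytest.approx(
            sm.power_lf_ms2 + sm.power_hf_ms2, rel=1e-9)

    def test_short_record_rejected(self):
        s = IntervalSeries.from_intervals([800.0] * 50)  # 40 s
        with pytest.raises(ValueError, match="too short"):
            band_powers(s)

    def test_sub_vlf_duration_warns(self):
        s = random_interval_series(2, n=200)  # ~160 s
        with pytest.warns(UserWarning, match="VLF"):
            sm = band_powers(s)
        assert not sm.vlf_reliable


class TestAnalyze:
    def test_full_report_on_healthy_preset(self):
        s = generate_interval_series(HEALTHY_PRESET.replace(seed=6))
        rep = analyze(s, record_id="h1")
        assert rep.time is not None and rep.geometric is not None
        assert rep.spectral is not None
        assert rep.time.sdann_ms is not None
        assert rep.meta["n_intervals"] == len(s)

    def test_short_record_reports_partial_metrics(self):
        s = IntervalSeries.from_intervals([900.0] * 100)  # 90 s
        rep = analyze(s)
        assert rep.time is not None and rep.time.sdann_ms is None
        assert rep.spectral is None
        assert any("spectral" in w for w in rep.meta["warnings"])

    def test_deterministic_on_fixed_input(self):
        s = random_interval_series(11, n=400)
        a = analyze(s)
        b = analyze(s)
        assert a.time == b.time
        assert a.spectral == b.spectral
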
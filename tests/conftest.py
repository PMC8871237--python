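import numpy as np
import pytest

from ppghrv import CohortConfig, IntervalSeries, generate_interval_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_interval_series(seed: int, n: int = 250) -> IntervalSeries:
    """A positive, irregular interval series for oracle comparisons."""
    r = np.random.default_rng(seed)
    iv = 800.0 + 60.0 * r.standard_normal(n) + 30.0 * np.sin(np.arange(n) / 7.0)
    iv = np.clip(iv, 300.0, None)
    return IntervalSeries.from_intervals(iv)


@pytest.fixture
def lf_only_config():
    """Pure 0.1 Hz, 50 ms interval modulation around 1000 ms, 20 minutes."""
    return CohortConfig(
        mean_rr_ms=1000.0,
        duration_s=1200.0,
        ulf_amp_ms=0.0,
        vlf_amp_ms=0.0,
        lf_amp_ms=50.0,
        lf_freq_hz=0.1,
        hf_amp_ms=0.0,
        noise_sd_ms=0.0,
        seed=1,
    )
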
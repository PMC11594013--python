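import numpy as np
import pytest

from convdry import MRSeries, MoistureSeries, evaluate_model


@pytest.fixture
def decreasing_series() -> MoistureSeries:
    """A plain monotone drying series on a 30-min grid."""
    times = np.arange(0.0, 301.0, 30.0)
    moisture = 4.0 * np.exp(-times / 120.0) + 0.05
    return MoistureSeries(times=times, moisture=moisture, temperature_C=60.0)


def make_page_mr(k: float, n: float, temperature_C: float = 70.0,
                 t_end_min: float = 210.0, step_min: float = 30.0,
                 noise_sd: float = 0.0, seed: int = 0) -> MRSeries:
    """Moisture-ratio series generated by the Page curve (k per hour)."""
    times = np.arange(0.0, t_end_min + 1e-9, step_min)
    mr = evaluate_model("page", {"k": k, "n": n}, times / 60.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mr = np.clip(mr + rng.normal(0.0, noise_sd, mr.shape), 0.0, None)
    return MRSeries(times=times, mr=mr, temperature_C=temperature_C)
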
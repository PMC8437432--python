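import numpy as np
import pytest

from ahba1c import GlucoseTrace, SimulationConfig


def make_constant_trace(
    glucose: float = 150.0, days: int = 182, per_day: int = 96
) -> GlucoseTrace:
    """A trace with every reading equal to ``glucose`` (15-min cadence)."""
    n = days * per_day
    times = (np.arange(n) + 0.5) / per_day
    return GlucoseTrace(times, np.full(n, glucose))


def make_daily_trace(daily_means, per_day: int = 96) -> GlucoseTrace:
    """A trace whose readings are constant within each day at the given
    daily means — its daily aggregation is exactly ``daily_means``."""
    daily_means = np.asarray(daily_means, dtype=float)
    n = daily_means.size * per_day
    times = (np.arange(n) + 0.5) / per_day
    return GlucoseTrace(times, np.repeat(daily_means, per_day))


@pytest.fixture
def constant_trace() -> GlucoseTrace:
    return make_constant_trace()


@pytest.fixture
def small_noiseless_config() -> SimulationConfig:
    """Three-subject cohort with every noise source off."""
    return SimulationConfig(
        n_subjects=3, seed=7, sensor_noise_sd=0.0, assay_noise_ngsp=0.0
    )
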
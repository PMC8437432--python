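"""Synthetic CGM cohorts with known red-cell kinetics.

The study design being emulated: six months of flash-monitor glucose
readings (one every 15 minutes) per subject, with laboratory HbA1c drawn at
enrolment, three months and six months.  Each synthetic subject carries a
known ground truth — red-cell lifespan, apparent glycation constant, the
noiseless model trajectory — so estimation and adjustment can be validated
end to end without clinical data.

Glucose is built in two layers.  Between days, the daily mean follows a
stationary AR(1) process around a subject-specific baseline; its stationary
standard deviation is the "between-day variability" knob the estimator's
identifiability depends on (set it to zero to exercise the
non-identifiability gate).  Within days, a circadian sinusoid, three
post-meal excursions with log-normal amplitudes and i.i.d. sensor noise are
added; these components are centred within each day so the configured daily
mean is preserved.  Not simulated: sensor bias or drift, calibration error,
hypoglycaemia dynamics, or any glucose dependence of red-cell removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError
from .kinetics import (
    GlucoseTrace,
    HbA1cTrajectory,
    KineticParameters,
    simulate_hba1c,
    steady_state_hba1c,
)
from .estimation import HbA1cMeasurement
from .units import HbA1cValue

__all__ = [
    "SimulationConfig",
    "GapSpec",
    "SyntheticSubject",
    "generate_subject",
    "generate_cohort",
    "inject_gaps",
]


@dataclass(frozen=True)
class GapSpec:
    """Sensor-wear gaps to inject: ``n_gaps`` windows with lengths drawn
    uniformly from ``length_days_range``, placed uniformly over the trace.
    Overlapping windows are unioned."""

    n_gaps: int = 0
    length_days_range: tuple[float, float] = (1.0, 3.0)
    windows: tuple[tuple[float, float], ...] = ()  # explicit (start, length)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort generator settings.

    Defaults mirror a six-month flash-monitoring study: 182 days of
    readings every 15 minutes, laboratory HbA1c at days 0/91/182, red-cell
    lifespans uniform on 60–150 days (inside the 50–180 day fitting range),
    and glycation constants drawn so steady-state HbA1c spans roughly
    6–11% NGSP — a treated-diabetes population.  The daily-mean glucose
    process is AR(1) with coefficient 0.7 and stationary SD 20 mg/dL around
    a baseline near 154 mg/dL (the steady state of ~7% HbA1c at reference
    kinetics).
    """

    n_subjects: int = 10
    study_days: int = 182
    cadence_minutes: float = 15.0
    visit_days: tuple[float, ...] = (0.0, 91.0, 182.0)
    lifespan_range_days: tuple[float, float] = (60.0, 150.0)
    steady_state_hba1c_range: tuple[float, float] = (0.06, 0.11)
    baseline_glucose_mean: float = 154.0
    baseline_glucose_sd: float = 25.0
    ar_coefficient: float = 0.7
    daily_sd: float = 20.0  # stationary SD of the daily-mean process, mg/dL
    circadian_amplitude: float = 10.0
    meal_hours: tuple[float, ...] = (8.0, 13.0, 19.0)
    meal_amplitude_median: float = 40.0
    meal_amplitude_sigma: float = 0.4  # log-normal shape
    meal_width_hours: float = 1.0
    sensor_noise_sd: float = 5.0
    assay_noise_ngsp: float = 0.1  # laboratory HbA1c noise, NGSP points
    gap_spec: GapSpec = field(default_factory=GapSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise InputError("cohort must contain at least one subject")
        if self.study_days <= 0 or self.cadence_minutes <= 0:
            raise InputError("study length and cadence must be positive")
        if 1440.0 % self.cadence_minutes != 0:
            raise InputError("cadence must divide a day evenly")
        if any(v < 0 or v > self.study_days for v in self.visit_days):
            raise InputError("visit days must lie within the study length")
        if min(self.daily_sd, self.sensor_noise_sd, self.assay_noise_ngsp) < 0:
            raise InputError("noise SDs must be non-negative")
        if not 0 <= self.ar_coefficient < 1:
            raise InputError("AR coefficient must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticSubject:
    """One simulated subject with full ground truth attached."""

    subject_id: str
    params: KineticParameters
    baseline_glucose: float
    trace: GlucoseTrace
    measurements: list[HbA1cMeasurement]  # with assay noise
    noiseless_measurements: list[HbA1cMeasurement]
    trajectory: HbA1cTrajectory  # noiseless model trajectory, daily grid

    @property
    def true_lifespan_days(self) -> float:
        return self.params.lifespan_days


def _daily_means(rng: np.random.Generator, config: SimulationConfig, baseline: float) -> np.ndarray:
    n = config.study_days
    phi = config.ar_coefficient
    x = np.empty(n)
    x[0] = rng.normal(0.0, config.daily_sd)
    innov_sd = config.daily_sd * math.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=n - 1) if n > 1 else np.empty(0)
    for d in range(1, n):
        x[d] = phi * x[d - 1] + eps[d - 1]
    return np.clip(baseline + x, 40.0, None)


def _within_day_pattern(rng: np.random.Generator, config: SimulationConfig, hours: np.ndarray) -> np.ndarray:
    """Circadian + meal excursions for one day, centred to zero mean."""
    signal = config.circadian_amplitude * np.sin(2.0 * math.pi * (hours - 16.0) / 24.0)
    for meal_h in config.meal_hours:
        amp = config.meal_amplitude_median * math.exp(
            rng.normal(0.0, config.meal_amplitude_sigma)
        )
        # post-meal excursion: gaussian bump peaking ~1h after the meal
        signal += amp * np.exp(-0.5 * ((hours - meal_h - 1.0) / config.meal_width_hours) ** 2)
    return signal - signal.mean()


def generate_subject(
    config: SimulationConfig, subject_index: int, seed: int | None = None
) -> SyntheticSubject:
    """Simulate one subject; reproducible from (config, subject_index, seed)."""
    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence((base_seed, subject_index)))

    lo, hi = config.lifespan_range_days
    lifespan = rng.uniform(lo, hi)
    k_age = 1.0 / lifespan
    baseline = max(80.0, rng.normal(config.baseline_glucose_mean, config.baseline_glucose_sd))
    a_lo, a_hi = config.steady_state_hba1c_range
    a_target = rng.uniform(a_lo, a_hi)
    K = a_target * k_age / (baseline * (1.0 - a_target))
    params = KineticParameters(K=K, k_age=k_age)

    means = _daily_means(rng, config, baseline)

    per_day = int(round(1440.0 / config.cadence_minutes))
    hours = (np.arange(per_day) + 0.5) * (24.0 / per_day)
    readings = np.empty(config.study_days * per_day)
    for d in range(config.study_days):
        pattern = _within_day_pattern(rng, config, hours)
        noise = (
            rng.normal(0.0, config.sensor_noise_sd, size=per_day)
            if config.sensor_noise_sd > 0
            else 0.0
        )
        readings[d * per_day : (d + 1) * per_day] = means[d] + pattern + noise
    np.clip(readings, 20.0, None, out=readings)
    times = (np.arange(readings.size) + 0.5) * (config.cadence_minutes / 1440.0)
    trace = GlucoseTrace(times, readings)
    if config.gap_spec.n_gaps > 0 or config.gap_spec.windows:
        trace = inject_gaps(trace, config.gap_spec, seed=int(rng.integers(2**31)))

    a0 = steady_state_hba1c(params.K, float(means[0]), params.k_age)
    trajectory = simulate_hba1c(trace, params, a0, start_time=0.0, end_time=config.study_days)

    noiseless = [
        HbA1cMeasurement(v, trajectory.at(v), source="model") for v in config.visit_days
    ]
    assay_sd = config.assay_noise_ngsp / 100.0
    noisy = [
        HbA1cMeasurement(
            m.time,
            HbA1cValue(float(np.clip(m.value.fraction + rng.normal(0.0, assay_sd), 1e-4, 0.999)))
            if assay_sd > 0
            else m.value,
            source="laboratory",
        )
        for m in noiseless
    ]
    return SyntheticSubject(
        subject_id=f"S{subject_index:04d}",
        params=params,
        baseline_glucose=baseline,
        trace=trace,
        measurements=noisy,
        noiseless_measurements=noiseless,
        trajectory=trajectory,
    )


def generate_cohort(config: SimulationConfig) -> list[SyntheticSubject]:
    """Simulate ``config.n_subjects`` independent subjects (deterministic
    for a fixed config and seed)."""
    return [generate_subject(config, i) for i in range(config.n_subjects)]


def inject_gaps(trace: GlucoseTrace, gap_spec: GapSpec, seed: int = 0) -> GlucoseTrace:
    """Mark sensor-wear gaps invalid.  Explicit windows are applied as
    given; random gaps are placed uniformly.  Overlaps union naturally."""
    windows = list(gap_spec.windows)
    if gap_spec.n_gaps > 0:
        rng = np.random.default_rng(seed)
        span = trace.end_time - trace.start_time
        lo, hi = gap_spec.length_days_range
        for _ in range(gap_spec.n_gaps):
            length = rng.uniform(lo, hi)
            if length >= span:
                raise InputError("gap longer than the trace span")
            start = trace.start_time + rng.uniform(0.0, span - length)
            windows.append((start, length))
    if not windows:
        return trace
    valid = trace.valid.copy()
    for start, length in windows:
        valid &= ~((trace.times >= start) & (trace.times < start + length))
    return GlucoseTrace(trace.times, trace.glucose, valid)
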
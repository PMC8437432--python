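"""Forward kinetic model of hemoglobin glycation driven by a CGM trace.

The glycated fraction ``A(t)`` of the hemoglobin pool obeys a first-order
balance between glycation of the non-glycated pool and removal of glycated
hemoglobin by red-cell turnover::

    dA/dt = K * g(t) * (1 - A) - k_age * A

where ``g(t)`` is extracellular glucose (mg/dL), ``K`` is the apparent
glycation constant (per day per mg/dL; the lumped product of the glycation
rate constant and the cell's glucose-uptake scaling) and ``k_age`` is the
red-cell turnover rate (per day).  At constant glucose the model settles to

    A_ss = K*g / (K*g + k_age)

which is the algebraic backbone of the turnover adjustment in
:mod:`ahba1c.adjustment`.

Because HbA1c dynamics play out over weeks, the default integration scheme
aggregates CGM readings to daily mean glucose and advances ``A`` with the
exact one-day solution of the (piecewise-constant-forcing) linear ODE, which
is unconditionally stable and keeps ``A`` inside (0, 1) for positive inputs.
A per-reading scheme is available for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EligibilityError, InputError, NumericalError
from .units import HbA1cValue

__all__ = [
    "GlucoseTrace",
    "KineticParameters",
    "HbA1cTrajectory",
    "DailyForcing",
    "daily_forcing",
    "simulate_hba1c",
    "steady_state_hba1c",
    "cgm_estimated_hba1c",
]

#: CGM cadence assumed when a trace is too short to infer one (minutes).
DEFAULT_CADENCE_MINUTES = 15.0

#: A day contributes a daily mean only if at least this fraction of its
#: expected readings are present and valid.
MIN_DAILY_FRACTION = 0.5

#: Runs of missing days up to this length are bridged by linear
#: interpolation of daily mean glucose; longer runs make the stretch
#: ineligible for simulation.
MAX_BRIDGE_DAYS = 2


@dataclass(frozen=True)
class GlucoseTrace:
    """Timestamped extracellular glucose series for one subject.

    ``times`` are days since the subject's first record (strictly
    increasing); ``glucose`` is mg/dL; ``valid`` flags readings usable for
    analysis (sensor errors and the like are carried but masked out).
    """

    times: np.ndarray
    glucose: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        glucose = np.asarray(self.glucose, dtype=float)
        valid = (
            np.ones(times.shape, dtype=bool)
            if self.valid is None
            else np.asarray(self.valid, dtype=bool)
        )
        if times.ndim != 1 or times.size == 0:
            raise InputError("glucose trace must be a non-empty 1-D series")
        if times.shape != glucose.shape or times.shape != valid.shape:
            raise InputError("times, glucose and valid must have equal length")
        if np.any(np.diff(times) <= 0):
            raise InputError("trace times must be strictly increasing")
        if not np.all(np.isfinite(glucose[valid])) or np.any(glucose[valid] <= 0):
            raise InputError("valid glucose readings must be positive and finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "glucose", glucose)
        object.__setattr__(self, "valid", valid)

    def __len__(self) -> int:
        return self.times.size

    @property
    def start_time(self) -> float:
        return float(self.times[0])

    @property
    def end_time(self) -> float:
        return float(self.times[-1])

    def cadence_minutes(self) -> float:
        """Median spacing between consecutive readings, in minutes."""
        if len(self) < 2:
            return DEFAULT_CADENCE_MINUTES
        return float(np.median(np.diff(self.times)) * 1440.0)

    def gaps(self, threshold_days: float) -> list[tuple[float, float]]:
        """Intervals between consecutive *valid* readings longer than
        ``threshold_days``, as (start, end) pairs in days."""
        t = self.times[self.valid]
        if t.size < 2:
            return []
        dt = np.diff(t)
        idx = np.nonzero(dt > threshold_days)[0]
        return [(float(t[i]), float(t[i + 1])) for i in idx]

    def slice(self, start: float, end: float) -> "GlucoseTrace":
        """Readings with ``start <= time <= end`` (empty slice is an error)."""
        mask = (self.times >= start) & (self.times <= end)
        if not np.any(mask):
            raise InputError(f"no readings in [{start}, {end}]")
        return GlucoseTrace(self.times[mask], self.glucose[mask], self.valid[mask])


@dataclass(frozen=True)
class KineticParameters:
    """Per-subject kinetics: apparent glycation constant and turnover rate."""

    K: float  # per day per (mg/dL)
    k_age: float  # per day

    def __post_init__(self) -> None:
        if not (self.K > 0 and math.isfinite(self.K)):
            raise InputError(f"K must be positive and finite, got {self.K!r}")
        if not (self.k_age > 0 and math.isfinite(self.k_age)):
            raise InputError(f"k_age must be positive and finite, got {self.k_age!r}")

    @property
    def lifespan_days(self) -> float:
        return 1.0 / self.k_age


@dataclass(frozen=True)
class HbA1cTrajectory:
    """Model glycated fraction A(t) sampled on a time grid (days)."""

    times: np.ndarray
    fraction: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        fraction = np.asarray(self.fraction, dtype=float)
        if times.shape != fraction.shape or times.ndim != 1:
            raise InputError("trajectory times and fractions must align")
        if np.any((fraction <= 0) | (fraction >= 1)):
            raise NumericalError("trajectory left the (0, 1) interval")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fraction", fraction)

    def at(self, time: float) -> HbA1cValue:
        """Linearly interpolated fraction at ``time`` (days)."""
        if time < self.times[0] or time > self.times[-1]:
            raise EligibilityError(
                f"time {time} outside simulated span "
                f"[{self.times[0]}, {self.times[-1]}]"
            )
        return HbA1cValue(float(np.interp(time, self.times, self.fraction)))


@dataclass(frozen=True)
class DailyForcing:
    """Daily mean glucose prepared for integration over [start_day, end_day].

    ``glucose[i]`` drives the model over day ``start_day + i``.  ``observed``
    marks days whose mean came from actual readings (as opposed to gap
    bridging); ``max_gap_days`` is the longest run of unobserved days.
    """

    start_day: int
    glucose: np.ndarray
    observed: np.ndarray
    max_gap_days: int

    @property
    def n_days(self) -> int:
        return self.glucose.size

    @property
    def coverage(self) -> float:
        """Fraction of days with an observed (not bridged) daily mean."""
        return float(np.mean(self.observed)) if self.n_days else 0.0

    @property
    def n_observed(self) -> int:
        return int(np.sum(self.observed))

    def variability(self) -> float:
        """Population SD of the observed daily means, mg/dL."""
        obs = self.glucose[self.observed]
        if obs.size < 2:
            raise EligibilityError("variability needs at least 2 observed days")
        return float(np.std(obs))


def daily_forcing(
    trace: GlucoseTrace,
    start_day: int | None = None,
    end_day: int | None = None,
    *,
    min_daily_fraction: float = MIN_DAILY_FRACTION,
    bridge: bool = True,
) -> DailyForcing:
    """Aggregate a trace to daily mean glucose over ``[start_day, end_day)``.

    A calendar day (unit interval of the trace's day axis) yields a mean
    when at least ``min_daily_fraction`` of its expected readings (from the
    trace cadence) are present and valid.  When ``bridge`` is true, missing
    days are filled by linear interpolation between neighbouring observed
    means (edges extended flat); the fill is recorded in ``observed`` so
    eligibility gates can still see the gaps.
    """
    if start_day is None:
        start_day = int(math.floor(trace.start_time))
    if end_day is None:
        end_day = int(math.ceil(trace.end_time))
    if end_day <= start_day:
        raise InputError(f"empty day range [{start_day}, {end_day})")

    n_days = end_day - start_day
    expected_per_day = max(1.0, 1440.0 / trace.cadence_minutes())

    t = trace.times[trace.valid]
    g = trace.glucose[trace.valid]
    day_idx = np.floor(t).astype(int) - start_day
    in_range = (day_idx >= 0) & (day_idx < n_days)
    day_idx, g = day_idx[in_range], g[in_range]

    counts = np.bincount(day_idx, minlength=n_days)
    sums = np.bincount(day_idx, weights=g, minlength=n_days)
    observed = counts >= min_daily_fraction * expected_per_day
    means = np.full(n_days, np.nan)
    means[observed] = sums[observed] / counts[observed]

    max_gap = _longest_false_run(observed)
    if bridge and not np.all(observed):
        if not np.any(observed):
            raise EligibilityError("no day in range has sufficient CGM readings")
        obs_idx = np.nonzero(observed)[0]
        means = np.interp(np.arange(n_days), obs_idx, means[obs_idx])

    return DailyForcing(start_day, means, observed, max_gap)


def _longest_false_run(mask: np.ndarray) -> int:
    longest = run = 0
    for ok in mask:
        run = 0 if ok else run + 1
        longest = max(longest, run)
    return longest


def steady_state_hba1c(K: float, glucose: float, k_age: float) -> HbA1cValue:
    """Fixed point of the glycation ODE at constant glucose:
    ``A_ss = K*g / (K*g + k_age)``."""
    if K <= 0 or glucose <= 0 or k_age <= 0:
        raise InputError("K, glucose and k_age must all be positive")
    drive = K * glucose
    return HbA1cValue(drive / (drive + k_age))


def _propagate(a0: float, glucose_days: np.ndarray, K: float, k_age: float) -> np.ndarray:
    """Exact piecewise-constant-forcing solution on a daily grid.

    Returns A at the ``n+1`` day boundaries given ``n`` daily means.  The
    one-day update is ``A_{d+1} = ss_d + (A_d - ss_d) * exp(-(K*g_d + k_age))``,
    unrolled in closed form with cumulative products so the fit objective is
    loop-free.
    """
    drive = K * glucose_days
    rate = drive + k_age
    ss = drive / rate
    f = np.exp(-rate)
    # A_n = P_n * (a0 + sum_{d<n} ss_d*(1-f_d)/P_{d+1}),  P_n = prod_{d<n} f_d
    log_p = np.concatenate(([0.0], np.cumsum(np.log(f))))
    p = np.exp(log_p)
    incr = np.concatenate(([0.0], np.cumsum(ss * (1.0 - f) / p[1:])))
    out = p * (a0 + incr)
    if not np.all(np.isfinite(out)):
        bad = int(np.nonzero(~np.isfinite(out))[0][0])
        raise NumericalError(f"integration produced a non-finite value at day step {bad}")
    return out


def _propagate_per_reading(
    a0: float, times: np.ndarray, glucose: np.ndarray, K: float, k_age: float
) -> np.ndarray:
    """Per-reading variant: glucose held at the left reading of each interval."""
    dt = np.diff(times)
    drive = K * glucose[:-1]
    rate = drive + k_age
    ss = drive / rate
    f = np.exp(-rate * dt)
    log_p = np.concatenate(([0.0], np.cumsum(np.log(f))))
    p = np.exp(log_p)
    incr = np.concatenate(([0.0], np.cumsum(ss * (1.0 - f) / p[1:])))
    out = p * (a0 + incr)
    if not np.all(np.isfinite(out)):
        bad = int(np.nonzero(~np.isfinite(out))[0][0])
        raise NumericalError(f"integration produced a non-finite value at step {bad}")
    return out


def simulate_hba1c(
    trace: GlucoseTrace,
    params: KineticParameters,
    initial_fraction: HbA1cValue,
    *,
    start_time: float | None = None,
    end_time: float | None = None,
    scheme: str = "daily",
    min_daily_fraction: float = MIN_DAILY_FRACTION,
) -> HbA1cTrajectory:
    """Evolve the glycated fraction along a glucose trace.

    With the default ``scheme="daily"`` the trajectory is reported at whole
    day boundaries; ``scheme="per_reading"`` integrates interval by interval
    on the raw reading grid.
    """
    if len(trace) == 0:
        raise InputError("cannot simulate on an empty trace")
    if scheme == "daily":
        start_day = int(math.floor(trace.start_time if start_time is None else start_time))
        end_day = int(math.ceil(trace.end_time if end_time is None else end_time))
        forcing = daily_forcing(
            trace, start_day, end_day, min_daily_fraction=min_daily_fraction
        )
        a = _propagate(initial_fraction.fraction, forcing.glucose, params.K, params.k_age)
        times = start_day + np.arange(forcing.n_days + 1, dtype=float)
    elif scheme == "per_reading":
        mask = trace.valid.copy()
        if start_time is not None:
            mask &= trace.times >= start_time
        if end_time is not None:
            mask &= trace.times <= end_time
        times = trace.times[mask]
        glucose = trace.glucose[mask]
        if times.size < 2:
            raise InputError("per-reading simulation needs at least 2 valid readings")
        a = _propagate_per_reading(
            initial_fraction.fraction, times, glucose, params.K, params.k_age
        )
    else:
        raise InputError(f"unknown integration scheme {scheme!r}")
    return HbA1cTrajectory(times, a)


def cgm_estimated_hba1c(
    trace: GlucoseTrace,
    params: KineticParameters,
    at_time: float,
    *,
    initialization: str = "anchor",
    anchor_time: float | None = None,
    anchor_value: HbA1cValue | None = None,
    min_history_lifespans: float = 5.0,
    scheme: str = "daily",
) -> HbA1cValue:
    """CGM-derived estimate of HbA1c at ``at_time`` (days).

    ``initialization="anchor"`` starts the model at a laboratory HbA1c
    (``anchor_time``/``anchor_value``) and integrates forward — this is the
    form the parameter fit aligns with the next laboratory value.
    ``initialization="steady_state"`` warms up from the steady state of the
    first daily mean; it requires at least ``min_history_lifespans`` red-cell
    lifespans of preceding CGM history so the start transient has decayed.
    """
    if at_time < trace.start_time or at_time > trace.end_time:
        raise EligibilityError(
            f"query time {at_time} outside trace span "
            f"[{trace.start_time}, {trace.end_time}]"
        )
    if initialization == "anchor":
        if anchor_time is None or anchor_value is None:
            raise InputError("anchor initialization requires anchor_time and anchor_value")
        if anchor_time > at_time:
            raise InputError("anchor_time must not be after at_time")
        if anchor_time == at_time:
            return anchor_value
        a0 = anchor_value
        t0 = anchor_time
    elif initialization == "steady_state":
        history = at_time - trace.start_time
        needed = min_history_lifespans * params.lifespan_days
        if history < needed:
            raise EligibilityError(
                f"steady-state warm-up needs {needed:.0f} days of history, "
                f"trace provides {history:.0f}"
            )
        first_day = daily_forcing(
            trace, int(math.floor(trace.start_time)), int(math.floor(trace.start_time)) + 1
        )
        a0 = steady_state_hba1c(params.K, float(first_day.glucose[0]), params.k_age)
        t0 = trace.start_time
    else:
        raise InputError(f"unknown initialization policy {initialization!r}")
    traj = simulate_hba1c(
        trace, params, a0, start_time=t0, end_time=at_time, scheme=scheme
    )
    return traj.at(min(at_time, float(traj.times[-1])))
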
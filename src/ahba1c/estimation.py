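"""Per-subject estimation of red-cell turnover and glycation constant.

The estimation unit is the *data section*: two laboratory HbA1c
measurements connected by CGM readings.  The kinetic model is anchored at
the section's first laboratory value, driven forward by daily mean glucose,
and the pair (``k_age``, ``K``) is chosen so the simulated glycated
fraction at the section's end matches the second laboratory value.  All of
a subject's eligible sections are fitted jointly with shared parameters.

Identifiability hinges on between-day glucose variability: with perfectly
constant glucose only the steady-state ratio ``K*g/(K*g + k_age)`` is
constrained — one number, two unknowns — so flat-glucose sections are
flagged ``insufficient_variability`` rather than fitted, and the least
squares runs in log-parameter space from a grid of starts to avoid settling
on that ridge.  A fit counts as converged only when the optimiser meets
tolerance at a red-cell lifespan strictly inside the plausible 50–180 day
range; solutions pinned at a bound are excluded.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import EligibilityError, InputError
from .kinetics import (
    DailyForcing,
    GlucoseTrace,
    KineticParameters,
    _propagate,
    daily_forcing,
)
from .units import HbA1cValue

__all__ = [
    "ExclusionReason",
    "HbA1cMeasurement",
    "DataSection",
    "FitConfig",
    "FitResult",
    "extract_sections",
    "fit_subject",
    "variability_score",
]


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    INSUFFICIENT_COVERAGE = "insufficient_coverage"
    INSUFFICIENT_VARIABILITY = "insufficient_variability"
    LIFESPAN_OUT_OF_BOUNDS = "lifespan_out_of_bounds"
    OPTIMIZER_FAILURE = "optimizer_failure"
    TOO_FEW_MEASUREMENTS = "too_few_measurements"


@dataclass(frozen=True)
class HbA1cMeasurement:
    """One laboratory HbA1c observation."""

    time: float  # days from subject start
    value: HbA1cValue
    source: str = "laboratory"


@dataclass(frozen=True)
class DataSection:
    """Two consecutive laboratory HbA1c measurements plus the connecting
    daily glucose forcing; ``exclusion`` records why the section cannot be
    used, or NONE."""

    start: HbA1cMeasurement
    end: HbA1cMeasurement
    forcing: DailyForcing | None
    exclusion: ExclusionReason = ExclusionReason.NONE

    def __post_init__(self) -> None:
        if self.end.time <= self.start.time:
            raise InputError("section end must be after its start")

    @property
    def eligible(self) -> bool:
        return self.exclusion is ExclusionReason.NONE

    @property
    def coverage(self) -> float:
        return self.forcing.coverage if self.forcing is not None else 0.0

    @property
    def span_days(self) -> float:
        return self.end.time - self.start.time


@dataclass(frozen=True)
class FitConfig:
    """Gates and optimiser settings for section extraction and fitting.

    The coverage and variability thresholds are study conventions, not
    physical constants; both are exposed so cohorts with different sensors
    or schedules can tighten or relax them.
    """

    coverage_threshold: float = 0.70  # min fraction of days with a daily mean
    max_gap_days: int = 2  # longest bridgeable run of missing days
    min_variability_mgdl: float = 5.0  # min SD of daily means
    min_daily_fraction: float = 0.5  # readings needed for a daily mean
    lifespan_bounds_days: tuple[float, float] = (50.0, 180.0)
    start_lifespans_days: tuple[float, ...] = (60.0, 100.0, 160.0)
    start_k_factors: tuple[float, ...] = (0.5, 1.0, 2.0)
    ftol: float = 1e-10
    xtol: float = 1e-8
    bound_margin_days: float = 0.5  # closer than this to a bound = pinned


@dataclass(frozen=True)
class FitResult:
    """Outcome of a subject fit: parameters or an exclusion reason."""

    params: KineticParameters | None
    residuals: np.ndarray
    objective: float
    converged: bool
    exclusion_reason: ExclusionReason
    n_sections_used: int = 0
    section_exclusions: tuple[ExclusionReason, ...] = field(default_factory=tuple)

    @property
    def lifespan_days(self) -> float | None:
        return self.params.lifespan_days if self.params is not None else None


def extract_sections(
    measurements: list[HbA1cMeasurement],
    trace: GlucoseTrace,
    config: FitConfig = FitConfig(),
) -> list[DataSection]:
    """Build all consecutive-measurement sections, annotated with eligibility.

    Fewer than two measurements make the subject ineligible (empty list).
    Each section carries its daily forcing and, where a gate fails, the
    exclusion reason (coverage and gap length checked first, then
    between-day variability).
    """
    if len(measurements) < 2:
        return []
    ordered = sorted(measurements, key=lambda m: m.time)
    times = [m.time for m in ordered]
    if len(set(times)) != len(times):
        raise InputError("measurement times must be unique per subject")

    sections: list[DataSection] = []
    for first, second in zip(ordered, ordered[1:]):
        start_day = int(math.floor(first.time))
        end_day = int(math.floor(second.time))
        if end_day <= start_day:
            sections.append(
                DataSection(first, second, None, ExclusionReason.INSUFFICIENT_COVERAGE)
            )
            continue
        try:
            forcing = daily_forcing(
                trace,
                start_day,
                end_day,
                min_daily_fraction=config.min_daily_fraction,
                bridge=True,
            )
        except EligibilityError:
            sections.append(
                DataSection(first, second, None, ExclusionReason.INSUFFICIENT_COVERAGE)
            )
            continue
        reason = _section_gate(forcing, config)
        sections.append(DataSection(first, second, forcing, reason))
    return sections


def _section_gate(forcing: DailyForcing, config: FitConfig) -> ExclusionReason:
    if (
        forcing.coverage < config.coverage_threshold
        or forcing.max_gap_days > config.max_gap_days
    ):
        return ExclusionReason.INSUFFICIENT_COVERAGE
    if forcing.n_observed < 2:
        return ExclusionReason.INSUFFICIENT_COVERAGE
    if forcing.variability() < config.min_variability_mgdl:
        return ExclusionReason.INSUFFICIENT_VARIABILITY
    return ExclusionReason.NONE


def variability_score(section: DataSection) -> float:
    """Between-day variability: population SD of the section's observed
    daily mean glucose, mg/dL."""
    if section.forcing is None:
        raise EligibilityError("section has no usable CGM forcing")
    return section.forcing.variability()


def _section_residuals(
    sections: list[DataSection], k_age: float, K: float
) -> np.ndarray:
    res = np.empty(len(sections))
    for i, s in enumerate(sections):
        a_end = _propagate(s.start.value.fraction, s.forcing.glucose, K, k_age)[-1]
        res[i] = s.end.value.fraction - a_end
    return res


def fit_subject(
    sections: list[DataSection],
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Jointly fit (k_age, K) to all eligible sections of one subject.

    Minimises the sum of squared differences between each section's end
    laboratory HbA1c and the model value, over log-parameters bounded so
    the implied lifespan stays in ``config.lifespan_bounds_days``.  Starts
    from a grid of lifespans crossed with glycation constants seeded by
    inverting the steady state at the section mean glucose.
    """
    section_reasons = tuple(s.exclusion for s in sections)
    eligible = [s for s in sections if s.eligible]
    if not eligible:
        reason = _dominant_reason(section_reasons)
        return FitResult(None, np.empty(0), math.nan, False, reason, 0, section_reasons)

    lo_life, hi_life = config.lifespan_bounds_days
    log_k_bounds = (math.log(1.0 / hi_life), math.log(1.0 / lo_life))

    mean_g = float(
        np.mean(np.concatenate([s.forcing.glucose for s in eligible]))
    )
    a0 = eligible[0].start.value.fraction

    def residual_fn(x: np.ndarray) -> np.ndarray:
        k_age, K = math.exp(x[0]), math.exp(x[1])
        return _section_residuals(eligible, k_age, K)

    solutions = []
    for life0 in config.start_lifespans_days:
        k0 = 1.0 / life0
        # steady-state inversion: A0 = K*g/(K*g + k) -> K = A0*k/(g*(1-A0))
        k_seed = a0 * k0 / (mean_g * (1.0 - a0))
        for factor in config.start_k_factors:
            x0 = np.array([math.log(k0), math.log(k_seed * factor)])
            try:
                sol = least_squares(
                    residual_fn,
                    x0,
                    bounds=(
                        [log_k_bounds[0], -40.0],
                        [log_k_bounds[1], 0.0],
                    ),
                    method="trf",
                    ftol=config.ftol,
                    xtol=config.xtol,
                    gtol=1e-12,
                )
            except (ValueError, FloatingPointError):
                continue
            if np.isfinite(sol.cost):
                solutions.append(sol)

    best = None
    if solutions:
        best_cost = min(s.cost for s in solutions)
        # The two-parameter problem can admit several numerically exact
        # interpolants (distinct roots of the section system).  Among
        # solutions whose cost ties the best within tolerance, report the
        # one with turnover closest to the population reference — a
        # deterministic, documented tie-break.
        tie_tol = max(10.0 * best_cost, 1e-16)
        tied = [s for s in solutions if s.cost <= best_cost + tie_tol]
        ref_log_k = math.log(1.0 / 106.0)
        best = min(tied, key=lambda s: abs(s.x[0] - ref_log_k))

    if best is None:
        return FitResult(
            None,
            np.empty(0),
            math.nan,
            False,
            ExclusionReason.OPTIMIZER_FAILURE,
            len(eligible),
            section_reasons,
        )

    k_age, K = math.exp(best.x[0]), math.exp(best.x[1])
    params = KineticParameters(K=K, k_age=k_age)
    residuals = _section_residuals(eligible, k_age, K)
    objective = float(np.sum(residuals**2))
    lifespan = params.lifespan_days

    pinned = (
        lifespan <= lo_life + config.bound_margin_days
        or lifespan >= hi_life - config.bound_margin_days
    )
    if pinned:
        return FitResult(
            params,
            residuals,
            objective,
            False,
            ExclusionReason.LIFESPAN_OUT_OF_BOUNDS,
            len(eligible),
            section_reasons,
        )
    return FitResult(
        params,
        residuals,
        objective,
        True,
        ExclusionReason.NONE,
        len(eligible),
        section_reasons,
    )


def _dominant_reason(reasons: tuple[ExclusionReason, ...]) -> ExclusionReason:
    if not reasons:
        return ExclusionReason.TOO_FEW_MEASUREMENTS
    non_none = [r for r in reasons if r is not ExclusionReason.NONE]
    counts: dict[ExclusionReason, int] = {}
    for r in non_none:
        counts[r] = counts.get(r, 0) + 1
    return max(counts, key=counts.get)  # type: ignore[arg-type]
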
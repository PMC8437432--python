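"""Unit systems for glycated hemoglobin, glucose, and red-cell kinetics.

Every quantity in this package has one canonical in-memory representation:

* HbA1c — the glycated fraction of hemoglobin, a dimensionless number in
  (0, 1).  The NGSP percentage is ``100 * fraction``; the IFCC value in
  mmol/mol is obtained from the NGSP percent via the IFCC–NGSP master
  equation.
* Glucose — mg/dL.  mmol/L inputs are converted with the molar mass of
  glucose (18.016 mg per mmol per dL scaling).
* Red-cell kinetics — the turnover rate ``k_age`` (fraction of the RBC pool
  replaced per day).  Under the constant-lifespan assumption the lifespan is
  ``1 / k_age`` days and the mean circulating cell age is half the lifespan.

The reference turnover used throughout is a 106-day red-cell lifespan
(``k_age`` ≈ 0.9434 %/day, commonly quoted as 0.94 %/day).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "IFCC_NGSP_SLOPE",
    "IFCC_NGSP_INTERCEPT",
    "MGDL_PER_MMOLL",
    "REFERENCE_LIFESPAN_DAYS",
    "K_AGE_REF",
    "GlucoseUnit",
    "HbA1cValue",
    "RBCKinetics",
    "GlucoseValue",
    "ngsp_percent_to_ifcc",
    "ifcc_to_ngsp_percent",
    "lifespan_from_turnover",
    "turnover_from_lifespan",
    "mean_age_from_lifespan",
    "mmoll_to_mgdl",
    "mgdl_to_mmoll",
]

# IFCC-NGSP master equation: IFCC [mmol/mol] = 10.929 * (NGSP% - 2.15)
IFCC_NGSP_SLOPE = 10.929
IFCC_NGSP_INTERCEPT = 2.15

# glucose molar mass scaling: 1 mmol/L = 18.016 mg/dL
MGDL_PER_MMOLL = 18.016

#: Standard red-cell lifespan used as the adjustment reference, days.
REFERENCE_LIFESPAN_DAYS = 106.0

#: Standard red-cell turnover rate, per day (= 1/106 ≈ 0.9434 %/day).
K_AGE_REF = 1.0 / REFERENCE_LIFESPAN_DAYS

# NGSP percent range accepted by the master-equation conversion.  Below the
# 2.15% intercept the IFCC value would be negative; values above 25% are
# outside any assay's reporting range.
_NGSP_MIN = 2.15
_NGSP_MAX = 25.0


class GlucoseUnit(str, enum.Enum):
    """Units a CGM export may report glucose in."""

    MGDL = "mg/dL"
    MMOLL = "mmol/L"


def ngsp_percent_to_ifcc(ngsp_percent: float) -> float:
    """Convert HbA1c from NGSP % to IFCC mmol/mol (master equation).

    Returns the unrounded value; round to integer only for presentation.
    """
    if not _NGSP_MIN < ngsp_percent < _NGSP_MAX:
        raise ValueError(
            f"NGSP value {ngsp_percent!r}% outside the convertible interval "
            f"({_NGSP_MIN}, {_NGSP_MAX})%"
        )
    return IFCC_NGSP_SLOPE * (ngsp_percent - IFCC_NGSP_INTERCEPT)


def ifcc_to_ngsp_percent(ifcc_mmol_mol: float) -> float:
    """Convert HbA1c from IFCC mmol/mol to NGSP % (inverse master equation)."""
    if ifcc_mmol_mol <= 0:
        raise ValueError(f"IFCC value must be positive, got {ifcc_mmol_mol!r}")
    return ifcc_mmol_mol / IFCC_NGSP_SLOPE + IFCC_NGSP_INTERCEPT


def lifespan_from_turnover(k_age: float) -> float:
    """RBC lifespan in days from the turnover rate (fraction/day)."""
    if k_age <= 0:
        raise ValueError(f"turnover rate must be positive, got {k_age!r}")
    return 1.0 / k_age


def turnover_from_lifespan(lifespan_days: float) -> float:
    """RBC turnover rate (fraction/day) from the lifespan in days."""
    if lifespan_days <= 0:
        raise ValueError(f"lifespan must be positive, got {lifespan_days!r}")
    return 1.0 / lifespan_days


def mean_age_from_lifespan(lifespan_days: float) -> float:
    """Mean circulating RBC age: half the lifespan (constant-lifespan pool)."""
    if lifespan_days <= 0:
        raise ValueError(f"lifespan must be positive, got {lifespan_days!r}")
    return lifespan_days / 2.0


def mmoll_to_mgdl(value: float) -> float:
    return value * MGDL_PER_MMOLL


def mgdl_to_mmoll(value: float) -> float:
    return value / MGDL_PER_MMOLL


@dataclass(frozen=True)
class HbA1cValue:
    """A glycated-hemoglobin fraction in (0, 1) (NGSP decimal).

    8% NGSP is stored as 0.08.  Conversions keep full precision; rounding
    (one decimal for NGSP %, integer for IFCC) belongs to the presentation
    layer only.
    """

    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError(
                f"HbA1c fraction must lie in (0, 1), got {self.fraction!r}"
            )

    @classmethod
    def from_ngsp_percent(cls, percent: float) -> "HbA1cValue":
        return cls(percent / 100.0)

    @classmethod
    def from_ifcc(cls, ifcc_mmol_mol: float) -> "HbA1cValue":
        return cls.from_ngsp_percent(ifcc_to_ngsp_percent(ifcc_mmol_mol))

    @property
    def ngsp_percent(self) -> float:
        return self.fraction * 100.0

    @property
    def ifcc(self) -> float:
        return ngsp_percent_to_ifcc(self.ngsp_percent)

    def format_ngsp(self) -> str:
        return f"{self.ngsp_percent:.1f}%"

    def format_ifcc(self) -> str:
        return f"{round(self.ifcc):d} mmol/mol"


@dataclass(frozen=True)
class RBCKinetics:
    """Red-cell turnover descriptors tied by 2·mean_age = lifespan = 1/k_age."""

    k_age: float

    def __post_init__(self) -> None:
        if not (self.k_age > 0 and math.isfinite(self.k_age)):
            raise ValueError(f"k_age must be positive and finite, got {self.k_age!r}")

    @classmethod
    def from_lifespan(cls, lifespan_days: float) -> "RBCKinetics":
        return cls(turnover_from_lifespan(lifespan_days))

    @classmethod
    def from_mean_age(cls, mean_age_days: float) -> "RBCKinetics":
        return cls.from_lifespan(2.0 * mean_age_days)

    @property
    def lifespan_days(self) -> float:
        return lifespan_from_turnover(self.k_age)

    @property
    def mean_age_days(self) -> float:
        return mean_age_from_lifespan(self.lifespan_days)


#: The distinguished reference kinetics instance (106-day lifespan).
REFERENCE_KINETICS = RBCKinetics.from_lifespan(REFERENCE_LIFESPAN_DAYS)


@dataclass(frozen=True)
class GlucoseValue:
    """A single glucose concentration, stored canonically in mg/dL."""

    concentration_mgdl: float
    source_unit: GlucoseUnit = GlucoseUnit.MGDL

    def __post_init__(self) -> None:
        if not (self.concentration_mgdl > 0 and math.isfinite(self.concentration_mgdl)):
            raise ValueError(
                f"glucose must be positive and finite, got {self.concentration_mgdl!r}"
            )

    @classmethod
    def parse(cls, value: float, unit: GlucoseUnit | str) -> "GlucoseValue":
        unit = GlucoseUnit(unit)
        mgdl = mmoll_to_mgdl(value) if unit is GlucoseUnit.MMOLL else value
        return cls(mgdl, unit)

    @property
    def mmoll(self) -> float:
        return mgdl_to_mmoll(self.concentration_mgdl)
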
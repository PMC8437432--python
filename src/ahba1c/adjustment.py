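"""Turnover-normalised HbA1c (aHbA1c).

Laboratory HbA1c reflects both glycaemia and the person's red-cell turnover:
at steady state the glycated fraction is ``A = K*g / (K*g + k_age)``, so a
slow turnover (long red-cell lifespan) raises HbA1c and a fast turnover
lowers it, at identical glucose exposure.  aHbA1c removes this nuisance by
asking what the same glycaemic drive ``K*g`` would produce at a reference
turnover.  Eliminating ``K*g`` between the two steady states gives

    aHbA1c = H / (H + (k_ref / k_age) * (1 - H))

with ``H`` the laboratory glycated fraction, ``k_age`` the individual
turnover rate and ``k_ref`` the reference (106-day lifespan by default).
For small ``H`` this reduces to the linear approximation
``aHbA1c ≈ (k_age / k_ref) * H``.

The adjustment is asymmetric: shortening the lifespan below the reference
moves aHbA1c further from the laboratory value than lengthening it by the
same number of days.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import InputError
from .units import (
    K_AGE_REF,
    HbA1cValue,
    ifcc_to_ngsp_percent,
    ngsp_percent_to_ifcc,
)

__all__ = [
    "AdjustmentBand",
    "AdjustedResult",
    "adjusted_hba1c",
    "adjusted_hba1c_approx",
    "adjusted_hba1c_ifcc",
    "adjustment_band",
]


class AdjustmentBand(str, enum.Enum):
    """Magnitude of the adjustment |aHbA1c − HbA1c| in NGSP points.

    Boundaries belong to the higher band: the intervals are [0,1), [1,2),
    [2,3), [3,∞).
    """

    UNDER_1 = "<1%"
    ONE_TO_TWO = "1-2%"
    TWO_TO_THREE = "2-3%"
    OVER_3 = ">3%"


def _classify(adjustment_ngsp_points: float) -> AdjustmentBand:
    mag = abs(adjustment_ngsp_points)
    if mag < 1.0:
        return AdjustmentBand.UNDER_1
    if mag < 2.0:
        return AdjustmentBand.ONE_TO_TWO
    if mag < 3.0:
        return AdjustmentBand.TWO_TO_THREE
    return AdjustmentBand.OVER_3


@dataclass(frozen=True)
class AdjustedResult:
    """A laboratory HbA1c together with its turnover-normalised value."""

    laboratory: HbA1cValue
    adjusted: HbA1cValue
    k_age: float
    k_age_ref: float

    @property
    def adjustment_ngsp_points(self) -> float:
        """(adjusted − laboratory) in NGSP percentage points (signed)."""
        return self.adjusted.ngsp_percent - self.laboratory.ngsp_percent

    @property
    def adjustment_ifcc(self) -> float:
        """(adjusted − laboratory) in mmol/mol (signed)."""
        return self.adjusted.ifcc - self.laboratory.ifcc

    @property
    def band(self) -> AdjustmentBand:
        return _classify(self.adjustment_ngsp_points)


def adjusted_hba1c(
    laboratory: HbA1cValue | float,
    k_age: float,
    k_age_ref: float = K_AGE_REF,
) -> AdjustedResult:
    """Normalise a laboratory HbA1c to the reference red-cell turnover.

    Parameters
    ----------
    laboratory
        Laboratory HbA1c as a glycated fraction (0.079 for 7.9% NGSP).
    k_age
        The individual's red-cell turnover rate, per day (1/lifespan).
    k_age_ref
        Reference turnover rate, per day; defaults to a 106-day lifespan.
    """
    lab = laboratory if isinstance(laboratory, HbA1cValue) else HbA1cValue(laboratory)
    if k_age <= 0 or k_age_ref <= 0:
        raise InputError("turnover rates must be positive")
    h = lab.fraction
    adjusted = h / (h + (k_age_ref / k_age) * (1.0 - h))
    return AdjustedResult(lab, HbA1cValue(adjusted), k_age, k_age_ref)


def adjusted_hba1c_approx(
    laboratory: HbA1cValue | float,
    k_age: float,
    k_age_ref: float = K_AGE_REF,
) -> HbA1cValue:
    """Small-H linearisation ``aHbA1c ≈ (k_age/k_ref) * H``.

    Useful for mental arithmetic; overestimates the exact adjustment by a
    relative factor bounded by ``H/(1-H)`` over the clinical range.
    """
    lab = laboratory if isinstance(laboratory, HbA1cValue) else HbA1cValue(laboratory)
    if k_age <= 0 or k_age_ref <= 0:
        raise InputError("turnover rates must be positive")
    return HbA1cValue((k_age / k_age_ref) * lab.fraction)


def adjusted_hba1c_ifcc(
    laboratory_ifcc: float,
    k_age: float,
    k_age_ref: float = K_AGE_REF,
) -> float:
    """aHbA1c in IFCC mmol/mol (unrounded).

    Converts through the NGSP fraction with the IFCC–NGSP master equation,
    applies the adjustment, and converts back; round to integer only for
    presentation.
    """
    lab = HbA1cValue.from_ngsp_percent(ifcc_to_ngsp_percent(laboratory_ifcc))
    result = adjusted_hba1c(lab, k_age, k_age_ref)
    return ngsp_percent_to_ifcc(result.adjusted.ngsp_percent)


def adjustment_band(result: AdjustedResult) -> AdjustmentBand:
    """Band of |aHbA1c − HbA1c| in NGSP points ([0,1), [1,2), [2,3), [3,∞))."""
    return result.band
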
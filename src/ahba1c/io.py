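"""Delimited-text readers, writers and cohort summaries.

File conventions (all headered CSV):

* CGM: ``subject_id, timestamp, glucose, unit`` — ISO-8601 timestamps,
  glucose in mg/dL or mmol/L as declared per row in ``unit``.
* HbA1c: ``subject_id, date, value, unit`` — ``unit`` is ``%`` (NGSP) or
  ``mmol/mol`` (IFCC).

In memory, each subject's clock starts at their first CGM reading; HbA1c
dates are converted to day offsets on that same origin when bundles are
assembled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjustment import AdjustedResult
from .errors import FormatError, InputError
from .estimation import ExclusionReason, FitResult, HbA1cMeasurement
from .kinetics import GlucoseTrace
from .simulate import SyntheticSubject
from .units import (
    GlucoseUnit,
    HbA1cValue,
    ifcc_to_ngsp_percent,
    mmoll_to_mgdl,
)

logger = logging.getLogger("ahba1c")

__all__ = [
    "SubjectCGM",
    "SubjectBundle",
    "CohortSummary",
    "read_cgm",
    "write_cgm",
    "read_hba1c",
    "write_hba1c",
    "build_bundles",
    "summarize_cohort",
    "write_synthetic_cohort",
]

_CGM_COLUMNS = ["subject_id", "timestamp", "glucose", "unit"]
_HBA1C_COLUMNS = ["subject_id", "date", "value", "unit"]

#: Origin date attached to synthetic cohorts when writing files.
SYNTHETIC_ORIGIN = pd.Timestamp("2024-01-01 00:00:00")


@dataclass(frozen=True)
class SubjectCGM:
    """A parsed CGM trace plus the wall-clock origin of its day axis."""

    subject_id: str
    trace: GlucoseTrace
    origin: pd.Timestamp


@dataclass
class SubjectBundle:
    """Everything known about one subject as processing progresses."""

    subject_id: str
    cgm: SubjectCGM
    measurements: list[HbA1cMeasurement]
    fit: FitResult | None = None
    adjusted: list[AdjustedResult] = field(default_factory=list)


@dataclass(frozen=True)
class CohortSummary:
    """Aggregate report: eligibility, lifespans and adjustment magnitudes."""

    n_subjects: int
    n_eligible: int
    n_excluded_by_reason: dict[str, int]
    lifespan_mean: float
    lifespan_median: float
    lifespan_iqr: tuple[float, float]
    abs_adjustment_mean_ngsp: float
    abs_adjustment_median_ngsp: float
    abs_adjustment_iqr_ngsp: tuple[float, float]
    band_counts: dict[str, int]

    @property
    def band_percentages(self) -> dict[str, float]:
        total = sum(self.band_counts.values())
        if total == 0:
            return {k: 0.0 for k in self.band_counts}
        return {k: 100.0 * v / total for k, v in self.band_counts.items()}


def _require_columns(df: pd.DataFrame, columns: list[str], path: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_cgm(path: str, max_bad_fraction: float = 0.05) -> dict[str, SubjectCGM]:
    """Parse a CGM file into per-subject traces (times in days from each
    subject's first reading, glucose unit-normalised to mg/dL).

    Rows with unparseable timestamps or non-positive glucose are dropped and
    counted; exceeding ``max_bad_fraction`` of the file is a format error.
    Duplicate timestamps are collapsed by mean; out-of-order rows are sorted
    with a warning.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, _CGM_COLUMNS, path)
    n_total = len(df)
    if n_total == 0:
        raise FormatError(f"{path}: no CGM rows")

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    glucose = pd.to_numeric(df["glucose"], errors="coerce")
    bad = ts.isna() | glucose.isna() | (glucose <= 0)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        if bad.mean() > max_bad_fraction:
            raise FormatError(
                f"{path}: {int(bad.sum())}/{n_total} unparseable CGM rows "
                f"(first offending lines: {lines[:5]})"
            )
        logger.warning("%s: dropped %d unparseable CGM rows", path, int(bad.sum()))
    df = df.loc[~bad].copy()
    df["timestamp"] = ts[~bad]
    df["glucose"] = glucose[~bad]

    mmoll = df["unit"].astype(str).str.strip() == GlucoseUnit.MMOLL.value
    unknown = ~mmoll & (df["unit"].astype(str).str.strip() != GlucoseUnit.MGDL.value)
    if unknown.any():
        raise FormatError(
            f"{path}: unknown glucose unit(s) {sorted(df.loc[unknown, 'unit'].unique())}"
        )
    df.loc[mmoll, "glucose"] = mmoll_to_mgdl(df.loc[mmoll, "glucose"])

    out: dict[str, SubjectCGM] = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        if not grp["timestamp"].is_monotonic_increasing:
            logger.warning("subject %s: out-of-order CGM rows sorted", sid)
            grp = grp.sort_values("timestamp")
        # collapse duplicate timestamps by mean
        grp = grp.groupby("timestamp", as_index=False)["glucose"].mean()
        # midnight of the first reading's date, so the day axis follows
        # calendar days (daily means aggregate within calendar days)
        origin = grp["timestamp"].iloc[0].normalize()
        times = (grp["timestamp"] - origin).dt.total_seconds().to_numpy() / 86400.0
        out[str(sid)] = SubjectCGM(
            str(sid), GlucoseTrace(times, grp["glucose"].to_numpy()), origin
        )
    return out


def write_cgm(subjects: dict[str, SubjectCGM], path: str) -> None:
    """Write traces back to the CGM file format (mg/dL; valid readings only)."""
    frames = []
    for sid, s in subjects.items():
        t = s.trace
        mask = t.valid
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "timestamp": s.origin + pd.to_timedelta(t.times[mask], unit="D"),
                    "glucose": t.glucose[mask],
                    "unit": GlucoseUnit.MGDL.value,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def _hba1c_from_row(value: float, unit: str) -> HbA1cValue:
    unit = unit.strip()
    if unit == "%":
        return HbA1cValue.from_ngsp_percent(value)
    if unit == "mmol/mol":
        return HbA1cValue.from_ngsp_percent(ifcc_to_ngsp_percent(value))
    raise FormatError(f"unknown HbA1c unit {unit!r} (expected '%' or 'mmol/mol')")


def read_hba1c(path: str) -> dict[str, list[tuple[pd.Timestamp, HbA1cValue]]]:
    """Parse laboratory HbA1c measurements, normalised to glycated fraction,
    sorted by date per subject.  Duplicate dates for one subject are an
    error (the laboratory schedule has at most one draw per day)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, _HBA1C_COLUMNS, path)
    df["date"] = pd.to_datetime(df["date"], errors="raise", format="ISO8601")
    out: dict[str, list[tuple[pd.Timestamp, HbA1cValue]]] = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        if grp["date"].duplicated().any():
            raise FormatError(f"subject {sid}: duplicate HbA1c measurement dates")
        grp = grp.sort_values("date")
        out[str(sid)] = [
            (row.date, _hba1c_from_row(float(row.value), str(row.unit)))
            for row in grp.itertuples()
        ]
    return out


def write_hba1c(
    measurements: dict[str, list[tuple[pd.Timestamp, HbA1cValue]]], path: str
) -> None:
    rows = [
        {
            "subject_id": sid,
            "date": ts.strftime("%Y-%m-%d"),
            "value": round(v.ngsp_percent, 4),
            "unit": "%",
        }
        for sid, entries in measurements.items()
        for ts, v in entries
    ]
    pd.DataFrame(rows, columns=_HBA1C_COLUMNS).to_csv(path, index=False)


def build_bundles(
    cgm: dict[str, SubjectCGM],
    hba1c: dict[str, list[tuple[pd.Timestamp, HbA1cValue]]],
) -> list[SubjectBundle]:
    """Join CGM and HbA1c by subject; HbA1c dates become day offsets on the
    subject's CGM origin.  Subjects missing either side are skipped with a
    warning."""
    bundles = []
    for sid in sorted(set(cgm) & set(hba1c)):
        s = cgm[sid]
        measurements = [
            HbA1cMeasurement(
                time=(ts - s.origin).total_seconds() / 86400.0, value=v
            )
            for ts, v in hba1c[sid]
        ]
        bundles.append(SubjectBundle(sid, s, measurements))
    for sid in sorted(set(cgm) ^ set(hba1c)):
        logger.warning("subject %s present in only one input; skipped", sid)
    return bundles


def _iqr(values: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(values, [25, 75])  # linear-interpolation quantiles
    return float(lo), float(hi)


def summarize_cohort(bundles: list[SubjectBundle]) -> CohortSummary:
    """Aggregate lifespans and adjustment magnitudes over converged fits.

    The per-subject adjustment is taken from the subject's most recent
    laboratory HbA1c (one band per individual).  With no eligible subjects
    the summary carries counts only (statistics are NaN).
    """
    from .adjustment import AdjustmentBand

    reasons: dict[str, int] = {}
    lifespans = []
    adjustments = []
    bands = {b.value: 0 for b in AdjustmentBand}
    for b in bundles:
        if b.fit is None or not b.fit.converged:
            reason = (
                b.fit.exclusion_reason.value
                if b.fit is not None
                else ExclusionReason.TOO_FEW_MEASUREMENTS.value
            )
            reasons[reason] = reasons.get(reason, 0) + 1
            continue
        lifespans.append(b.fit.lifespan_days)
        if b.adjusted:
            last = b.adjusted[-1]
            adjustments.append(abs(last.adjustment_ngsp_points))
            bands[last.band.value] += 1

    n_eligible = len(lifespans)
    nan = float("nan")
    ls = np.asarray(lifespans)
    adj = np.asarray(adjustments)
    return CohortSummary(
        n_subjects=len(bundles),
        n_eligible=n_eligible,
        n_excluded_by_reason=reasons,
        lifespan_mean=float(ls.mean()) if n_eligible else nan,
        lifespan_median=float(np.median(ls)) if n_eligible else nan,
        lifespan_iqr=_iqr(ls) if n_eligible else (nan, nan),
        abs_adjustment_mean_ngsp=float(adj.mean()) if adj.size else nan,
        abs_adjustment_median_ngsp=float(np.median(adj)) if adj.size else nan,
        abs_adjustment_iqr_ngsp=_iqr(adj) if adj.size else (nan, nan),
        band_counts=bands,
    )


def write_synthetic_cohort(
    subjects: list[SyntheticSubject], cgm_path: str, hba1c_path: str, truth_path: str | None = None
) -> None:
    """Write a simulated cohort in the same formats the readers consume,
    plus an optional ground-truth table."""
    cgm = {
        s.subject_id: SubjectCGM(s.subject_id, s.trace, SYNTHETIC_ORIGIN)
        for s in subjects
    }
    write_cgm(cgm, cgm_path)
    hba1c = {
        s.subject_id: [
            (SYNTHETIC_ORIGIN + pd.to_timedelta(m.time, unit="D"), m.value)
            for m in s.measurements
        ]
        for s in subjects
    }
    write_hba1c(hba1c, hba1c_path)
    if truth_path is not None:
        pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in subjects],
                "true_lifespan_days": [s.true_lifespan_days for s in subjects],
                "true_k_age_per_day": [s.params.k_age for s in subjects],
                "true_K_per_day_per_mgdl": [s.params.K for s in subjects],
                "baseline_glucose_mgdl": [s.baseline_glucose for s in subjects],
            }
        ).to_csv(truth_path, index=False)
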
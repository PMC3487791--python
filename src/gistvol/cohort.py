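"""Cohort data model: typed per-lesion measurements, scans, survival, CSV I/O.

Measurement cohorts are plain CSV tables (one row per lesion, timepoint,
method and reader).  This module parses them into validated record types,
selects target lesions at baseline, maps calendar scans onto nominal
follow-up timepoints, and aggregates target lesions into per-patient
timepoint summaries used by the response classifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: Volumes are stored in mL in files; axis lengths in mm.  1 mL = 1000 mm^3.
MM3_PER_ML = 1000.0

#: Nominal measurement timepoints in months after start of therapy.
TIMEPOINTS = (0, 3, 6, 12)
FOLLOWUP_TIMEPOINTS = (3, 6, 12)

#: A scan maps onto a nominal timepoint only within this window (months).
TIMEPOINT_WINDOW_MONTHS = 1.5

#: Relative tolerance for the axes <-> volume consistency invariant.
AXES_VOLUME_RTOL = 1e-3


class Method(str, Enum):
    """Measurement technique."""

    MANUAL = "manual"
    SEMIAUTO = "semiauto"


class SchemaError(ValueError):
    """Raised when a CSV file does not carry the required columns."""


@dataclass(frozen=True)
class LesionMeasurement:
    """One lesion measured at one timepoint by one method/reader.

    ``axes_mm`` (semi-axes, ascending) is populated by synthetic cohorts
    only; when present the recorded volume must equal the ellipsoid volume
    of the axes to within 0.1% relative tolerance.
    """

    patient_id: str
    lesion_id: str
    timepoint_months: int
    method: Method
    reader_id: str
    longest_diameter_mm: float
    volume_mL: float
    mean_density_HU: float | None = None
    axes_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.timepoint_months not in TIMEPOINTS:
            raise ValueError(
                f"timepoint_months must be one of {TIMEPOINTS}, "
                f"got {self.timepoint_months}"
            )
        if not self.longest_diameter_mm > 0:
            raise ValueError("non-positive diameter")
        if not self.volume_mL > 0:
            raise ValueError("non-positive volume")
        if self.axes_mm is not None:
            r1, r2, r3 = self.axes_mm
            if not (0 < r1 <= r2 <= r3):
                raise ValueError("axes must be positive and ascending")
            expected_mL = (4.0 / 3.0) * math.pi * r1 * r2 * r3 / MM3_PER_ML
            if abs(self.volume_mL - expected_mL) > AXES_VOLUME_RTOL * expected_mL:
                raise ValueError(
                    "volume inconsistent with ellipsoid axes: "
                    f"{self.volume_mL:.4f} mL vs {expected_mL:.4f} mL"
                )

    @property
    def is_baseline(self) -> bool:
        return self.timepoint_months == 0


@dataclass(frozen=True)
class ScanRecord:
    """A CT scan for one patient, timed from the first dose of therapy."""

    patient_id: str
    scan_date: date
    months_from_first_imatinib: float

    def __post_init__(self) -> None:
        if self.months_from_first_imatinib < 0:
            raise ValueError("months_from_first_imatinib must be >= 0")


@dataclass(frozen=True)
class SurvivalEntry:
    """Per-patient overall survival from first dose of therapy."""

    patient_id: str
    os_months_from_first_imatinib: float
    event: bool  # True = death observed, False = censored

    def __post_init__(self) -> None:
        if self.os_months_from_first_imatinib < 0:
            raise ValueError("os_months must be >= 0")


@dataclass(frozen=True)
class TargetLesionSet:
    """Up to two target lesions chosen at baseline (largest diameters)."""

    patient_id: str
    lesion_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.lesion_ids) not in (1, 2):
            raise ValueError("target lesion set must hold 1 or 2 lesions")


@dataclass(frozen=True)
class TimepointSummary:
    """Per-patient aggregate over target lesions at one timepoint.

    ``sum_longest_diameter_mm`` is the RECIST sum of longest diameters;
    ``total_volume_mL`` its volumetric counterpart.  The density change is
    the mean over target lesions of the per-lesion relative HU change
    versus baseline, defined only when both timepoints carry densities.
    """

    patient_id: str
    timepoint_months: int
    sum_longest_diameter_mm: float
    total_volume_mL: float
    mean_density_HU: float | None = None
    mean_relative_density_change_pct: float | None = None
    lesion_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sum_longest_diameter_mm > 0:
            raise ValueError("non-positive diameter sum")
        if not self.total_volume_mL > 0:
            raise ValueError("non-positive volume total")


@dataclass
class ParseReport:
    """Outcome of parsing one CSV file."""

    n_accepted: int = 0
    n_rejected: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)

    def reject(self, row: int, message: str) -> None:
        self.n_rejected += 1
        self.errors.append((row, message))


_MEASUREMENT_COLUMNS = [
    "patient_id",
    "lesion_id",
    "timepoint_months",
    "method",
    "reader_id",
    "longest_diameter_mm",
    "volume_mL",
    "mean_density_HU",
]
_AXIS_COLUMNS = ["r1_mm", "r2_mm", "r3_mm"]
_SCAN_COLUMNS = ["patient_id", "scan_date", "months_from_first_imatinib"]
_SURVIVAL_COLUMNS = ["patient_id", "os_months_from_first_imatinib", "event"]


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def _parse_measurement_row(row: pd.Series) -> LesionMeasurement:
    axes = None
    if all(c in row.index for c in _AXIS_COLUMNS):
        vals = [_opt_float(row[c]) for c in _AXIS_COLUMNS]
        if all(v is not None for v in vals):
            axes = (vals[0], vals[1], vals[2])
    return LesionMeasurement(
        patient_id=str(row["patient_id"]),
        lesion_id=str(row["lesion_id"]),
        timepoint_months=int(row["timepoint_months"]),
        method=Method(str(row["method"])),
        reader_id=str(row["reader_id"]),
        longest_diameter_mm=float(row["longest_diameter_mm"]),
        volume_mL=float(row["volume_mL"]),
        mean_density_HU=_opt_float(row.get("mean_density_HU")),
        axes_mm=axes,
    )


def _parse_scan_row(row: pd.Series) -> ScanRecord:
    return ScanRecord(
        patient_id=str(row["patient_id"]),
        scan_date=pd.Timestamp(row["scan_date"]).date(),
        months_from_first_imatinib=float(row["months_from_first_imatinib"]),
    )


def _parse_survival_row(row: pd.Series) -> SurvivalEntry:
    return SurvivalEntry(
        patient_id=str(row["patient_id"]),
        os_months_from_first_imatinib=float(row["os_months_from_first_imatinib"]),
        event=bool(int(row["event"])),
    )


_SCHEMAS = {
    "measurements": (_MEASUREMENT_COLUMNS, _parse_measurement_row),
    "scans": (_SCAN_COLUMNS, _parse_scan_row),
    "survival": (_SURVIVAL_COLUMNS, _parse_survival_row),
}


def read_cohort(path: str | Path, schema: str):
    """Read one cohort CSV into typed records plus a parse report.

    Parameters
    ----------
    path : file path of a UTF-8, comma-separated file with a header row.
    schema : one of ``"measurements"``, ``"scans"``, ``"survival"``.

    Returns
    -------
    (records, report) : rows failing a type invariant are rejected and
    logged in the report with their (0-based) data-row index; a missing
    required column raises :class:`SchemaError`.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    required, parse = _SCHEMAS[schema]
    frame = pd.read_csv(path, dtype={"patient_id": str, "lesion_id": str,
                                     "reader_id": str})
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    records = []
    report = ParseReport()
    for idx, row in frame.iterrows():
        try:
            records.append(parse(row))
            report.n_accepted += 1
        except (ValueError, TypeError, KeyError) as exc:
            report.reject(int(idx), str(exc))
    return records, report


def write_cohort(records: Iterable, path: str | Path) -> None:
    """Write homogeneous records back to CSV (inverse of :func:`read_cohort`)."""
    records = list(records)
    if not records:
        raise ValueError("nothing to write")
    first = records[0]
    if isinstance(first, LesionMeasurement):
        rows = []
        for m in records:
            row = {
                "patient_id": m.patient_id,
                "lesion_id": m.lesion_id,
                "timepoint_months": m.timepoint_months,
                "method": m.method.value,
                "reader_id": m.reader_id,
                "longest_diameter_mm": m.longest_diameter_mm,
                "volume_mL": m.volume_mL,
                "mean_density_HU": m.mean_density_HU,
                "r1_mm": m.axes_mm[0] if m.axes_mm else None,
                "r2_mm": m.axes_mm[1] if m.axes_mm else None,
                "r3_mm": m.axes_mm[2] if m.axes_mm else None,
            }
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    elif isinstance(first, ScanRecord):
        pd.DataFrame(
            [
                {
                    "patient_id": s.patient_id,
                    "scan_date": s.scan_date.isoformat(),
                    "months_from_first_imatinib": s.months_from_first_imatinib,
                }
                for s in records
            ]
        ).to_csv(path, index=False)
    elif isinstance(first, SurvivalEntry):
        pd.DataFrame(
            [
                {
                    "patient_id": s.patient_id,
                    "os_months_from_first_imatinib": s.os_months_from_first_imatinib,
                    "event": int(s.event),
                }
                for s in records
            ]
        ).to_csv(path, index=False)
    else:
        raise TypeError(f"unsupported record type {type(first).__name__}")


def assign_timepoint(
    scans: Sequence[ScanRecord],
    nominal: int,
    window_months: float = TIMEPOINT_WINDOW_MONTHS,
) -> ScanRecord | None:
    """Pick the scan closest in time to a nominal follow-up timepoint.

    The scan minimizing ``|months - nominal|`` wins, ties going to the
    earlier scan.  Returns ``None`` when no scan falls within
    ``window_months`` of the nominal timepoint.
    """
    if nominal not in FOLLOWUP_TIMEPOINTS:
        raise ValueError(f"nominal timepoint must be one of {FOLLOWUP_TIMEPOINTS}")
    eligible = [
        s for s in scans
        if abs(s.months_from_first_imatinib - nominal) <= window_months
    ]
    if not eligible:
        return None
    return min(
        eligible,
        key=lambda s: (
            abs(s.months_from_first_imatinib - nominal),
            s.months_from_first_imatinib,
        ),
    )


def select_target_lesions(
    baseline: Sequence[LesionMeasurement],
) -> TargetLesionSet:
    """Choose up to two target lesions: the largest baseline diameters.

    Ties are broken by lexicographic lesion id, so the choice is
    deterministic and independent of input order.
    """
    baseline = [m for m in baseline if m.is_baseline]
    if not baseline:
        raise ValueError("no baseline lesions")
    patients = {m.patient_id for m in baseline}
    if len(patients) != 1:
        raise ValueError(f"expected a single patient, got {sorted(patients)}")
    ranked = sorted(baseline, key=lambda m: (-m.longest_diameter_mm, m.lesion_id))
    chosen = tuple(m.lesion_id for m in ranked[:2])
    return TargetLesionSet(patient_id=baseline[0].patient_id, lesion_ids=chosen)


def summarize_timepoint(
    measurements: Sequence[LesionMeasurement],
    baseline: Sequence[LesionMeasurement] | None = None,
    targets: TargetLesionSet | None = None,
) -> TimepointSummary:
    """Aggregate target-lesion measurements at one timepoint.

    Sums diameters and volumes; when per-lesion baseline measurements are
    supplied and densities are present on both sides, also computes the
    mean per-lesion relative density change (percent versus baseline).

    ``targets``, when given, enforces that every target lesion is measured
    at this timepoint; a missing lesion raises an error naming it.
    """
    if not measurements:
        raise ValueError("no measurements to summarize")
    patients = {m.patient_id for m in measurements}
    timepoints = {m.timepoint_months for m in measurements}
    methods = {m.method for m in measurements}
    if len(patients) != 1 or len(timepoints) != 1:
        raise ValueError("measurements must share one patient and timepoint")
    if len(methods) != 1:
        raise ValueError("measurements must share a single method")

    present = {m.lesion_id for m in measurements}
    if targets is not None:
        missing = [lid for lid in targets.lesion_ids if lid not in present]
        if missing:
            raise ValueError(
                f"target lesion(s) missing at timepoint "
                f"{next(iter(timepoints))}: {missing}"
            )

    sum_d = sum(m.longest_diameter_mm for m in measurements)
    total_v = sum(m.volume_mL for m in measurements)

    densities = [m.mean_density_HU for m in measurements]
    mean_hu = (
        sum(densities) / len(densities)
        if all(d is not None for d in densities)
        else None
    )

    density_change = None
    if baseline is not None:
        base_by_id = {m.lesion_id: m for m in baseline if m.is_baseline}
        changes = []
        for m in measurements:
            b = base_by_id.get(m.lesion_id)
            if (
                b is not None
                and b.mean_density_HU is not None
                and m.mean_density_HU is not None
            ):
                changes.append(
                    100.0 * (m.mean_density_HU - b.mean_density_HU) / b.mean_density_HU
                )
        if changes and len(changes) == len(measurements):
            density_change = sum(changes) / len(changes)

    return TimepointSummary(
        patient_id=next(iter(patients)),
        timepoint_months=next(iter(timepoints)),
        sum_longest_diameter_mm=sum_d,
        total_volume_mL=total_v,
        mean_density_HU=mean_hu,
        mean_relative_density_change_pct=density_change,
        lesion_ids=tuple(sorted(present)),
    )
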
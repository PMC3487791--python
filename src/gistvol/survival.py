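"""Landmark overall-survival analysis by response group.

Survival is measured from a fixed landmark CT timepoint (3, 6 or
12 months); patients who died or were censored on or before the landmark
are excluded, which avoids guarantee-time bias when grouping by response.
Kaplan-Meier estimation is delegated to lifelines; the log-rank test and
Mantel-Haenszel hazard ratio are computed from the observed/expected
event tables directly, so the HR shares its ingredients with the test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

from .cohort import SurvivalEntry

__all__ = [
    "SurvivalRecord",
    "LandmarkReport",
    "KMCurve",
    "HazardRatioResult",
    "LANDMARKS",
    "landmark_cohort",
    "km_estimate",
    "logrank",
    "mh_hazard_ratio",
]

LANDMARKS = (3, 6, 12)

#: Reporting truncation used for curve export (estimation is untruncated).
REPORT_TRUNCATION_MONTHS = 72.0


@dataclass(frozen=True)
class SurvivalRecord:
    """Landmark-adjusted follow-up for one patient."""

    patient_id: str
    time_months: float
    event: bool
    group: str

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise ValueError("time must be >= 0")


@dataclass
class LandmarkReport:
    n_included: int = 0
    n_excluded_before_landmark: int = 0
    n_without_call: int = 0
    excluded_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve: S(0) = 1, non-increasing."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    n: int
    median_months: float  # inf when the curve never crosses 0.5

    def truncated(self, horizon: float = REPORT_TRUNCATION_MONTHS) -> "KMCurve":
        keep = [i for i, t in enumerate(self.times) if t <= horizon]
        return KMCurve(
            times=tuple(self.times[i] for i in keep),
            survival=tuple(self.survival[i] for i in keep),
            at_risk=tuple(self.at_risk[i] for i in keep),
            n=self.n,
            median_months=self.median_months,
        )


@dataclass(frozen=True)
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    logrank_chi2: float
    logrank_p: float
    observed: tuple[float, float]  # (reference, comparison)
    expected: tuple[float, float]
    ci_defined: bool = True


def landmark_cohort(
    survival: Sequence[SurvivalEntry],
    landmark_months: int,
    calls: Mapping[str, str],
    grouping: str = "pd_vs_rest",
) -> tuple[list[SurvivalRecord], LandmarkReport]:
    """Build landmark-adjusted records grouped by response at the landmark.

    ``calls`` maps patient id to a response category ("PR"/"SD"/"PD").
    ``grouping``: ``"pd_vs_rest"`` collapses PR and SD into "non-PD";
    ``"three_group"`` keeps the three categories distinct.  Patients whose
    OS does not exceed the landmark, or who lack a call, are excluded and
    counted in the report.
    """
    if landmark_months not in LANDMARKS:
        raise ValueError(f"landmark must be one of {LANDMARKS}")
    if grouping not in ("pd_vs_rest", "three_group"):
        raise ValueError(f"unknown grouping {grouping!r}")

    records: list[SurvivalRecord] = []
    report = LandmarkReport()
    for entry in survival:
        call = calls.get(entry.patient_id)
        if call is None:
            report.n_without_call += 1
            continue
        if entry.os_months_from_first_imatinib <= landmark_months:
            report.n_excluded_before_landmark += 1
            report.excluded_ids.append(entry.patient_id)
            continue
        group = call if grouping == "three_group" else (
            "PD" if call == "PD" else "non-PD"
        )
        records.append(
            SurvivalRecord(
                patient_id=entry.patient_id,
                time_months=entry.os_months_from_first_imatinib - landmark_months,
                event=entry.event,
                group=group,
            )
        )
        report.n_included += 1
    return records, report


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate over one group of records.

    Ties are handled with events before censorings at equal times (the
    standard convention, as implemented by lifelines).
    """
    if not records:
        raise ValueError("no records")
    durations = np.array([r.time_months for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter().fit(durations, event_observed=events)
    table = kmf.event_table
    times = table.index.to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=int)
    surv = (
        kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy(dtype=float)
    )
    median = float(kmf.median_survival_time_)
    return KMCurve(
        times=tuple(times),
        survival=tuple(surv),
        at_risk=tuple(at_risk),
        n=len(records),
        median_months=median,
    )


def _observed_expected(
    records: Sequence[SurvivalRecord],
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Per-group observed events, expected events, and the O-E covariance."""
    labels = sorted({r.group for r in records})
    gidx = {g: i for i, g in enumerate(labels)}
    k = len(labels)
    times = np.array([r.time_months for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    groups = np.array([gidx[r.group] for r in records], dtype=int)

    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in np.unique(times[events]):
        at_risk = times >= t
        n_t = int(at_risk.sum())
        d_t = int((events & (times == t)).sum())
        n_gt = np.array([(at_risk & (groups == g)).sum() for g in range(k)], float)
        d_gt = np.array(
            [(events & (times == t) & (groups == g)).sum() for g in range(k)], float
        )
        observed += d_gt
        expected += d_t * n_gt / n_t
        if n_t > 1:
            hyper = d_t * (n_t - d_t) / (n_t - 1)
            p = n_gt / n_t
            cov += hyper * (np.diag(p) - np.outer(p, p))
    return labels, observed, expected, cov


def logrank(records: Sequence[SurvivalRecord]) -> tuple[float, int, float]:
    """Log-rank test across the record groups.

    Returns ``(chi2, df, p)`` with df = number of groups - 1; the
    statistic is the usual quadratic form of (O - E) in its covariance.
    """
    labels = sorted({r.group for r in records})
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    _, observed, expected, cov = _observed_expected(records)
    z = (observed - expected)[:-1]
    v = cov[:-1, :-1]
    chi2 = float(z @ np.linalg.pinv(v) @ z) if z.size else 0.0
    df = len(labels) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def mh_hazard_ratio(
    records: Sequence[SurvivalRecord], reference_group: str
) -> HazardRatioResult:
    """Mantel-Haenszel hazard ratio between exactly two groups.

    HR = (O1/E1) / (O0/E0) with observed/expected events taken from the
    log-rank table; 95% CI = exp(ln HR +/- 1.96 * sqrt(1/E1 + 1/E0)).
    The comparison group is the non-reference one; HR > 1 means it fares
    worse.  With zero observed or expected events in a group the CI (and
    possibly the HR) is undefined and flagged.
    """
    labels = sorted({r.group for r in records})
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    if reference_group not in labels:
        raise ValueError(f"reference group {reference_group!r} not in {labels}")
    lab, observed, expected, _ = _observed_expected(records)
    ref = lab.index(reference_group)
    cmp_ = 1 - ref
    chi2, _, p = logrank(records)

    o0, e0 = observed[ref], expected[ref]
    o1, e1 = observed[cmp_], expected[cmp_]
    defined = o0 > 0 and o1 > 0 and e0 > 0 and e1 > 0
    if defined:
        hr = (o1 / e1) / (o0 / e0)
        half = 1.96 * np.sqrt(1.0 / e1 + 1.0 / e0)
        ci_low = float(hr * np.exp(-half))
        ci_high = float(hr * np.exp(half))
    else:
        hr = float("nan") if (e1 == 0 or e0 == 0 or o0 == 0) else 0.0
        ci_low, ci_high = float("nan"), float("nan")
    return HazardRatioResult(
        hr=float(hr),
        ci_low=ci_low,
        ci_high=ci_high,
        logrank_chi2=chi2,
        logrank_p=p,
        observed=(float(o0), float(o1)),
        expected=(float(e0), float(e1)),
        ci_defined=bool(defined),
    )
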
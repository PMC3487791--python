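"""Response classifiers and the geometry linking 1D and 3D cut-offs.

Four criteria are implemented on per-patient timepoint summaries:

* RECIST 1.1 — percent change of the sum of longest diameters
  (PR <= -30%, PD >= +20% or new lesion);
* 3D-sphere — volumetric cut-offs obtained by cubing the RECIST ones
  (PR <= -65.7%, PD >= +72.8%), the "adjusted/scaled" conversion;
* 3D-ellipsoid — volumetric changes judged against the RECIST cut-offs
  themselves (-30/+20), motivated by prolate spheroids whose only
  changing axis carries the measured diameter;
* Choi — size (+/-10%) combined with mean CT density change (-15% HU).

Also provides the unadjusted >=20% change classifier used for the
1D-versus-3D change-detection comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .cohort import TimepointSummary

__all__ = [
    "Criteria",
    "Category",
    "Direction",
    "CutoffSet",
    "ResponseCall",
    "ChangeClass",
    "RECIST_CUTOFFS",
    "ELLIPSOID_CUTOFFS",
    "SPHERE_CUTOFFS",
    "relative_change",
    "sphere_volume",
    "ellipsoid_volume",
    "derive_sphere_cutoffs",
    "invert_sphere_cutoffs",
    "classify_recist",
    "classify_volume",
    "classify_choi",
    "classify_size_change",
]


class Criteria(str, Enum):
    RECIST = "RECIST"
    SPHERE = "SPHERE"
    ELLIPSOID = "ELLIPSOID"
    CHOI = "CHOI"


class Category(str, Enum):
    PR = "PR"
    SD = "SD"
    PD = "PD"


class Direction(str, Enum):
    DECREASE = "DECREASE"
    NO_CHANGE = "NO_CHANGE"
    INCREASE = "INCREASE"


@dataclass(frozen=True)
class CutoffSet:
    """PR/PD percent-change cut-offs for one criterion (PR < 0 < PD)."""

    criteria: Criteria
    pr_cutoff_pct: float
    pd_cutoff_pct: float

    def __post_init__(self) -> None:
        if not (self.pr_cutoff_pct <= 0 <= self.pd_cutoff_pct):
            raise ValueError("require pr_cutoff <= 0 <= pd_cutoff")

    def to_dict(self) -> dict:
        return {
            "criteria": self.criteria.value,
            "pr_cutoff_pct": self.pr_cutoff_pct,
            "pd_cutoff_pct": self.pd_cutoff_pct,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CutoffSet":
        return cls(Criteria(d["criteria"]), d["pr_cutoff_pct"], d["pd_cutoff_pct"])


@dataclass(frozen=True)
class ResponseCall:
    """One PR/SD/PD call for one patient, timepoint and criterion."""

    patient_id: str
    timepoint_months: int
    criteria: Criteria
    category: Category
    size_change_pct: float
    density_change_pct: float | None = None
    new_lesion: bool = False
    new_intratumoral_nodule: bool = False
    density_missing: bool = False


@dataclass(frozen=True)
class ChangeClass:
    """Direction of an (unadjusted) size change against a +/- threshold."""

    patient_id: str
    timepoint_months: int
    dimension: str  # "oneD" or "threeD"
    direction: Direction
    change_pct: float
    threshold_pct: float = 20.0


def relative_change(baseline: float, value: float) -> float:
    """Percent change from baseline: ``100 * (value - baseline) / baseline``."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (value - baseline) / baseline


def sphere_volume(diameter: float) -> float:
    """Volume of a sphere with the given diameter (pi * d^3 / 6)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return math.pi * diameter**3 / 6.0


def ellipsoid_volume(r1: float, r2: float, r3: float) -> float:
    """Volume of an ellipsoid with semi-axes r1, r2, r3 (4/3 pi r1 r2 r3)."""
    if r1 <= 0 or r2 <= 0 or r3 <= 0:
        raise ValueError("all semi-axes must be positive")
    return (4.0 / 3.0) * math.pi * r1 * r2 * r3


def derive_sphere_cutoffs(recist: "CutoffSet") -> "CutoffSet":
    """Cube-law conversion of diameter cut-offs to spherical-volume cut-offs.

    A fractional diameter change ``f`` changes a sphere's volume by
    ``(1+f)^3 - 1``; (-30, +20) maps to (-65.7, +72.8).
    """
    pr = 100.0 * ((1.0 + recist.pr_cutoff_pct / 100.0) ** 3 - 1.0)
    pd_ = 100.0 * ((1.0 + recist.pd_cutoff_pct / 100.0) ** 3 - 1.0)
    return CutoffSet(Criteria.SPHERE, pr, pd_)


def invert_sphere_cutoffs(sphere: "CutoffSet") -> "CutoffSet":
    """Cube-root inverse of :func:`derive_sphere_cutoffs`."""
    pr = 100.0 * ((1.0 + sphere.pr_cutoff_pct / 100.0) ** (1.0 / 3.0) - 1.0)
    pd_ = 100.0 * ((1.0 + sphere.pd_cutoff_pct / 100.0) ** (1.0 / 3.0) - 1.0)
    return CutoffSet(Criteria.RECIST, pr, pd_)


RECIST_CUTOFFS = CutoffSet(Criteria.RECIST, -30.0, 20.0)
ELLIPSOID_CUTOFFS = CutoffSet(Criteria.ELLIPSOID, -30.0, 20.0)
SPHERE_CUTOFFS = derive_sphere_cutoffs(RECIST_CUTOFFS)


def _check_matched(summary_t: TimepointSummary, summary_0: TimepointSummary) -> None:
    if summary_t.patient_id != summary_0.patient_id:
        raise ValueError("summaries belong to different patients")
    if summary_t.lesion_ids and summary_0.lesion_ids:
        if summary_t.lesion_ids != summary_0.lesion_ids:
            raise ValueError(
                "mismatched target sets: "
                f"{summary_0.lesion_ids} vs {summary_t.lesion_ids}"
            )


def classify_recist(
    summary_t: TimepointSummary,
    summary_0: TimepointSummary,
    new_lesion: bool = False,
) -> ResponseCall:
    """RECIST 1.1 call from sums of longest diameters.

    PR iff change <= -30%; PD iff change >= +20% or a new lesion appeared
    (the new-lesion PD overrides a size-based PR); SD otherwise.
    Boundaries are inclusive toward the more extreme category.
    """
    _check_matched(summary_t, summary_0)
    change = relative_change(
        summary_0.sum_longest_diameter_mm, summary_t.sum_longest_diameter_mm
    )
    if new_lesion or change >= RECIST_CUTOFFS.pd_cutoff_pct:
        category = Category.PD
    elif change <= RECIST_CUTOFFS.pr_cutoff_pct:
        category = Category.PR
    else:
        category = Category.SD
    return ResponseCall(
        patient_id=summary_t.patient_id,
        timepoint_months=summary_t.timepoint_months,
        criteria=Criteria.RECIST,
        category=category,
        size_change_pct=change,
        new_lesion=new_lesion,
    )


def classify_volume(
    summary_t: TimepointSummary,
    summary_0: TimepointSummary,
    cutoffs: CutoffSet,
    new_lesion: bool = False,
) -> ResponseCall:
    """Volumetric call (3D-sphere or 3D-ellipsoid) from total volumes."""
    if cutoffs.criteria not in (Criteria.SPHERE, Criteria.ELLIPSOID):
        raise ValueError("cutoffs must be for SPHERE or ELLIPSOID")
    _check_matched(summary_t, summary_0)
    change = relative_change(summary_0.total_volume_mL, summary_t.total_volume_mL)
    if new_lesion or change >= cutoffs.pd_cutoff_pct:
        category = Category.PD
    elif change <= cutoffs.pr_cutoff_pct:
        category = Category.PR
    else:
        category = Category.SD
    return ResponseCall(
        patient_id=summary_t.patient_id,
        timepoint_months=summary_t.timepoint_months,
        criteria=cutoffs.criteria,
        category=category,
        size_change_pct=change,
        new_lesion=new_lesion,
    )


def classify_choi(
    summary_t: TimepointSummary,
    summary_0: TimepointSummary,
    new_lesion: bool = False,
    new_nodule: bool = False,
) -> ResponseCall:
    """Choi call from size of diameters plus mean CT density change.

    PR iff (size change <= -10% or mean density change <= -15%) with no new
    lesion or intra-tumoral nodule; PD iff a new lesion/nodule appeared or
    size grew >= +10% without the density PR rule being met; SD otherwise.
    When densities are unavailable the call proceeds on size alone and the
    result is flagged ``density_missing``.
    """
    _check_matched(summary_t, summary_0)
    change = relative_change(
        summary_0.sum_longest_diameter_mm, summary_t.sum_longest_diameter_mm
    )
    density_change = summary_t.mean_relative_density_change_pct
    density_missing = density_change is None
    density_pr = density_change is not None and density_change <= -15.0

    if new_lesion or new_nodule:
        category = Category.PD
    elif change <= -10.0 or density_pr:
        category = Category.PR
    elif change >= 10.0:
        category = Category.PD
    else:
        category = Category.SD
    return ResponseCall(
        patient_id=summary_t.patient_id,
        timepoint_months=summary_t.timepoint_months,
        criteria=Criteria.CHOI,
        category=category,
        size_change_pct=change,
        density_change_pct=density_change,
        new_lesion=new_lesion,
        new_intratumoral_nodule=new_nodule,
        density_missing=density_missing,
    )


def classify_size_change(
    baseline: float,
    value: float,
    threshold_pct: float = 20.0,
    patient_id: str = "",
    timepoint_months: int = 0,
    dimension: str = "oneD",
) -> ChangeClass:
    """Unadjusted change classifier: DECREASE / NO_CHANGE / INCREASE.

    DECREASE iff change <= -threshold, INCREASE iff change >= +threshold
    (boundary inclusive), NO_CHANGE otherwise.
    """
    if threshold_pct <= 0:
        raise ValueError("threshold must be positive")
    change = relative_change(baseline, value)
    if change <= -threshold_pct:
        direction = Direction.DECREASE
    elif change >= threshold_pct:
        direction = Direction.INCREASE
    else:
        direction = Direction.NO_CHANGE
    return ChangeClass(
        patient_id=patient_id,
        timepoint_months=timepoint_months,
        dimension=dimension,
        direction=direction,
        change_pct=change,
        threshold_pct=threshold_pct,
    )
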
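"""Synthetic measurement cohorts with the structure the analysis assumes.

Lesions are prolate spheroids (r1 = r2 <= r3) whose semi-axes evolve
multiplicatively per quarter according to a latent patient class:

* ``isotropic_responder`` — all axes shrink at the same rate, so diameter
  and volume changes obey the cube law;
* ``anisotropic_responder`` — the short axes shrink much faster than the
  longest one, producing large volume changes at small diameter changes
  (the mechanism behind 1D/3D discordance);
* ``stable`` — no true change;
* ``progressor`` — all axes grow; new lesions may appear.

Measured diameters track 2*r3 with small multiplicative (log-normal)
reader noise; measured volumes carry larger 3D noise.  CT density
declines in responders.  Overall survival is exponential with a per-class
hazard, administratively censored.  Given a seed, output is
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .cohort import FOLLOWUP_TIMEPOINTS, MM3_PER_ML, TIMEPOINTS
from .criteria import ellipsoid_volume

__all__ = [
    "CLASSES",
    "SimulationConfig",
    "CohortTables",
    "simulate_cohort",
    "expected_detection_rates",
    "write_cohort_dir",
]

CLASSES = ("isotropic_responder", "anisotropic_responder", "stable", "progressor")


class SimulationConfig(BaseModel):
    """Parameters of the synthetic cohort generator.

    Axis rates are multiplicative per quarter (3 months); noise levels are
    coefficients of variation expressed as fractions (0.032 = 3.2%).
    """

    n_patients: int = Field(default=84, ge=1)
    seed: int = 0

    min_lesions: int = Field(default=1, ge=1)
    max_lesions: int = Field(default=4, ge=1)

    # Baseline geometry: log-normal longest semi-axis, uniform aspect r1/r3.
    baseline_r3_median_mm: float = Field(default=20.0, gt=0)
    baseline_r3_log_sd: float = Field(default=0.4, ge=0)
    baseline_aspect_min: float = Field(default=0.6, gt=0, le=1)
    baseline_aspect_max: float = Field(default=1.0, gt=0, le=1)

    class_probs: dict[str, float] = Field(
        default={
            "isotropic_responder": 0.20,
            "anisotropic_responder": 0.35,
            "stable": 0.30,
            "progressor": 0.15,
        }
    )
    axis_rates: dict[str, tuple[float, float, float]] = Field(
        default={
            "isotropic_responder": (0.90, 0.90, 0.90),
            "anisotropic_responder": (0.75, 0.75, 0.93),
            "stable": (1.0, 1.0, 1.0),
            "progressor": (1.10, 1.10, 1.10),
        }
    )

    density_baseline_mean_HU: float = 75.0
    density_baseline_sd_HU: float = 10.0
    responder_density_drop_pct_per_quarter: float = Field(default=12.0, ge=0, lt=100)
    density_noise_sd_HU: float = Field(default=1.5, ge=0)

    # Measurement noise (CV as a fraction). Reader noise applies to the
    # manual readers, method noise to the semi-automated technique.
    reader_cv_1d: float = Field(default=0.002, ge=0)
    reader_cv_3d: float = Field(default=0.032, ge=0)
    method_cv_1d: float = Field(default=0.0015, ge=0)
    method_cv_3d: float = Field(default=0.096, ge=0)

    # Survival: exponential hazard per month, administrative censoring.
    hazards_per_month: dict[str, float] = Field(
        default={
            "isotropic_responder": 0.010,
            "anisotropic_responder": 0.010,
            "stable": 0.018,
            "progressor": 0.050,
        }
    )
    censor_horizon_months: float = Field(default=84.0, gt=0)

    new_lesion_prob: float = Field(default=0.25, ge=0, le=1)
    new_nodule_prob: float = Field(default=0.10, ge=0, le=1)

    scan_jitter_months: float = Field(default=0.4, ge=0, lt=1.5)
    first_scan_date: date = date(2005, 1, 3)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.max_lesions < self.min_lesions:
            raise ValueError("max_lesions < min_lesions")
        if set(self.class_probs) != set(CLASSES):
            raise ValueError(f"class_probs must cover exactly {CLASSES}")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if set(self.axis_rates) != set(CLASSES):
            raise ValueError(f"axis_rates must cover exactly {CLASSES}")
        if set(self.hazards_per_month) != set(CLASSES):
            raise ValueError(f"hazards_per_month must cover exactly {CLASSES}")
        for rates in self.axis_rates.values():
            if any(r <= 0 for r in rates):
                raise ValueError("axis rates must be positive")
        for h in self.hazards_per_month.values():
            if h <= 0:
                raise ValueError("hazards must be positive")
        if self.baseline_aspect_max < self.baseline_aspect_min:
            raise ValueError("aspect bounds out of order")
        return self


@dataclass
class CohortTables:
    """Simulator output: the cohort CSV schemas plus latent truth."""

    measurements: pd.DataFrame
    scans: pd.DataFrame
    survival: pd.DataFrame
    truth: pd.DataFrame
    events: pd.DataFrame


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit median and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=size))


def _consistent_axes(diameter_mm: float, volume_mL: float) -> tuple[float, float, float]:
    """Semi-axes (ascending) matching a measured diameter and volume.

    r3 is half the measured diameter; r1 = r2 absorb the volume, so the
    ellipsoid-volume invariant of the measurement record holds exactly.
    """
    r3 = diameter_mm / 2.0
    r12 = math.sqrt(volume_mL * MM3_PER_ML * 3.0 / (4.0 * math.pi * r3))
    axes = sorted((r12, r12, r3))
    return (axes[0], axes[1], axes[2])


def simulate_cohort(config: SimulationConfig) -> CohortTables:
    """Generate one synthetic cohort.

    Returns data frames following the cohort CSV schemas (measurements,
    scans, survival) plus an ``events`` table of new-lesion/new-nodule
    flags and a ``truth`` table with latent classes and noise-free lesion
    states for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    class_names = list(CLASSES)
    probs = np.array([config.class_probs[c] for c in class_names])

    meas_rows: list[dict] = []
    scan_rows: list[dict] = []
    surv_rows: list[dict] = []
    truth_rows: list[dict] = []
    event_rows: list[dict] = []

    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        cls = class_names[rng.choice(len(class_names), p=probs)]
        rates = np.array(config.axis_rates[cls], dtype=float)
        n_lesions = int(rng.integers(config.min_lesions, config.max_lesions + 1))

        r3_0 = config.baseline_r3_median_mm * np.exp(
            rng.normal(0.0, config.baseline_r3_log_sd, size=n_lesions)
        )
        aspect = rng.uniform(
            config.baseline_aspect_min, config.baseline_aspect_max, size=n_lesions
        )
        base_axes = np.stack([aspect * r3_0, aspect * r3_0, r3_0], axis=1)
        base_density = rng.normal(
            config.density_baseline_mean_HU,
            config.density_baseline_sd_HU,
            size=n_lesions,
        )

        responder = cls in ("isotropic_responder", "anisotropic_responder")
        drop = config.responder_density_drop_pct_per_quarter / 100.0

        for tp in TIMEPOINTS:
            quarters = tp / 3.0
            axes_t = base_axes * rates**quarters
            axes_t = np.sort(axes_t, axis=1)  # longest measured axis may switch
            density_t = base_density * (
                (1.0 - drop) ** quarters if responder else 1.0
            )

            for j in range(n_lesions):
                lid = f"{pid}-L{j + 1}"
                r1, r2, r3 = axes_t[j]
                true_vol_mL = ellipsoid_volume(r1, r2, r3) / MM3_PER_ML
                true_d = 2.0 * r3
                truth_rows.append(
                    {
                        "patient_id": pid,
                        "lesion_id": lid,
                        "timepoint_months": tp,
                        "true_class": cls,
                        "r1_mm": r1,
                        "r2_mm": r2,
                        "r3_mm": r3,
                        "true_volume_mL": true_vol_mL,
                        "true_density_HU": density_t[j],
                    }
                )
                # Manual method: two independent readers, no densities.
                for reader in ("R1", "R2"):
                    d = true_d * _lognormal_factor(rng, config.reader_cv_1d)
                    v = true_vol_mL * _lognormal_factor(rng, config.reader_cv_3d)
                    ax = _consistent_axes(d, v)
                    meas_rows.append(
                        {
                            "patient_id": pid,
                            "lesion_id": lid,
                            "timepoint_months": tp,
                            "method": "manual",
                            "reader_id": reader,
                            "longest_diameter_mm": d,
                            "volume_mL": v,
                            "mean_density_HU": None,
                            "r1_mm": ax[0],
                            "r2_mm": ax[1],
                            "r3_mm": ax[2],
                        }
                    )
                # Semi-automated method: one pass, carries densities.
                d = true_d * _lognormal_factor(rng, config.method_cv_1d)
                v = true_vol_mL * _lognormal_factor(rng, config.method_cv_3d)
                ax = _consistent_axes(d, v)
                hu = density_t[j] + rng.normal(0.0, config.density_noise_sd_HU)
                meas_rows.append(
                    {
                        "patient_id": pid,
                        "lesion_id": lid,
                        "timepoint_months": tp,
                        "method": "semiauto",
                        "reader_id": "S1",
                        "longest_diameter_mm": d,
                        "volume_mL": v,
                        "mean_density_HU": hu,
                        "r1_mm": ax[0],
                        "r2_mm": ax[1],
                        "r3_mm": ax[2],
                    }
                )

            months = tp + (
                rng.uniform(-config.scan_jitter_months, config.scan_jitter_months)
                if tp > 0
                else 0.0
            )
            scan_rows.append(
                {
                    "patient_id": pid,
                    "scan_date": (
                        config.first_scan_date + timedelta(days=round(months * 30.44))
                    ).isoformat(),
                    "months_from_first_imatinib": max(months, 0.0),
                }
            )

        # New-lesion / nodule events (progressors only), cumulative flags.
        new_lesion = False
        new_nodule = False
        for tp in FOLLOWUP_TIMEPOINTS:
            if cls == "progressor":
                new_lesion = new_lesion or (rng.random() < config.new_lesion_prob)
                new_nodule = new_nodule or (rng.random() < config.new_nodule_prob)
            event_rows.append(
                {
                    "patient_id": pid,
                    "timepoint_months": tp,
                    "new_lesion": int(new_lesion),
                    "new_nodule": int(new_nodule),
                }
            )

        os_true = rng.exponential(1.0 / config.hazards_per_month[cls])
        event = os_true <= config.censor_horizon_months
        surv_rows.append(
            {
                "patient_id": pid,
                "os_months_from_first_imatinib": min(
                    os_true, config.censor_horizon_months
                ),
                "event": int(event),
            }
        )

    return CohortTables(
        measurements=pd.DataFrame(meas_rows),
        scans=pd.DataFrame(scan_rows),
        survival=pd.DataFrame(surv_rows),
        truth=pd.DataFrame(truth_rows),
        events=pd.DataFrame(event_rows),
    )


def write_cohort_dir(tables: CohortTables, directory: str | Path) -> None:
    """Write the simulated tables as the cohort CSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables.measurements.to_csv(directory / "measurements.csv", index=False)
    tables.scans.to_csv(directory / "scans.csv", index=False)
    tables.survival.to_csv(directory / "survival.csv", index=False)
    tables.events.to_csv(directory / "events.csv", index=False)
    tables.truth.to_csv(directory / "truth.csv", index=False)


def expected_detection_rates(
    config: SimulationConfig, threshold_pct: float = 20.0
) -> dict[str, dict[int, dict]]:
    """Noise-free detection truth implied by the configured axis rates.

    For every class and follow-up timepoint: the true diameter and volume
    percent changes, and whether a >= ``threshold_pct`` change would be
    flagged in 1D and in 3D.  Assumes the longest-axis rate is the largest
    of the three (true for the defaults), so the measured diameter tracks
    the third axis throughout.
    """
    out: dict[str, dict[int, dict]] = {}
    for cls in CLASSES:
        rates = config.axis_rates[cls]
        if max(rates) != rates[2]:
            raise ValueError(
                f"class {cls!r}: longest-axis rate must be the largest "
                "for the closed-form detection rates to hold"
            )
        out[cls] = {}
        for tp in FOLLOWUP_TIMEPOINTS:
            q = tp / 3.0
            d_change = 100.0 * (rates[2] ** q - 1.0)
            v_change = 100.0 * (math.prod(r**q for r in rates) - 1.0)
            out[cls][tp] = {
                "diameter_change_pct": d_change,
                "volume_change_pct": v_change,
                "detect_1d": abs(d_change) >= threshold_pct,
                "detect_3d": abs(v_change) >= threshold_pct,
                "decrease_1d": d_change <= -threshold_pct,
                "decrease_3d": v_change <= -threshold_pct,
            }
    return out


def expected_decrease_rate_3d(
    config: SimulationConfig, timepoint_months: int, threshold_pct: float = 20.0
) -> float:
    """Cohort-level probability of a true 3D decrease >= threshold."""
    rates = expected_detection_rates(config, threshold_pct)
    return sum(
        config.class_probs[cls] * float(rates[cls][timepoint_months]["decrease_3d"])
        for cls in CLASSES
    )
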
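"""Synthetic patient-cohort and mouse-experiment generators.

The clinical and animal data the model was originally calibrated against are
not publicly deposited, so these generators emulate their structure for
end-to-end testing of the calibration and growth-curve pipelines:

* a patient cohort with per-patient blood volume fraction (log-uniform over
  the clinically observed 1e-3 .. 1e-1 range), kill fraction generated from
  the bolus law plus additive Gaussian measurement noise (truncated to
  [0, 1]), and contrast-CT Hounsfield Units tied to BVF by a linear map with
  ~25% multiplicative coefficient of variation (physiology and
  contrast-injection variability);
* a four-arm mouse experiment (control + free drug + two particle sizes,
  10 mice per arm): control volumes grow linearly at Lambda ~ 70 mm^3/day
  from initial volumes of 100-200 mm^3; treated volumes are the control
  trajectory scaled by the viable fraction 1 - f(t), where f rises
  quadratically and plateaus at Lambda_k / Lambda after `plateau_day` days.
  This makes the post-plateau net growth rate exactly Lambda - Lambda_k and
  preserves death-rate ratios in the plateau kill fractions.

Randomness is split per patient/mouse by counter so adding a record never
perturbs earlier ones, and per-mouse streams are shared across arms (common
random numbers): a zero-death-rate arm is byte-identical to the control arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import ParameterError
from .bolus_reference import BolusModel, CohortRecord, default_bolus_table
from .nanocarrier_flux import MouseArm

COHORT_COLUMNS = ["patient_id", "bvf", "bvf_sd", "f_kill", "f_kill_sd", "hu", "hu_sd"]


@dataclass(frozen=True)
class CohortGenSpec:
    """Ground truth and noise settings for the synthetic patient cohort."""

    n_patients: int = 21
    r_b: float = 15.83
    L: float = 155.06
    bvf_range: tuple[float, float] = (1e-3, 1e-1)
    noise_sd_fkill: float = 0.05
    ct_slope: float = 1e-3
    ct_intercept: float = 0.0
    ct_cv: float = 0.25
    hu_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 3:
            raise ParameterError(f"need n_patients >= 3, got {self.n_patients}")
        lo, hi = self.bvf_range
        if not (0 < lo < hi < 1):
            raise ParameterError(f"bvf_range must be within (0, 1) and ascending, got {self.bvf_range}")
        if self.noise_sd_fkill < 0 or self.ct_cv < 0:
            raise ParameterError("noise levels must be >= 0")
        if not (0 <= self.hu_missing_rate < 1):
            raise ParameterError(f"hu_missing_rate must be in [0, 1), got {self.hu_missing_rate}")


@dataclass(frozen=True)
class MouseGenSpec:
    """Ground truth for the synthetic four-arm tumor-growth experiment.

    ``death_rates`` maps treated-arm labels to net volumetric death rates
    Lambda_k (mm^3/day); the control arm is added automatically.  Defaults
    follow the companion experiment: control growth ~70 mm^3/day, particle
    arms Lambda_k ~ 35 mm^3/day (plateau kill ~0.5) and a free-drug arm at
    one third of that, kill plateau reached ~4 days after treatment onset.
    """

    n_per_arm: int = 10
    v0_range: tuple[float, float] = (100.0, 200.0)
    growth_rate: float = 70.0
    death_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "free-dox": 35.0 / 3.0,
            "iNPG/pDox-1.0": 35.0,
            "iNPG/pDox-2.6": 35.0,
        }
    )
    plateau_day: float = 4.0
    measurement_days: tuple[float, ...] = (0.0, 3.0, 7.0, 11.0, 14.0, 17.0)
    noise_sd: float = 20.0
    seed: int = 0
    control_label: str = "PBS"

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ParameterError("need n_per_arm >= 1")
        if not (0 < self.v0_range[0] <= self.v0_range[1]):
            raise ParameterError(f"v0_range must be positive ascending, got {self.v0_range}")
        if self.growth_rate <= 0 or self.plateau_day <= 0 or self.noise_sd < 0:
            raise ParameterError("growth_rate and plateau_day must be > 0, noise_sd >= 0")
        days = np.asarray(self.measurement_days, float)
        if days.size < 2 or np.any(np.diff(days) <= 0):
            raise ParameterError(f"measurement_days must be >= 2 ascending values, got {days}")
        for label, lk in self.death_rates.items():
            if lk < 0:
                raise ParameterError(f"death rate for {label!r} must be >= 0, got {lk}")
            if lk >= self.growth_rate:
                raise ParameterError(
                    f"death rate for {label!r} must stay below the control growth rate "
                    f"(plateau kill Lambda_k/Lambda < 1), got {lk} >= {self.growth_rate}"
                )


def gen_cohort(spec: CohortGenSpec, model: BolusModel | None = None) -> list[CohortRecord]:
    """Generate a reproducible synthetic cohort from the bolus law.

    With zero noise the records lie exactly on the bolus curve and the CT
    line.  ``model`` defaults to the shared bolus surrogate; pass the same
    callable to `calibrate_cohort` for exact closed-loop recovery.
    """
    if model is None:
        model = default_bolus_table()
    lo, hi = spec.bvf_range
    records = []
    for i in range(spec.n_patients):
        rng = np.random.default_rng([spec.seed, i])
        bvf = float(math.exp(rng.uniform(math.log(lo), math.log(hi))))
        f_true = model(bvf, spec.r_b, spec.L)
        f_obs = float(np.clip(f_true + spec.noise_sd_fkill * rng.standard_normal(), 0.0, 1.0))
        hu_true = (bvf - spec.ct_intercept) / spec.ct_slope
        hu_obs = float(hu_true * (1.0 + spec.ct_cv * rng.standard_normal()))
        has_hu = rng.uniform() >= spec.hu_missing_rate
        records.append(
            CohortRecord(
                patient_id=f"P{i + 1:03d}",
                bvf=bvf,
                f_kill=f_obs,
                bvf_sd=0.0,
                f_kill_sd=spec.noise_sd_fkill,
                hu=hu_obs if has_hu else None,
                hu_sd=spec.ct_cv * abs(hu_true) if has_hu else None,
            )
        )
    return records


def cohort_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "bvf": r.bvf,
                "bvf_sd": r.bvf_sd,
                "f_kill": r.f_kill,
                "f_kill_sd": r.f_kill_sd,
                "hu": r.hu,
                "hu_sd": r.hu_sd,
            }
            for r in records
        ],
        columns=COHORT_COLUMNS,
    )


def write_cohort_csv(records: Sequence[CohortRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False, float_format="%.9g")


def read_cohort_csv(path: str | Path) -> list[CohortRecord]:
    df = pd.read_csv(path)
    required = {"patient_id", "bvf", "f_kill"}
    if not required.issubset(df.columns):
        raise ParameterError(f"cohort CSV must have columns {sorted(required)}, got {list(df.columns)}")
    records = []
    for _, row in df.iterrows():
        hu = row.get("hu")
        hu_sd = row.get("hu_sd")
        records.append(
            CohortRecord(
                patient_id=str(row["patient_id"]),
                bvf=float(row["bvf"]),
                f_kill=float(row["f_kill"]),
                bvf_sd=float(row.get("bvf_sd", 0.0) or 0.0),
                f_kill_sd=float(row.get("f_kill_sd", 0.0) or 0.0),
                hu=None if pd.isna(hu) else float(hu),
                hu_sd=None if hu_sd is None or pd.isna(hu_sd) else float(hu_sd),
            )
        )
    return records


def _kill_fraction_trajectory(t: np.ndarray, Lambda: float, Lambda_k: float, plateau_day: float) -> np.ndarray:
    """Quadratic onset to a plateau at Lambda_k / Lambda."""
    f_plateau = Lambda_k / Lambda
    return f_plateau * np.minimum(1.0, (t / plateau_day) ** 2)


def gen_mouse_arms(spec: MouseGenSpec) -> list[MouseArm]:
    """Generate control + treated arms; control arm is listed first."""
    days = np.asarray(spec.measurement_days, float)
    arm_rates = {spec.control_label: 0.0, **spec.death_rates}
    arms = []
    for label, lk in arm_rates.items():
        volumes = np.empty((spec.n_per_arm, days.size))
        for m in range(spec.n_per_arm):
            # per-mouse stream shared across arms: Lambda_k=0 reproduces control exactly
            rng = np.random.default_rng([spec.seed, m])
            v0 = rng.uniform(*spec.v0_range)
            noise = spec.noise_sd * rng.standard_normal(days.size)
            clean = (v0 + spec.growth_rate * days) * (
                1.0 - _kill_fraction_trajectory(days, spec.growth_rate, lk, spec.plateau_day)
            )
            volumes[m] = np.maximum(clean + noise, 1.0)
        arms.append(MouseArm(label=label, days=days, volumes=volumes))
    return arms
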
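"""Constant-flux nano-carrier kill law and in-vivo growth-curve arithmetic.

When drug-loaded particles lodged in the tumor vasculature release drug at a
constant mass flux F (g/day), the tumor volume obeys

    V_T(t) = V_T0 - (1/2) lambda_k F t^2,

so the kill fraction grows quadratically in time,

    f_kill(t) = F lambda_k t^2 / (2 V_T0),

until release tapers or the tumor is exhausted.  With the net volumetric
death rate Lambda_k = lambda_k * F * t (mm^3/day, measurable as the control
growth rate minus the treated net growth rate), the same law reads
f_kill = Lambda_k t / (2 V_T0), and the time to reach a target kill is
t_kill = 2 V_T0 f_target / Lambda_k.

The module also carries the companion analysis of tumor-volume time series
from a treatment experiment: linear growth-rate fits per arm and the
control-normalized kill-fraction series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import ParameterError


@dataclass(frozen=True)
class FluxKillParams:
    """Constant drug flux F (g/day), kill rate lambda_k (1/(g*day)), and
    initial tumor volume V_T0 (mm^3)."""

    F: float
    lambda_k: float
    V_T0: float

    def __post_init__(self) -> None:
        for name in ("F", "lambda_k", "V_T0"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class GrowthRates:
    """Linear growth rates (mm^3/day): control, treated, and their difference."""

    Lambda: float
    Lambda_treated: float | None = None
    Lambda_k: float | None = None

    def __post_init__(self) -> None:
        if self.Lambda_treated is not None and self.Lambda_k is not None:
            if abs(self.Lambda_k - (self.Lambda - self.Lambda_treated)) > 1e-9:
                raise ParameterError(
                    "Lambda_k must equal Lambda - Lambda_treated when both are given"
                )


@dataclass(frozen=True)
class MouseArm:
    """Tumor volumes (mm^3) for one treatment arm: shape (n_mice, n_days).

    ``days`` are post-treatment days; ``day_offset`` records the
    post-inoculation day of treatment onset (day 14 in the companion
    experiment's convention).
    """

    label: str
    days: np.ndarray
    volumes: np.ndarray
    day_offset: float = 14.0

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        vols = np.atleast_2d(np.asarray(self.volumes, dtype=float))
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "volumes", vols)
        if days.ndim != 1 or np.any(np.diff(days) <= 0):
            raise ParameterError(f"days must be strictly ascending, got {days}")
        if vols.shape[1] != days.size:
            raise ParameterError(
                f"volumes shape {vols.shape} does not match {days.size} measurement days"
            )
        if np.any(vols <= 0) or not np.all(np.isfinite(vols)):
            raise ParameterError("volumes must be positive and finite")

    def mean_volumes(self) -> np.ndarray:
        """Arithmetic mean across mice per measurement day."""
        return self.volumes.mean(axis=0)


def quadratic_fkill(p: FluxKillParams, t: float) -> float:
    """Quadratic-in-time kill fraction, capped at 1 (with a warning) beyond
    the validity range of the constant-flux law."""
    if t < 0:
        raise ParameterError(f"t must be >= 0, got {t}")
    f = p.F * p.lambda_k * t**2 / (2.0 * p.V_T0)
    if f > 1:
        warnings.warn(
            f"constant-flux law gives f_kill={f:.3g} > 1 at t={t}; capped at 1 "
            "(outside the law's validity range)",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    return float(f)


def quadratic_fkill_rate(Lambda_k: float, V_T0: float, t: float) -> float:
    """Kill fraction in the measured-rate form f = Lambda_k * t / (2 V_T0),
    via the identity lambda_k = Lambda_k / (F t)."""
    if t < 0:
        raise ParameterError(f"t must be >= 0, got {t}")
    if Lambda_k <= 0 or V_T0 <= 0:
        raise ParameterError("Lambda_k and V_T0 must be positive")
    f = Lambda_k * t / (2.0 * V_T0)
    if f > 1:
        warnings.warn(
            f"rate form gives f_kill={f:.3g} > 1 at t={t}; capped at 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    return float(f)


def time_to_kill(f_target: float, Lambda_k: float, V_T0: float) -> float:
    """Days to reach a target kill fraction: t = 2 V_T0 f_target / Lambda_k."""
    if not (0 < f_target <= 1):
        raise ParameterError(f"f_target must be in (0, 1], got {f_target}")
    if Lambda_k <= 0:
        raise ParameterError(f"Lambda_k must be positive, got {Lambda_k}")
    if V_T0 <= 0:
        raise ParameterError(f"V_T0 must be positive, got {V_T0}")
    return 2.0 * V_T0 * f_target / Lambda_k


def total_dose(dose_per_mass_mg_per_kg: float, body_mass_g: float, n_administrations: int = 1) -> float:
    """Total administered drug mass in grams.

    ``dose_per_mass_mg_per_kg`` in mg per kg body weight, ``body_mass_g`` in
    grams; e.g. 6 mg/kg for a 20 g mouse gives 1.2e-4 g.
    """
    if dose_per_mass_mg_per_kg < 0 or body_mass_g <= 0 or n_administrations < 1:
        raise ParameterError("dose must be >= 0, body mass > 0, administrations >= 1")
    return dose_per_mass_mg_per_kg * (body_mass_g / 1000.0) / 1000.0 * n_administrations


def fit_linear_growth(arm: MouseArm, day_range: tuple[float, float] | None = None) -> float:
    """OLS slope (mm^3/day) of the arm's mean volume against day.

    ``day_range`` restricts the fit window (inclusive), e.g. to the
    pre-plateau or post-plateau phase.
    """
    days = arm.days
    mean_v = arm.mean_volumes()
    if day_range is not None:
        mask = (days >= day_range[0]) & (days <= day_range[1])
        days, mean_v = days[mask], mean_v[mask]
    if days.size < 2:
        raise ParameterError(f"growth fit needs >= 2 time points, got {days.size}")
    slope, _ = np.polyfit(days, mean_v, 1)
    return float(slope)


def net_death_rate(control_rate: float, treated_rate: float) -> float:
    """Net volumetric death rate Lambda_k = control growth - treated net growth."""
    return control_rate - treated_rate


def mouse_fkill_series(treated: MouseArm, control: MouseArm) -> pd.DataFrame:
    """Kill-fraction time series from control-normalized tumor volumes.

    Each arm's mean volume is first normalized by its own initial volume;
    the treated fold-change is then divided by the control fold-change, and
    f_kill = 1 - that ratio.  Day 0 (treatment onset) gives 0 by construction,
    and the result is invariant to rescaling all volumes by a common factor.
    """
    if treated.days.size != control.days.size or np.any(treated.days != control.days):
        missing = sorted(set(control.days.tolist()) ^ set(treated.days.tolist()))
        raise ParameterError(f"treated and control arms measured on different days: {missing}")
    fold_t = treated.mean_volumes() / treated.mean_volumes()[0]
    fold_c = control.mean_volumes() / control.mean_volumes()[0]
    f = 1.0 - fold_t / fold_c
    return pd.DataFrame({"day": treated.days, "f_kill": f})


def read_mouse_csv(path: str | Path) -> list[MouseArm]:
    """Read arms from a long-format CSV with columns
    arm, mouse_id, day_post_treatment, volume_mm3."""
    df = pd.read_csv(path)
    required = {"arm", "mouse_id", "day_post_treatment", "volume_mm3"}
    if not required.issubset(df.columns):
        raise ParameterError(f"mouse CSV must have columns {sorted(required)}, got {list(df.columns)}")
    arms = []
    for label, sub in df.groupby("arm", sort=False):
        wide = sub.pivot(index="mouse_id", columns="day_post_treatment", values="volume_mm3")
        wide = wide.sort_index(axis=1)
        if wide.isna().any().any():
            raise ParameterError(f"arm {label!r} has missing volume measurements")
        arms.append(MouseArm(label=str(label), days=wide.columns.to_numpy(float), volumes=wide.to_numpy()))
    return arms


def write_mouse_csv(arms: Sequence[MouseArm], path: str | Path) -> None:
    rows = []
    for arm in arms:
        for m in range(arm.volumes.shape[0]):
            for j, day in enumerate(arm.days):
                rows.append(
                    {
                        "arm": arm.label,
                        "mouse_id": f"{arm.label}-{m + 1:02d}",
                        "day_post_treatment": day,
                        "volume_mm3": arm.volumes[m, j],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")
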
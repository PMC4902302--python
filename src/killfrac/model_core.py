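"""Parameter containers and the dimensional <-> dimensionless transforms.

The model describes drug diffusing out of a cylindrical blood vessel into the
surrounding tumor tissue while killing cells in proportion to cumulative drug
exposure.  Two composite scales reduce the dimensional problem to a
parameter-free system of governing equations:

* ``L = sqrt(D / (phi0 * lambda_u))`` — the diffusion penetration length, the
  distance over which drug concentration decays into drug-consuming tissue;
* ``T = (lambda_k * lambda_u * phi0 * sigma0) ** -0.5`` — the characteristic
  time of drug-induced apoptotic cycles, used as the simulation time unit.

After nondimensionalization only two parameters remain, both entering through
the boundary conditions: the dimensionless vessel radius ``r_b / L`` and the
blood volume fraction BVF, which fixes the outer radius of the annular tissue
volume influenced by the vessel at ``r_b / (L * sqrt(BVF))``.

Units: dimensional inputs are micrometres and days; unit conversion is the
caller's job.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass
from pathlib import Path


class ParameterError(ValueError):
    """An input parameter violates its physical constraints."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value <= 0:
            raise ParameterError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class DimensionalParams:
    """Full dimensional parameter set (micrometre / day units).

    Attributes
    ----------
    D : float
        Drug diffusivity (um^2/day).
    lambda_u : float
        Per-volume cellular drug uptake rate (1/day per unit volume fraction).
    lambda_k : float
        Cell death rate per unit cumulative drug concentration.
    sigma0 : float
        Drug concentration held at the vessel wall (arbitrary but fixed units).
    phi0 : float
        Initial tumor volume fraction, in (0, 1].
    r_b : float
        Blood vessel radius (um).
    BVF : float
        Blood volume fraction, in (0, 1).
    """

    D: float
    lambda_u: float
    lambda_k: float
    sigma0: float
    phi0: float
    r_b: float
    BVF: float

    def __post_init__(self) -> None:
        _require_positive(
            D=self.D,
            lambda_u=self.lambda_u,
            lambda_k=self.lambda_k,
            sigma0=self.sigma0,
            phi0=self.phi0,
            r_b=self.r_b,
            BVF=self.BVF,
        )
        if self.phi0 > 1:
            raise ParameterError(f"phi0 must be <= 1, got {self.phi0}")
        if self.BVF >= 1:
            raise ParameterError(
                f"BVF must be < 1 (the influenced tissue volume is undefined otherwise), got {self.BVF}"
            )


@dataclass(frozen=True)
class Scales:
    """Characteristic length and time scales of the dimensionless problem.

    ``L`` in micrometres, ``T`` in days.
    """

    L: float
    T: float

    def __post_init__(self) -> None:
        _require_positive(L=self.L, T=self.T)


@dataclass(frozen=True)
class DimensionlessParams:
    """The two parameters that fully determine the dimensionless problem.

    ``R_outer`` (the dimensionless radius of the influenced tissue volume,
    ``rb_over_L / sqrt(BVF)``) is derived, so the geometric identity holds
    exactly by construction.
    """

    rb_over_L: float
    BVF: float

    def __post_init__(self) -> None:
        _require_positive(rb_over_L=self.rb_over_L, BVF=self.BVF)
        if self.BVF >= 1:
            raise ParameterError(
                f"BVF must be < 1 (the influenced tissue volume is undefined otherwise), got {self.BVF}"
            )

    @property
    def R_outer(self) -> float:
        return self.rb_over_L / math.sqrt(self.BVF)


def derive_scales(p: DimensionalParams) -> Scales:
    """Compute the diffusion penetration length L and apoptotic-cycle time T."""
    L = math.sqrt(p.D / (p.phi0 * p.lambda_u))
    T = (p.lambda_k * p.lambda_u * p.phi0 * p.sigma0) ** -0.5
    return Scales(L=L, T=T)


def to_dimensionless(p: DimensionalParams) -> DimensionlessParams:
    """Reduce a dimensional parameter set to (r_b/L, BVF)."""
    scales = derive_scales(p)
    return DimensionlessParams(rb_over_L=p.r_b / scales.L, BVF=p.BVF)


_DIMENSIONAL_KEYS = {"D", "lambda_u", "lambda_k", "sigma0", "phi0", "r_b", "BVF"}
_DIMENSIONLESS_KEYS = {"rb_over_L", "BVF"}


def load_params(path: str | Path) -> DimensionalParams | DimensionlessParams:
    """Load parameters from a flat TOML file.

    The file must contain exactly the keys of one of the two parameter sets:
    ``D, lambda_u, lambda_k, sigma0, phi0, r_b, BVF`` (dimensional) or
    ``rb_over_L, BVF`` (dimensionless).  Unknown keys are rejected.
    """
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    keys = set(data)
    if keys == _DIMENSIONAL_KEYS:
        return DimensionalParams(**data)
    if keys == _DIMENSIONLESS_KEYS:
        return DimensionlessParams(**data)
    raise ParameterError(
        f"config keys {sorted(keys)} match neither the dimensional set "
        f"{sorted(_DIMENSIONAL_KEYS)} nor the dimensionless set {sorted(_DIMENSIONLESS_KEYS)}"
    )
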
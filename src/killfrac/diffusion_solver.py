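"""Quasi-steady radial drug field in the annulus around a blood vessel.

Solves the dimensionless modified-Helmholtz problem

    (1/r') d/dr' ( r' d(sigma')/dr' ) - phi' * sigma' = 0

on ``r' in [rb_over_L, R_outer]`` with a unit Dirichlet condition at the
vessel wall and a zero-flux condition at the outer edge of the influenced
tissue volume.  Drug transport is much faster than cell death, so the field
relaxes instantly to the steady state set by the current cell density phi'.

Discretization is a conservative (flux-form) second-order central scheme on a
uniform grid; the outer Neumann condition uses a second-order ghost-node
reflection.  The resulting tridiagonal system is strictly diagonally dominant
and solved in a single banded-elimination pass.

For spatially uniform phi' = 1 the problem has a modified-Bessel closed form
(`analytic_uniform_sigma`) used as an independent oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded
from scipy.special import i0, i1, k0, k1

from .model_core import DimensionlessParams, ParameterError


class SolverError(RuntimeError):
    """The linear system could not be solved reliably."""


@dataclass(frozen=True)
class RadialGrid:
    """Uniform radial grid from the vessel wall to the influenced-volume edge."""

    rb_over_L: float
    R_outer: float
    n_nodes: int
    r_prime: np.ndarray = field(init=False, repr=False, compare=False)
    dr: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_nodes < 16:
            raise ParameterError(f"n_nodes must be >= 16, got {self.n_nodes}")
        if not (0 < self.rb_over_L < self.R_outer):
            raise ParameterError(
                f"need 0 < rb_over_L < R_outer, got {self.rb_over_L}, {self.R_outer}"
            )
        r = np.linspace(self.rb_over_L, self.R_outer, self.n_nodes)
        object.__setattr__(self, "r_prime", r)
        object.__setattr__(self, "dr", float(r[1] - r[0]))

    @classmethod
    def from_params(cls, dp: DimensionlessParams, n_nodes: int = 2001) -> "RadialGrid":
        return cls(rb_over_L=dp.rb_over_L, R_outer=dp.R_outer, n_nodes=n_nodes)


@dataclass(frozen=True)
class DrugField:
    """Dimensionless drug concentration per grid node (1 at the vessel wall)."""

    sigma_prime: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma_prime, dtype=float)
        object.__setattr__(self, "sigma_prime", s)


def _banded_matrix(grid: RadialGrid, phi_prime: np.ndarray):
    """Assemble the tridiagonal system for the unknown nodes 1..n-1.

    The Dirichlet node is eliminated (its unit value moves to the right-hand
    side) so the boundary value is exact, not subject to elimination
    round-off.  Layout per `solve_banded`.
    """
    n = grid.n_nodes
    r = grid.r_prime
    dr2 = grid.dr**2
    m = n - 1  # unknowns: nodes 1..n-1
    ab = np.zeros((3, m))
    rhs = np.zeros(m)

    i = np.arange(1, n - 1)
    r_minus = 0.5 * (r[i] + r[i - 1])
    r_plus = 0.5 * (r[i] + r[i + 1])
    lower = r_minus / (r[i] * dr2)
    upper = r_plus / (r[i] * dr2)
    j = i - 1  # position within the reduced system
    ab[2, j[:-1]] = lower[1:]  # sub-diagonal (lower coupling of nodes 2..n-2)
    ab[0, j + 1] = upper  # super-diagonal
    ab[1, j] = -(lower + upper) - phi_prime[i]
    rhs[0] = -lower[0] * 1.0  # known sigma'[0] = 1

    # outer zero flux via ghost reflection sigma[n] = sigma[n-2]
    ab[2, m - 2] = 2.0 / dr2
    ab[1, m - 1] = -2.0 / dr2 - phi_prime[n - 1]
    return ab, rhs


def solve_steady_drug(grid: RadialGrid, phi_prime: np.ndarray) -> DrugField:
    """Solve the quasi-steady drug field for a given cell-density profile.

    Parameters
    ----------
    grid : RadialGrid
    phi_prime : ndarray
        Per-node tumor volume fraction normalized by its initial value,
        each entry in [0, 1].

    Returns
    -------
    DrugField
        Satisfies ``sigma'[0] == 1`` exactly and ``0 < sigma' <= 1``
        everywhere (discrete maximum principle).
    """
    phi = np.asarray(phi_prime, dtype=float)
    if phi.shape != (grid.n_nodes,):
        raise ParameterError(
            f"phi_prime has shape {phi.shape}, expected ({grid.n_nodes},)"
        )
    if not np.all(np.isfinite(phi)) or phi.min() < 0 or phi.max() > 1:
        raise ParameterError("phi_prime must be finite and within [0, 1] at every node")

    ab, rhs = _banded_matrix(grid, phi)
    try:
        interior = solve_banded((1, 1), ab, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - should not occur
        raise SolverError(
            f"banded solve failed on grid n={grid.n_nodes}, "
            f"[{grid.rb_over_L}, {grid.R_outer}]: {exc}"
        ) from exc
    if not np.all(np.isfinite(interior)):
        raise SolverError("non-finite drug field returned; system ill-conditioned")
    sigma = np.empty(grid.n_nodes)
    sigma[0] = 1.0
    sigma[1:] = interior
    return DrugField(sigma_prime=sigma)


def steady_residual(grid: RadialGrid, phi_prime: np.ndarray, sigma_prime: np.ndarray) -> np.ndarray:
    """Discrete residual of the steady equation at interior nodes (diagnostic)."""
    r = grid.r_prime
    dr2 = grid.dr**2
    s = np.asarray(sigma_prime, dtype=float)
    phi = np.asarray(phi_prime, dtype=float)
    i = np.arange(1, grid.n_nodes - 1)
    r_minus = 0.5 * (r[i] + r[i - 1])
    r_plus = 0.5 * (r[i] + r[i + 1])
    lap = (r_plus * (s[i + 1] - s[i]) - r_minus * (s[i] - s[i - 1])) / (r[i] * dr2)
    return lap - phi[i] * s[i]


def analytic_uniform_sigma(r, a: float, R: float):
    """Closed-form steady drug profile for uniform cell density (phi' = 1).

    The modified-Helmholtz equation in an annulus with unit Dirichlet inner
    and zero-flux outer boundary has the solution

        sigma'(r) = [K1(R) I0(r) + I1(R) K0(r)] / [K1(R) I0(a) + I1(R) K0(a)].

    Acts as an independent oracle for the finite-difference solver.
    """
    if a >= R:
        raise ParameterError(f"need inner radius a < outer radius R, got a={a}, R={R}")
    r = np.asarray(r, dtype=float)
    if np.any(r < a) or np.any(r > R * (1 + 1e-12)):
        raise ParameterError("r must lie within [a, R]")
    num = k1(R) * i0(r) + i1(R) * k0(r)
    den = k1(R) * i0(a) + i1(R) * k0(a)
    out = num / den
    return float(out) if out.ndim == 0 else out


def field_to_frame(grid: RadialGrid, sigma_prime: np.ndarray, phi_prime: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "r_prime": grid.r_prime,
            "sigma_prime": np.asarray(sigma_prime, dtype=float),
            "phi_prime": np.asarray(phi_prime, dtype=float),
        }
    )


def write_field_csv(
    path: str | Path,
    grid: RadialGrid,
    sigma_prime: np.ndarray,
    phi_prime: np.ndarray,
    metadata: dict | None = None,
) -> None:
    """Dump a radial field snapshot as CSV, optionally with a JSON sidecar."""
    frame = field_to_frame(grid, sigma_prime, phi_prime)
    frame.to_csv(path, index=False, float_format="%.9g")
    if metadata is not None:
        Path(path).with_suffix(".json").write_text(json.dumps(metadata, indent=2, sort_keys=True))
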
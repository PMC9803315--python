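"""Explicit-Euler integration of the uncontrolled reaction–diffusion models.

The nonlinear path re-evaluates the TGF-beta Hill factor at every step
from the supplied schedule; the linear path (used by the control
modules) freezes the homeostatic factors into the assembled system.  For
spatially uniform initial data and zero-flux boundaries the PDE
trajectory collapses onto the single-node ODE at every node, which the
tests exploit as an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from .discretization import (
    Grid2D,
    LinearSystem,
    assemble_fibroblast_system,
    assemble_myofibroblast_system,
    build_grid,
    cfl_max_step,
)
from .parameters import (
    FibroblastParams,
    HomogenizationConstants,
    MyofibroblastParams,
    SimulationSettings,
)

__all__ = [
    "DensityField",
    "Trajectory",
    "reaction_myofibroblast",
    "reaction_fibroblast",
    "step_explicit",
    "simulate",
    "time_to_fraction",
    "initial_field",
]


class IntegrationError(RuntimeError):
    """Raised when the explicit integration produces non-finite values."""


@dataclass(frozen=True)
class DensityField:
    """Density values over the interior nodes of one grid."""

    values: np.ndarray
    grid: Grid2D

    def __post_init__(self):
        if self.values.shape != (self.grid.n_interior,):
            raise ValueError(
                f"field length {self.values.shape} does not match "
                f"{self.grid.n_interior} interior nodes"
            )

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed density fields for one species."""

    times: np.ndarray           # (T,), days, uniformly spaced
    values: np.ndarray          # (T, n_interior), g cm^-3
    species: str
    grid: Grid2D

    def __post_init__(self):
        if len(self.times) != len(self.values):
            raise ValueError("times and values disagree in length")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")

    @property
    def mean_density(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def field(self, k: int) -> DensityField:
        return DensityField(values=self.values[k], grid=self.grid)


def reaction_myofibroblast(m, TGF, params: MyofibroblastParams):
    """Pointwise myofibroblast reaction rate.

    Activation of fibroblasts (held at f0) by Hill-saturated TGF-beta
    and PDGF, minus apoptosis d_m·m.
    """
    if params.K_TGF <= 0 or params.K_G <= 0:
        raise ValueError("saturation constants must be strictly positive")
    if np.any(np.asarray(TGF) < 0):
        raise ValueError("TGF concentration must be non-negative")
    activation = (
        params.lambda_mfT * TGF / (params.K_TGF + TGF)
        + params.lambda_mfG * params.G0 / (params.K_G + params.G0)
    ) * params.f0
    return activation - params.d_m * m


def reaction_fibroblast(
    f, TGFf, params: FibroblastParams, myof: MyofibroblastParams
):
    """Pointwise fibroblast reaction rate.

    AEC-derived source lambda_Ef·E0, TGF-beta-driven production, minus
    apoptosis, PDGF-driven transformation to myofibroblast, TGF-beta
    production drain and ECM deposition.
    """
    if myof.K_TGF <= 0 or params.K_E <= 0:
        raise ValueError("saturation constants must be strictly positive")
    if np.any(np.asarray(TGFf) < 0):
        raise ValueError("TGF concentration must be non-negative")
    source = params.lambda_Ef * params.E0
    production = (
        params.lambda_fE * (TGFf / (myof.K_TGF + TGFf))
        * params.E / (params.E + params.K_E)
    )
    loss = (
        params.d_f
        + myof.lambda_mfG * myof.G0 / (myof.K_G + myof.G0)
        + params.lambda_TGFf * params.E / (params.E + params.K_E)
        + params.lambda_rhof
    )
    return source + production - loss * f


def step_explicit(
    field: DensityField,
    system: LinearSystem,
    U: Union[float, np.ndarray],
    dt: float,
    step_index: int = 0,
) -> DensityField:
    """One forward-Euler step of the linear system: x + dt·(Ax + BU + b)."""
    u_vec = np.broadcast_to(np.asarray(U, dtype=float), (system.grid.n_interior,))
    new = field.values + dt * (system.A @ field.values + system.B @ u_vec + system.b)
    if not np.all(np.isfinite(new)):
        raise IntegrationError(
            f"non-finite density at step {step_index}; "
            f"dt={dt} may exceed the stability bound {cfl_max_step(system):.3g}"
        )
    return DensityField(values=new, grid=field.grid)


def initial_field(
    grid: Grid2D,
    homeostatic: float,
    damage_extent: Optional[float] = None,
    damage_factor: float = 10.0,
) -> DensityField:
    """Uniform initial density, optionally elevated inside a damaged square.

    When ``damage_extent`` is set, nodes inside the centred square of
    that side length start at ``damage_factor`` times the homeostatic
    value; the uniform field is the default.
    """
    values = np.full(grid.n_interior, homeostatic)
    if damage_extent is not None:
        xy = grid.interior_coordinates()
        half = damage_extent / 2.0
        inside = np.all(np.abs(xy - 0.5) <= half, axis=1)
        values[inside] *= damage_factor
    return DensityField(values=values, grid=grid)


def simulate(
    species: str,
    myof: MyofibroblastParams,
    homog: HomogenizationConstants,
    settings: SimulationSettings,
    fib: Optional[FibroblastParams] = None,
    grid: Optional[Grid2D] = None,
    tgf_schedule: Optional[Callable[[float], float]] = None,
    start: Optional[DensityField] = None,
) -> Trajectory:
    """Integrate one uncontrolled species from t0 to tf at spacing dt.

    TGF-beta follows ``tgf_schedule(t)`` (default: constant at the
    tabulated initial concentration); the Hill factor is re-evaluated
    every step.
    """
    if grid is None:
        grid = build_grid(settings.n_interior_per_side)
    if species == "myofibroblast":
        system = assemble_myofibroblast_system(myof, homog, grid, settings.scheme)
        K_TGF = myof.K_TGF
        tgf0 = myof.TGF0
        x0 = myof.m0
    elif species == "fibroblast":
        if fib is None:
            raise ValueError("fibroblast simulation requires FibroblastParams")
        system = assemble_fibroblast_system(fib, myof, homog, grid, settings.scheme)
        K_TGF = myof.K_TGF
        tgf0 = fib.TGFf0
        x0 = myof.f0
    else:
        raise ValueError(f"unknown species {species!r}")

    if tgf_schedule is None:
        tgf_schedule = lambda t: tgf0  # noqa: E731

    if start is None:
        start = initial_field(grid, x0, settings.damage_extent)

    n_steps = int(round((settings.tf - settings.t0) / settings.dt))
    times = settings.t0 + settings.dt * np.arange(n_steps + 1)
    values = np.empty((n_steps + 1, grid.n_interior))
    values[0] = start.values
    field = start
    for k in range(n_steps):
        tgf = tgf_schedule(times[k])
        u = tgf / (K_TGF + tgf)
        field = step_explicit(field, system, u, settings.dt, step_index=k)
        values[k + 1] = field.values
    return Trajectory(times=times, values=values, species=species, grid=grid)


def time_to_fraction(traj: Trajectory, fraction: float) -> Optional[float]:
    """First time at which the mean density drops to ``fraction`` of its
    initial value; None if it never does."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction!r}")
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    mean = traj.mean_density
    below = np.nonzero(mean <= fraction * mean[0])[0]
    if below.size == 0:
        return None
    return float(traj.times[below[0]])
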
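"""Lower-bound-constrained optimal control of TGF-beta.

The unconstrained regulator can demand negative TGF-beta, which no drug
can realize.  The constrained problem keeps the Hill fraction at or
above its homeostatic value, U(t) ≥ U(t0), enforced through the KKT
multiplier μ ≥ 0: wherever the unconstrained feedback candidate falls to
or below the bound, μ > 0 and the applied control sits exactly at U(t0)
(so the applied TGF-beta equals its initial concentration); elsewhere
μ = 0 and the feedback is applied unchanged.

By default the projection is elementwise per node and per step (the
pointwise KKT condition).  ``global_branch`` reproduces the published
all-or-nothing reading: if the unconstrained feedback violates the bound
anywhere over the horizon, the control is held at U(t0) for all times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .discretization import (
    Grid2D,
    LinearSystem,
    assemble_myofibroblast_system,
    build_grid,
)
from .forward_sim import DensityField, IntegrationError, Trajectory, initial_field
from .lqr import (
    ControlTrajectory,
    CostReport,
    FeedbackLaw,
    feedback_law,
    optimal_cost,
    running_cost,
    solve_affine,
    solve_riccati,
    tgf_to_u,
)
from .parameters import (
    HomogenizationConstants,
    MyofibroblastParams,
    SimulationSettings,
)

__all__ = ["ConstraintStatus", "ConstrainedRun", "kkt_branch", "solve_constrained_model"]


@dataclass(frozen=True)
class ConstraintStatus:
    """Per-step record of the KKT branch.

    μ's numeric value is never needed — only its sign — so it is stored
    as a boolean: ``mu_positive[k, i]`` is True where the bound is
    active (U held at U(t0)) at step k, node i.
    """

    times: np.ndarray
    mu_positive: np.ndarray     # (T, N) bool
    U_applied: np.ndarray       # (T, N)


@dataclass(frozen=True)
class ConstrainedRun:
    trajectory: Trajectory
    control: ControlTrajectory
    status: ConstraintStatus
    cost: CostReport


def kkt_branch(U_candidate, U0: float):
    """Project a feedback candidate onto the feasible set U ≥ U0.

    Returns (U_applied, mu_positive): the candidate above the bound is
    kept (μ = 0); at or below the bound the control sits at U0 (μ > 0,
    complementary slackness).
    """
    if not 0 <= U0 < 1:
        raise ValueError(f"U0 must lie in [0, 1), got {U0!r}")
    U_candidate = np.asarray(U_candidate, dtype=float)
    active = U_candidate <= U0
    applied = np.where(active, U0, U_candidate)
    if applied.ndim == 0:
        return float(applied), bool(active)
    return applied, active


def solve_constrained_model(
    params: MyofibroblastParams,
    homog: HomogenizationConstants,
    grid: Optional[Grid2D] = None,
    settings: Optional[SimulationSettings] = None,
    system: Optional[LinearSystem] = None,
) -> ConstrainedRun:
    """Integrate the myofibroblast system under the projected feedback.

    At every step the unconstrained candidate U = K m + ρ is computed,
    passed through :func:`kkt_branch`, and the branched control drives
    the state.  At active steps the applied TGF-beta equals its initial
    concentration exactly.
    """
    if settings is None:
        settings = SimulationSettings()
    if system is not None:
        grid = system.grid
    elif grid is None:
        grid = build_grid(settings.n_interior_per_side)
    if system is None:
        system = assemble_myofibroblast_system(params, homog, grid, settings.scheme)

    riccati = solve_riccati(system.A, system.B, settings)
    affine = solve_affine(system.A, system.B, riccati, system.b, settings)
    law = feedback_law(riccati, affine, system.B, system.b)

    U0 = tgf_to_u(params.TGF0, params.K_TGF)
    start = initial_field(grid, params.m0, settings.damage_extent)

    n_steps = int(round((settings.tf - settings.t0) / settings.dt))
    times = settings.t0 + settings.dt * np.arange(n_steps + 1)
    N = grid.n_interior
    state = np.empty((n_steps + 1, N))
    U_applied = np.empty((n_steps + 1, N))
    active = np.empty((n_steps + 1, N), dtype=bool)
    state[0] = start.values

    if settings.global_branch:
        # all-or-nothing reading: simulate the unconstrained loop first;
        # any violation clamps the whole horizon at U(t0)
        violates = _unconstrained_violates(system, law, state[0], settings, U0, n_steps)

    for k in range(n_steps + 1):
        candidate = law.gain_at(k) @ state[k] + law.rho_at(k)
        if settings.global_branch:
            if violates:
                U_applied[k], active[k] = np.full(N, U0), np.ones(N, dtype=bool)
            else:
                U_applied[k], active[k] = candidate, np.zeros(N, dtype=bool)
        else:
            U_applied[k], active[k] = kkt_branch(candidate, U0)
        if k < n_steps:
            new = state[k] + settings.dt * (
                system.A @ state[k] + system.B @ U_applied[k] + system.b
            )
            if not np.all(np.isfinite(new)):
                raise IntegrationError(f"constrained-loop instability at step {k}")
            state[k + 1] = new

    # exact bound restoration: where active, TGF is the initial value bit-for-bit
    TGF = np.where(active, params.TGF0, params.K_TGF * U_applied / (1.0 - U_applied))
    traj = Trajectory(times=times, values=state, species="myofibroblast", grid=grid)
    ctrl = ControlTrajectory(
        times=times, U=U_applied, TGF=TGF,
        feasible=np.all(U_applied >= 0.0, axis=1),
    )
    status = ConstraintStatus(times=times, mu_positive=active, U_applied=U_applied)
    cost = CostReport(
        J_running=running_cost(times, state, U_applied),
        J_star=optimal_cost(riccati.initial, state[0]),
    )
    return ConstrainedRun(trajectory=traj, control=ctrl, status=status, cost=cost)


def _unconstrained_violates(system, law: FeedbackLaw, x0, settings, U0, n_steps) -> bool:
    state = x0.copy()
    for k in range(n_steps + 1):
        U = law.gain_at(k) @ state + law.rho_at(k)
        if np.any(U <= U0):
            return True
        if k < n_steps:
            state = state + settings.dt * (system.A @ state + system.B @ U + system.b)
    return False
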
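"""Linear-quadratic synthesis of the optimal TGF-beta schedule.

The myofibroblast dynamics dm/dt = A m + B U + b are driven toward zero
by minimising ½∫(mᵀm + UᵀU)dt over the horizon.  Pontryagin's principle
gives the feedback U* = K m* + ρ with K = −BᵀP from the Riccati equation

    AᵀP + PA − P B Bᵀ P + I = 0        (algebraic mode)

or its backward-integrated differential form with P(tf) = 0.  The affine
offset ρ absorbs the constant forcing b; the default ``adjoint`` mode
decomposes the costate as λ = P m + s with

    ṡ = −(A − B Bᵀ P)ᵀ s − P b,   s(tf) = 0,   ρ = −Bᵀ s,

while ``paper_eta`` realises the printed matrix recursion
η̇ + η(A − BᵀPB) = P with ρ = Bᵀ η b.  The control U is the Hill
fraction TGF/(K_TGF + TGF) ∈ [0, 1); the exact substitution
TGF = K_TGF·U/(1−U) maps feasible controls back to concentrations.
Negative U (negative TGF) is recorded and flagged, never clamped: its
occurrence is precisely what motivates the constrained problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import scipy.linalg

from .discretization import LinearSystem
from .forward_sim import DensityField, IntegrationError, Trajectory
from .parameters import SimulationSettings

__all__ = [
    "ControlTrajectory",
    "RiccatiSolution",
    "AffineTerm",
    "FeedbackLaw",
    "CostReport",
    "tgf_to_u",
    "u_to_tgf",
    "solve_riccati",
    "solve_affine",
    "feedback_law",
    "closed_loop_simulate",
    "optimal_cost",
    "running_cost",
]

#: Relative residual accepted for the algebraic Riccati solution.
RICCATI_RTOL = 1e-8


class NumericalError(RuntimeError):
    """Raised when a Riccati/affine solve fails its residual check."""


def tgf_to_u(TGF, K_TGF: float, *, allow_negative: bool = False):
    """Hill fraction U = TGF/(K_TGF + TGF).

    ``allow_negative`` admits the algebraic extension to negative
    concentrations (used only to verify the substitution is a two-sided
    inverse); physical inputs are non-negative.
    """
    TGF = np.asarray(TGF, dtype=float)
    if not allow_negative and np.any(TGF < 0):
        raise ValueError("TGF concentration must be non-negative")
    out = TGF / (K_TGF + TGF)
    return float(out) if out.ndim == 0 else out


def u_to_tgf(U, K_TGF: float):
    """Inverse substitution TGF = K_TGF·U/(1−U); exact inverse on U < 1."""
    U = np.asarray(U, dtype=float)
    if np.any(U >= 1.0 - 1e-12):
        raise ValueError("U must stay below 1 (TGF saturation singularity)")
    out = K_TGF * U / (1.0 - U)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ControlTrajectory:
    """Time-indexed control history.

    ``U`` is the dimensionless Hill fraction per node; ``TGF`` the
    mapped concentration (negative where U < 0 — physically infeasible,
    marked by ``feasible``).
    """

    times: np.ndarray       # (T,)
    U: np.ndarray           # (T, N)
    TGF: np.ndarray         # (T, N)
    feasible: np.ndarray    # (T,), True where all nodes have U >= 0

    @property
    def U_mean(self) -> np.ndarray:
        return self.U.mean(axis=1)

    @property
    def TGF_mean(self) -> np.ndarray:
        return self.TGF.mean(axis=1)


@dataclass(frozen=True)
class RiccatiSolution:
    """Stationary or time-indexed solution P of the Riccati equation."""

    mode: str                               # "algebraic" | "differential"
    P: Optional[np.ndarray] = None          # (N, N), algebraic mode
    times: Optional[np.ndarray] = None      # (T,), differential mode
    P_family: Optional[np.ndarray] = None   # (T, N, N), differential mode
    residual: float = 0.0

    def at(self, k: int) -> np.ndarray:
        """P at time index k (constant in algebraic mode)."""
        if self.mode == "algebraic":
            return self.P
        return self.P_family[k]

    @property
    def initial(self) -> np.ndarray:
        """P(t0), the matrix entering the optimal-cost formula."""
        return self.P if self.mode == "algebraic" else self.P_family[0]


@dataclass(frozen=True)
class AffineTerm:
    """Affine offset of the costate decomposition.

    ``value`` is the adjoint vector s (or its time family), or the
    matrix η in paper_eta mode; ``rho`` is the resulting control offset.
    """

    mode: str                           # "adjoint" | "paper_eta"
    value: np.ndarray
    rho: np.ndarray                     # (N,) or (T, N)
    time_varying: bool = False

    def rho_at(self, k: int) -> np.ndarray:
        return self.rho[k] if self.time_varying else self.rho


@dataclass(frozen=True)
class FeedbackLaw:
    """Linear state feedback U = K m + rho."""

    K: np.ndarray                       # (N, N) or (T, N, N)
    rho: np.ndarray                     # (N,) or (T, N)
    time_varying: bool = False

    def gain_at(self, k: int) -> np.ndarray:
        return self.K[k] if self.time_varying else self.K

    def rho_at(self, k: int) -> np.ndarray:
        return self.rho[k] if self.time_varying else self.rho


@dataclass(frozen=True)
class CostReport:
    """Quadrature cost of a realized run and the Riccati-predicted optimum."""

    J_running: float    # trapezoid quadrature of ½(mᵀm + UᵀU)
    J_star: float       # ½ m0ᵀ P(t0) m0


def _care_residual(A, B, P) -> float:
    return float(np.linalg.norm(A.T @ P + P @ A - P @ B @ B.T @ P + np.eye(len(A))))


def _horizon(settings: SimulationSettings) -> np.ndarray:
    n_steps = int(round((settings.tf - settings.t0) / settings.dt))
    return settings.t0 + settings.dt * np.arange(n_steps + 1)


def solve_riccati(
    A: np.ndarray,
    B: np.ndarray,
    settings: Optional[SimulationSettings] = None,
    mode: Optional[str] = None,
) -> RiccatiSolution:
    """Solve the Riccati equation with unit state and control weights.

    Algebraic mode calls the stationary CARE solver and verifies the
    residual; differential mode integrates Ṗ = −(AᵀP + PA − PBBᵀP + I)
    backward from P(tf) = 0 with the settings' Euler step.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if settings is None:
        settings = SimulationSettings()
    if mode is None:
        mode = settings.riccati_mode
    n = len(A)
    I = np.eye(n)
    if mode == "algebraic":
        try:
            P = scipy.linalg.solve_continuous_are(A, B, I, I)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise NumericalError(f"CARE solver failed: {exc}") from exc
        P = 0.5 * (P + P.T)
        res = _care_residual(A, B, P)
        if res > RICCATI_RTOL * (1.0 + np.linalg.norm(P)):
            raise NumericalError(
                f"CARE residual {res:.3e} exceeds "
                f"{RICCATI_RTOL:.0e}·(1+||P||_F)={RICCATI_RTOL * (1 + np.linalg.norm(P)):.3e}"
            )
        return RiccatiSolution(mode="algebraic", P=P, residual=res)
    if mode == "differential":
        times = _horizon(settings)
        T = len(times)
        family = np.zeros((T, n, n))
        BBt = B @ B.T
        for k in range(T - 1, 0, -1):
            P = family[k]
            family[k - 1] = P + settings.dt * (A.T @ P + P @ A - P @ BBt @ P + I)
            family[k - 1] = 0.5 * (family[k - 1] + family[k - 1].T)
        return RiccatiSolution(
            mode="differential", times=times, P_family=family,
            residual=_care_residual(A, B, family[0]),
        )
    raise ValueError(f"unknown Riccati mode {mode!r}")


def solve_affine(
    A: np.ndarray,
    B: np.ndarray,
    riccati: RiccatiSolution,
    b: np.ndarray,
    settings: Optional[SimulationSettings] = None,
    mode: Optional[str] = None,
) -> AffineTerm:
    """Affine offset for the constant forcing b.

    adjoint: stationary s with (A − BBᵀP)ᵀ s = −P b (algebraic Riccati)
    or the backward-integrated family with s(tf) = 0 (differential);
    ρ = −Bᵀ s.  paper_eta: η(A − BᵀPB) = P (stationary) or the printed
    backward recursion; ρ = Bᵀ η b.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if settings is None:
        settings = SimulationSettings()
    if mode is None:
        mode = settings.affine_mode

    if mode == "adjoint":
        if riccati.mode == "algebraic":
            P = riccati.P
            Acl = A - B @ B.T @ P
            try:
                s = np.linalg.solve(Acl.T, -P @ b)
            except np.linalg.LinAlgError as exc:
                raise NumericalError(f"singular adjoint solve: {exc}") from exc
            return AffineTerm(mode="adjoint", value=s, rho=-B.T @ s)
        times = riccati.times
        T = len(times)
        n = len(A)
        s_fam = np.zeros((T, n))
        BBt = B @ B.T
        for k in range(T - 1, 0, -1):
            P = riccati.P_family[k]
            s = s_fam[k]
            s_fam[k - 1] = s + settings.dt * ((A - BBt @ P).T @ s + P @ b)
        rho = np.einsum("ij,tj->ti", -B.T, s_fam)
        return AffineTerm(mode="adjoint", value=s_fam, rho=rho, time_varying=True)

    if mode == "paper_eta":
        if riccati.mode == "algebraic":
            P = riccati.P
            M = A - B.T @ P @ B
            try:
                eta = np.linalg.solve(M.T, P.T).T  # η M = P
            except np.linalg.LinAlgError as exc:
                raise NumericalError(f"singular eta solve: {exc}") from exc
            return AffineTerm(mode="paper_eta", value=eta, rho=B.T @ eta @ b)
        times = riccati.times
        T = len(times)
        n = len(A)
        eta_fam = np.zeros((T, n, n))
        for k in range(T - 1, 0, -1):
            P = riccati.P_family[k]
            eta = eta_fam[k]
            # η̇ = P − η(A − BᵀPB), integrated backward from η(tf)=0
            eta_fam[k - 1] = eta - settings.dt * (P - eta @ (A - B.T @ P @ B))
        rho = np.einsum("ij,tjk,k->ti", B.T, eta_fam, b)
        return AffineTerm(mode="paper_eta", value=eta_fam, rho=rho, time_varying=True)

    raise ValueError(f"unknown affine mode {mode!r}")


def feedback_law(
    riccati: RiccatiSolution,
    affine: Optional[AffineTerm],
    B: np.ndarray,
    b: np.ndarray,
) -> FeedbackLaw:
    """Assemble U = K m + ρ with K = −BᵀP and ρ from the affine term."""
    B = np.atleast_2d(np.asarray(B, dtype=float))
    n = len(B)
    if riccati.mode == "algebraic":
        K = -B.T @ riccati.P
        time_varying = False
    else:
        K = -np.einsum("ij,tjk->tik", B.T, riccati.P_family)
        time_varying = True
    if affine is None:
        rho = np.zeros((len(K), n)) if time_varying else np.zeros(n)
    else:
        rho = affine.rho
        if affine.time_varying != time_varying:
            raise ValueError("Riccati and affine terms disagree on time dependence")
    return FeedbackLaw(K=K, rho=rho, time_varying=time_varying)


def running_cost(
    times: np.ndarray,
    state: np.ndarray,
    U: np.ndarray,
    state_ref: Optional[np.ndarray] = None,
) -> float:
    """Trapezoid quadrature of ½((x−ref)ᵀ(x−ref) + UᵀU) along a run."""
    diff = state if state_ref is None else state - state_ref
    integrand = 0.5 * (np.sum(diff * diff, axis=1) + np.sum(U * U, axis=1))
    return float(np.trapezoid(integrand, times))


def closed_loop_simulate(
    system: LinearSystem,
    law: FeedbackLaw,
    m0_field: DensityField,
    settings: SimulationSettings,
    K_TGF: float = 1e-10,
) -> tuple[Trajectory, ControlTrajectory, CostReport]:
    """Integrate the feedback-controlled system and report its cost.

    The recorded TGF is the exact substitution K_TGF·U/(1−U) wherever
    U < 1; steps where any node has U < 0 are flagged infeasible (the
    mapped concentration is negative there) and never clamped.
    """
    times = _horizon(settings)
    T = len(times)
    N = system.grid.n_interior
    state = np.empty((T, N))
    U = np.empty((T, N))
    state[0] = m0_field.values
    for k in range(T - 1):
        U[k] = law.gain_at(k) @ state[k] + law.rho_at(k)
        new = state[k] + settings.dt * (
            system.A @ state[k] + system.B @ U[k] + system.b
        )
        if not np.all(np.isfinite(new)):
            raise IntegrationError(f"closed-loop instability at step {k}")
        state[k + 1] = new
    U[T - 1] = law.gain_at(T - 1) @ state[T - 1] + law.rho_at(T - 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        TGF = np.where(U < 1.0, K_TGF * U / (1.0 - U), np.inf)
    feasible = np.all(U >= 0.0, axis=1)

    traj = Trajectory(times=times, values=state, species=system.species, grid=system.grid)
    ctrl = ControlTrajectory(times=times, U=U, TGF=TGF, feasible=feasible)
    # predicted optimum uses P(t0); recover it from the gain K = -BᵀP when
    # B is invertible, otherwise fall back to the running quadrature only
    J_running = running_cost(times, state, U)
    J_star = _predicted_cost(system, law, m0_field)
    return traj, ctrl, CostReport(J_running=J_running, J_star=J_star)


def _predicted_cost(system: LinearSystem, law: FeedbackLaw, m0_field: DensityField) -> float:
    K0 = law.gain_at(0)
    try:
        P0 = -np.linalg.solve(system.B.T, K0)
    except np.linalg.LinAlgError:
        return float("nan")
    return optimal_cost(P0, m0_field.values)


def optimal_cost(P: np.ndarray, m0) -> float:
    """Minimum performance index ½·m0ᵀ P m0."""
    m0 = np.atleast_1d(np.asarray(m0, dtype=float))
    P = np.atleast_2d(np.asarray(P, dtype=float))
    return float(0.5 * m0 @ P @ m0)
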
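"""Canonical registry of model constants.

All values are carried in the units of the source kinetic literature
(grams, centimetres, days).  The myofibroblast subsystem describes the
density ``m(x, y, t)`` of activated, collagen-depositing cells driven by
TGF-beta and PDGF; the fibroblast subsystem describes the precursor
density ``f(x, y, t)`` fed by alveolar epithelial cells (AEC) and drained
by apoptosis, myofibroblast transformation, TGF-beta production and ECM
deposition.  The homogenization constants replace the alveolar
microstructure by an effective medium: ``gamma`` is the tissue volume
fraction and ``a_diag`` the diagonal entry of the effective diffusion
tensor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "MyofibroblastParams",
    "FibroblastParams",
    "HomogenizationConstants",
    "SimulationSettings",
    "default_parameters",
    "validate",
]

#: Exact homogenized tissue volume fraction.
GAMMA_DEFAULT = 127.0 / 343.0


@dataclass(frozen=True)
class MyofibroblastParams:
    """Kinetic constants of the myofibroblast diffusion equation.

    Rates are per day, densities/concentrations in g·cm⁻³,
    diffusivity in cm²·day⁻¹.
    """

    m0: float = 8.5e-3          # initial myofibroblast density
    f0: float = 4.75e-3         # homeostatic fibroblast density
    G0: float = 0.58e-3         # activated PDGF concentration
    TGF0: float = 2.51e-12      # activated TGF-beta concentration
    d_m: float = 1.66e-2        # myofibroblast death rate
    D_m: float = 1.47e-5        # myofibroblast diffusivity
    lambda_mfT: float = 1.2e-1  # fibroblast->myofibroblast rate via TGF-beta
    lambda_mfG: float = 1.2e-1  # fibroblast->myofibroblast rate via PDGF
    K_G: float = 1.5e-8         # PDGF half-saturation
    K_TGF: float = 1e-10        # TGF-beta half-saturation


@dataclass(frozen=True)
class FibroblastParams:
    """Kinetic constants of the fibroblast diffusion equation.

    ``rho_ecm0`` (initial ECM density) is recorded for completeness but
    enters no implemented equation; only the deposition rate
    ``lambda_rhof`` does.  ``lambda_Ef`` is tabulated in g·cm⁻³ and used
    exactly as printed in the source term ``lambda_Ef * E0``.
    """

    E: float = 7.99e-1          # activated AEC density
    E0: float = 7.99e-1         # homeostatic AEC density
    TGFf0: float = 2.51e-12     # TGF-beta concentration, fibroblast pool
    TGFm0: float = 2.51e-12     # TGF-beta concentration, myofibroblast pool
    rho_ecm0: float = 3e-3      # ECM density (recorded, unused)
    d_f: float = 1.66e-2        # fibroblast death rate
    D_f: float = 1.47e-6        # fibroblast diffusivity
    lambda_fE: float = 5e-4     # fibroblast production rate
    lambda_rhof: float = 3e-3   # fibroblast->ECM deposition rate
    lambda_TGFf: float = 7.5e-3  # TGF-beta production rate by fibroblasts
    lambda_Ef: float = 2.5e-1   # AEC-derived source strength (as printed)
    K_E: float = 1e-1           # AEC half-saturation


@dataclass(frozen=True)
class HomogenizationConstants:
    gamma: float = GAMMA_DEFAULT  # tissue volume fraction, dimensionless
    a_diag: float = 0.11          # effective diffusion coefficient, dimensionless


@dataclass(frozen=True)
class SimulationSettings:
    """Run-level knobs shared by the simulator and the control solvers.

    ``scheme`` selects the finite-difference assembly: ``neumann5`` is
    the mass-conserving five-point zero-flux Laplacian; ``paper_literal``
    reproduces the printed block matrices.  ``riccati_mode`` picks the
    stationary (algebraic) or backward-integrated (differential) Riccati
    solution; ``affine_mode`` picks the adjoint offset vector ``s`` or
    the printed matrix recursion ``eta``.
    """

    t0: float = 0.0
    tf: float = 300.0
    dt: float = 0.1
    n_interior_per_side: int = 6
    scheme: str = "neumann5"
    riccati_mode: str = "algebraic"
    affine_mode: str = "adjoint"
    vanish_fraction: float = 0.01
    damage_extent: Optional[float] = None   # side (cm) of the damaged square I_D
    global_branch: bool = False             # all-or-nothing KKT clamping
    strict_cross_term: bool = False         # joint Riccati with (m-f) weight
    live_coupling: bool = False             # feed simulated f(t) into the m-equation

    _SCHEMES = ("neumann5", "paper_literal")
    _RICCATI_MODES = ("algebraic", "differential")
    _AFFINE_MODES = ("adjoint", "paper_eta")


def default_parameters() -> tuple[MyofibroblastParams, FibroblastParams, HomogenizationConstants]:
    """Return the tabulated default constants for both subsystems."""
    return MyofibroblastParams(), FibroblastParams(), HomogenizationConstants()


def _positive(report: list[str], obj, names) -> None:
    for name in names:
        if not getattr(obj, name) > 0:
            report.append(f"{name} must be strictly positive (got {getattr(obj, name)!r})")


def _non_negative(report: list[str], obj, names) -> None:
    for name in names:
        if getattr(obj, name) < 0:
            report.append(f"{name} must be non-negative (got {getattr(obj, name)!r})")


def validate(params) -> list[str]:
    """Check a parameter object against its invariants.

    Returns a list of human-readable violations; empty iff the object is
    valid.  Callers decide whether a non-empty report aborts the run.
    """
    report: list[str] = []
    if isinstance(params, MyofibroblastParams):
        _positive(report, params, ["d_m", "lambda_mfT", "lambda_mfG", "K_G", "K_TGF"])
        _non_negative(report, params, ["m0", "f0", "G0", "TGF0", "D_m"])
    elif isinstance(params, FibroblastParams):
        _positive(
            report, params,
            ["d_f", "lambda_fE", "lambda_rhof", "lambda_TGFf", "lambda_Ef", "K_E"],
        )
        _non_negative(report, params, ["E", "E0", "TGFf0", "TGFm0", "rho_ecm0", "D_f"])
    elif isinstance(params, HomogenizationConstants):
        if not 0 < params.gamma <= 1:
            report.append(f"gamma must lie in (0, 1] (got {params.gamma!r})")
        if not params.a_diag > 0:
            report.append(f"a_diag must be strictly positive (got {params.a_diag!r})")
    elif isinstance(params, SimulationSettings):
        if not params.t0 < params.tf:
            report.append(f"t0 must precede tf (got t0={params.t0!r}, tf={params.tf!r})")
        if not params.dt > 0:
            report.append(f"dt must be strictly positive (got {params.dt!r})")
        if params.n_interior_per_side < 1:
            report.append(
                f"n_interior_per_side must be >= 1 (got {params.n_interior_per_side!r})"
            )
        if not 0 < params.vanish_fraction <= 1:
            report.append(
                f"vanish_fraction must lie in (0, 1] (got {params.vanish_fraction!r})"
            )
        if params.damage_extent is not None and not 0 < params.damage_extent < 1:
            report.append(
                f"damage_extent must lie in (0, 1) cm (got {params.damage_extent!r})"
            )
        if params.scheme not in SimulationSettings._SCHEMES:
            report.append(f"scheme must be one of {SimulationSettings._SCHEMES}")
        if params.riccati_mode not in SimulationSettings._RICCATI_MODES:
            report.append(f"riccati_mode must be one of {SimulationSettings._RICCATI_MODES}")
        if params.affine_mode not in SimulationSettings._AFFINE_MODES:
            report.append(f"affine_mode must be one of {SimulationSettings._AFFINE_MODES}")
    else:
        raise TypeError(f"unknown parameter type: {type(params).__name__}")
    return report


def field_names(cls) -> list[str]:
    return [f.name for f in dataclasses.fields(cls)]


def with_overrides(obj, overrides: dict):
    """Return a copy of a frozen parameter object with fields replaced."""
    return dataclasses.replace(obj, **overrides)
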
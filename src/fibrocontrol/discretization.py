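"""Finite-difference grids and state-space assembly.

The unit tissue square [0, 1]² is discretized with nodes x_i = i/n; the
(n−1)² interior nodes carry the unknown densities, stacked row-major with
the x-index fastest.  Each species' homogenized reaction–diffusion
equation, linearized around the homeostatic state, becomes

    dm/dt = A m + B U + b

where ``A`` holds the scaled Laplacian minus the total linear loss rate,
``B = theta·I`` injects the Hill-saturated TGF-beta control ``U`` and
``b`` carries the constant source.

Two assemblies are provided.  ``neumann5`` is the physically consistent
five-point zero-flux stencil: with the loss rate removed every row of A
sums to zero (discrete mass conservation) and the Laplacian block is
symmetric.  ``paper_literal`` reproduces the printed block matrices
(1-D tridiagonal G blocks, sub-diagonal L couplings, identity blocks in
B, boundary entries frozen into b) for archaeology of the published
figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .parameters import (
    FibroblastParams,
    HomogenizationConstants,
    MyofibroblastParams,
)

__all__ = [
    "Grid2D",
    "LinearSystem",
    "build_grid",
    "effective_diffusion",
    "assemble_myofibroblast_system",
    "assemble_fibroblast_system",
    "cfl_max_step",
]


@dataclass(frozen=True)
class Grid2D:
    """Uniform square grid with n subdivisions per side."""

    n: int

    @property
    def dx(self) -> float:
        return 1.0 / self.n

    @property
    def n_interior_per_side(self) -> int:
        return self.n - 1

    @property
    def n_interior(self) -> int:
        return (self.n - 1) ** 2

    @property
    def k1(self) -> float:
        return float(self.n) ** 2

    @property
    def k2(self) -> float:
        return float(self.n) ** 2

    def interior_coordinates(self) -> np.ndarray:
        """(n_interior, 2) array of (x, y) node positions, x fastest."""
        s = self.n_interior_per_side
        idx = np.arange(1, s + 1) * self.dx
        xx, yy = np.meshgrid(idx, idx, indexing="xy")
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass(frozen=True)
class LinearSystem:
    """Assembled state-space triple for one species on one grid."""

    A: np.ndarray       # (N, N), day^-1
    B: np.ndarray       # (N, N), day^-1, control injection
    b: np.ndarray       # (N,), g cm^-3 day^-1
    r: float            # diffusion stencil weight, day^-1
    theta: float        # control gain, day^-1
    c: float            # constant source, g cm^-3 day^-1
    alpha: float        # total linear loss rate, day^-1
    grid: Grid2D
    scheme: str
    species: str

    def __post_init__(self):
        N = self.grid.n_interior
        if self.A.shape != (N, N) or self.B.shape != (N, N) or self.b.shape != (N,):
            raise ValueError(
                f"dimension mismatch: grid has {N} interior nodes, "
                f"A {self.A.shape}, B {self.B.shape}, b {self.b.shape}"
            )


def build_grid(n_interior_per_side: int) -> Grid2D:
    """Grid with ``n_interior_per_side``² interior nodes (n = that + 1)."""
    if int(n_interior_per_side) != n_interior_per_side or n_interior_per_side < 1:
        raise ValueError(
            f"n_interior_per_side must be a positive integer, got {n_interior_per_side!r}"
        )
    return Grid2D(n=int(n_interior_per_side) + 1)


def effective_diffusion(D: float, homog: HomogenizationConstants) -> float:
    """Homogenized diffusivity (a_diag/gamma)·D of the effective medium."""
    if D < 0:
        raise ValueError(f"diffusivity must be non-negative, got {D!r}")
    return (homog.a_diag / homog.gamma) * D


def _neumann5_laplacian(grid: Grid2D) -> np.ndarray:
    """Integer-count 5-point Laplacian with zero-flux (mirror) boundaries.

    Entry counts only; multiply by r to get day^-1.  Rows sum to zero and
    the matrix is symmetric: a boundary-adjacent node simply loses the
    coupling in the mirrored direction.
    """
    s = grid.n_interior_per_side
    N = s * s
    L = np.zeros((N, N))
    for j in range(s):
        for i in range(s):
            k = j * s + i
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < s and 0 <= jj < s:
                    L[k, jj * s + ii] += 1.0
                    L[k, k] -= 1.0
                # mirror rule: boundary neighbour equals the node itself,
                # so the pair contributes nothing
    return L


def _paper_literal_A(grid: Grid2D, r: float, loss: float) -> np.ndarray:
    """Printed block-tridiagonal A: tridiagonal G blocks, sub-diagonal L."""
    s = grid.n_interior_per_side
    G = np.zeros((s, s))
    np.fill_diagonal(G, -2.0 * r - loss)
    idx = np.arange(s - 1)
    G[idx, idx + 1] = r
    G[idx + 1, idx] = r
    L = np.zeros((s, s))
    L[idx + 1, idx] = r
    A = np.zeros((s * s, s * s))
    for j in range(s):
        A[j * s:(j + 1) * s, j * s:(j + 1) * s] = G
        if j > 0:
            A[j * s:(j + 1) * s, (j - 1) * s:j * s] = L
            A[(j - 1) * s:j * s, j * s:(j + 1) * s] = L.T
    return A


def _paper_literal_B(grid: Grid2D, theta: float) -> np.ndarray:
    """Printed B: theta·I diagonal blocks, identity off-diagonal blocks."""
    s = grid.n_interior_per_side
    B = np.zeros((s * s, s * s))
    eye = np.eye(s)
    for j in range(s):
        B[j * s:(j + 1) * s, j * s:(j + 1) * s] = theta * eye
        if j > 0:
            B[j * s:(j + 1) * s, (j - 1) * s:j * s] = eye
            B[(j - 1) * s:j * s, j * s:(j + 1) * s] = eye
    return B


def _paper_literal_b(grid: Grid2D, r: float, c: float, boundary_density: float) -> np.ndarray:
    """Printed b: per-block x-boundary entries (frozen) plus the source."""
    s = grid.n_interior_per_side
    b = np.full(s * s, c)
    for j in range(s):
        b[j * s] += r * boundary_density
        b[j * s + s - 1] += r * boundary_density
    return b


def _assemble(
    *,
    D: float,
    loss: float,
    theta: float,
    c: float,
    boundary_density: float,
    homog: HomogenizationConstants,
    grid: Grid2D,
    scheme: str,
    species: str,
    alpha: float,
) -> LinearSystem:
    r = homog.a_diag * D / (homog.gamma * grid.dx ** 2)
    N = grid.n_interior
    if scheme == "neumann5":
        A = r * _neumann5_laplacian(grid) - loss * np.eye(N)
        B = theta * np.eye(N)
        b = np.full(N, c)
    elif scheme == "paper_literal":
        A = _paper_literal_A(grid, r, loss)
        B = _paper_literal_B(grid, theta)
        b = _paper_literal_b(grid, r, c, boundary_density)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return LinearSystem(
        A=A, B=B, b=b, r=r, theta=theta, c=c, alpha=alpha,
        grid=grid, scheme=scheme, species=species,
    )


def assemble_myofibroblast_system(
    params: MyofibroblastParams,
    homog: HomogenizationConstants,
    grid: Grid2D,
    scheme: str = "neumann5",
) -> LinearSystem:
    """State-space triple for the myofibroblast subsystem.

    The linearization freezes the fibroblast and PDGF factors at their
    initial values: gain theta = lambda_mfT·f0, source
    c = lambda_mfG·G0/(K_G+G0)·f0, loss d_m.
    """
    theta = params.lambda_mfT * params.f0
    c = params.lambda_mfG * params.G0 / (params.K_G + params.G0) * params.f0
    return _assemble(
        D=params.D_m, loss=params.d_m, theta=theta, c=c,
        boundary_density=params.m0, homog=homog, grid=grid,
        scheme=scheme, species="myofibroblast", alpha=0.0,
    )


def fibroblast_loss_rate(params: FibroblastParams, myof: MyofibroblastParams) -> float:
    """Total linear fibroblast loss rate alpha.

    Sum of transformation to myofibroblast (PDGF), TGF-beta production,
    ECM deposition and apoptosis.
    """
    return (
        myof.lambda_mfG * myof.G0 / (myof.K_G + myof.G0)
        + params.lambda_TGFf * params.E / (params.E + params.K_E)
        + params.lambda_rhof
        + params.d_f
    )


def assemble_fibroblast_system(
    params: FibroblastParams,
    myof: MyofibroblastParams,
    homog: HomogenizationConstants,
    grid: Grid2D,
    scheme: str = "neumann5",
) -> LinearSystem:
    """State-space triple for the fibroblast subsystem.

    Gain theta_f = lambda_fE·E/(E+K_E), source c_f = lambda_Ef·E0, and
    loss alpha as in :func:`fibroblast_loss_rate`.
    """
    alpha = fibroblast_loss_rate(params, myof)
    theta = params.lambda_fE * params.E / (params.E + params.K_E)
    c = params.lambda_Ef * params.E0
    return _assemble(
        D=params.D_f, loss=alpha, theta=theta, c=c,
        boundary_density=myof.f0, homog=homog, grid=grid,
        scheme=scheme, species="fibroblast", alpha=alpha,
    )


def cfl_max_step(system: LinearSystem, loss_rate: Optional[float] = None) -> float:
    """Largest dt for which the explicit diffusion–decay step is non-expanding.

    2/(4r + loss): the most negative eigenvalue of the 5-point Laplacian
    is bounded by −4r, and the decay adds the loss rate.
    """
    if loss_rate is None:
        loss_rate = system.alpha if system.alpha > 0 else -np.min(np.diag(system.A)) - 4 * system.r
        loss_rate = max(loss_rate, 0.0)
    denom = 4.0 * system.r + loss_rate
    return float("inf") if denom <= 0 else 2.0 / denom
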
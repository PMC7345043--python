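"""RMS electric potential, field, and DEP drive on one repeating electrode unit.

The electrode array is axially periodic with period L_u = 2 (l + d), so the
Laplace problem for the RMS potential,

    (d2/dx2 + d2/dy2 + d2/dz2) V_RMS = 0,

is solved once on a single repeating unit and the result is tiled over the
whole array.  Boundary conditions: known RMS voltages on the electrode
patches of the two sidewalls (V_RMS = V_pp / (2 sqrt 2) on a signal
electrode, 0 on a ground electrode), zero normal derivative (insulated)
everywhere else.

The axial cut of the unit is taken through the *midplane of the signal
electrodes*: the unit reads [signal/2 | gap | ground | gap | signal/2].
For an aligned, axially periodic array these planes are exact mirror planes
of the infinite-array solution, so the insulated (zero normal derivative)
condition at x = 0 and x = L_u reproduces the periodic solution exactly and
the tiled field is continuous across unit boundaries.  A literal periodic
wrap is available via ``axial_bc="periodic"`` and yields the same solution.

Discretization is the 7-point finite-difference Laplacian on a uniform
grid, relaxed with Gauss--Seidel (optionally over-relaxed).  The electric
field E = -grad V_RMS, the squared field magnitude E2 = E.E, and its
gradient grad(E2) -- the quantity the DEP force is proportional to -- are
formed with second-order central differences (second-order one-sided at the
faces).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import gs_sweep, laplacian_residual, trilinear
from .constants import VPP_TO_VRMS
from .geometry import DeviceGeometry

__all__ = [
    "PotentialGrid",
    "DepForceField",
    "ResolutionError",
    "ConvergenceError",
    "OutOfDomainError",
    "build_repeating_unit",
    "solve_potential",
    "dep_force_field",
    "sample_dep",
    "TAG_INTERIOR",
    "TAG_SIGNAL",
    "TAG_GROUND",
    "TAG_INSULATED",
]

TAG_INTERIOR = 0
TAG_SIGNAL = 1
TAG_GROUND = 2
TAG_INSULATED = 3


class ResolutionError(ValueError):
    """Grid spacing too coarse to resolve the electrode layout."""


class OutOfDomainError(ValueError):
    """Position outside the channel."""


class ConvergenceError(RuntimeError):
    """Gauss--Seidel failed to reach tolerance within max_iter sweeps."""

    def __init__(self, msg, residual):
        super().__init__(msg)
        self.residual = residual


@dataclass
class PotentialGrid:
    """Discrete V_RMS on one repeating unit.

    ``values`` has shape (nx, ny, nz) spanning [0, L_u] x [0, W_ch] x
    [0, H_ch]; ``fixed`` marks Dirichlet (electrode) nodes; ``tags`` labels
    every node interior / signal / ground / insulated.
    """

    spacing: float
    values: np.ndarray
    fixed: np.ndarray
    tags: np.ndarray
    axial_bc: str = "insulated"
    solved: bool = False
    iterations: int = 0
    residual: float = math.inf

    @property
    def dims(self):
        return self.values.shape


@dataclass
class DepForceField:
    """E, E2 = |E|^2 and grad(E2) on the repeating unit.

    ``grad_e2`` has shape (3, nx, ny, nz) in V^2/m^3; the DEP force on a
    particle is (2 pi eps_m eps0 r^3 Re[f_CM]) * grad_e2 at its position.
    """

    spacing: float
    e_field: np.ndarray  # (3, nx, ny, nz), V/m
    e2: np.ndarray  # (nx, ny, nz), V^2/m^2
    grad_e2: np.ndarray  # (3, nx, ny, nz), V^2/m^3


def _snap(length: float, spacing: float, name: str) -> int:
    m = int(round(length / spacing))
    if m < 1:
        raise ResolutionError(f"{name}={length} is below one grid spacing")
    if abs(length - m * spacing) > 1e-9 * max(length, spacing):
        warnings.warn(
            f"{name}={length:.6g} m is not a multiple of spacing={spacing:.6g} m; "
            f"snapping to {m * spacing:.6g} m",
            stacklevel=3,
        )
    return m


def build_repeating_unit(
    geometry: DeviceGeometry, spacing: float, axial_bc: str = "insulated"
) -> PotentialGrid:
    """Lay out the unsolved potential grid for one repeating unit.

    The unit spans [0, 2(l+d)] axially.  Each sidewall carries one signal
    electrode (split half/half across the axial ends, where the periodic
    mirror planes lie) and one centered ground electrode, both spanning the
    full channel height, separated by gaps of length d.
    """
    if axial_bc not in ("insulated", "periodic"):
        raise ValueError("axial_bc must be 'insulated' or 'periodic'")
    l, d = geometry.electrode_length, geometry.electrode_gap
    if spacing > min(l, d) / 2:
        raise ResolutionError(
            f"spacing {spacing:.3g} m exceeds min(l, d)/2 = {min(l, d) / 2:.3g} m"
        )
    nhalf = _snap(l / 2, spacing, "l/2")
    ngap = _snap(d, spacing, "d")
    nl = 2 * nhalf
    ny = _snap(geometry.channel_width, spacing, "W_ch") + 1
    nz = _snap(geometry.channel_height, spacing, "H_ch") + 1
    nx = 2 * (nhalf + ngap) + nl + 1

    values = np.zeros((nx, ny, nz))
    fixed = np.zeros((nx, ny, nz), dtype=np.bool_)
    tags = np.full((nx, ny, nz), TAG_INTERIOR, dtype=np.int8)

    # all boundary faces default to insulated
    for sl in (
        (0, slice(None), slice(None)),
        (-1, slice(None), slice(None)),
        (slice(None), 0, slice(None)),
        (slice(None), -1, slice(None)),
        (slice(None), slice(None), 0),
        (slice(None), slice(None), -1),
    ):
        tags[sl] = TAG_INSULATED

    # electrode footprints along x (node indices, inclusive)
    signal_idx = np.zeros(nx, dtype=np.bool_)
    signal_idx[: nhalf + 1] = True
    signal_idx[nx - 1 - nhalf :] = True
    ground_idx = np.zeros(nx, dtype=np.bool_)
    g0 = nhalf + ngap
    ground_idx[g0 : g0 + nl + 1] = True

    vs1 = geometry.vpp_side1 * VPP_TO_VRMS
    vs2 = geometry.vpp_side2 * VPP_TO_VRMS
    for j, vsig in ((0, vs1), (ny - 1, vs2)):
        values[signal_idx, j, :] = vsig
        fixed[signal_idx, j, :] = True
        tags[signal_idx, j, :] = TAG_SIGNAL
        values[ground_idx, j, :] = 0.0
        fixed[ground_idx, j, :] = True
        tags[ground_idx, j, :] = TAG_GROUND

    return PotentialGrid(spacing=spacing, values=values, fixed=fixed, tags=tags, axial_bc=axial_bc)


def solve_potential(
    grid: PotentialGrid,
    tol: float = 1e-6,
    max_iter: int = 200_000,
    relaxation: float = 1.0,
) -> PotentialGrid:
    """Relax the grid in place with Gauss--Seidel until the largest node
    update of a sweep drops below ``tol`` times the largest electrode
    voltage.  Raises :class:`ConvergenceError` (carrying the final residual)
    if ``max_iter`` sweeps do not suffice."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if not (0 < relaxation < 2):
        raise ValueError("relaxation must be in (0, 2)")
    vref = float(np.max(np.abs(grid.values[grid.fixed]))) if grid.fixed.any() else 0.0
    threshold = tol * vref if vref > 0 else tol
    periodic = grid.axial_bc == "periodic"
    maxd = math.inf
    for it in range(1, max_iter + 1):
        maxd = gs_sweep(grid.values, grid.fixed, relaxation, periodic)
        if periodic:
            grid.values[-1] = grid.values[0]
        if maxd < threshold:
            grid.solved = True
            grid.iterations = it
            grid.residual = laplacian_residual(grid.values, grid.fixed)
            return grid
    grid.iterations = max_iter
    grid.residual = laplacian_residual(grid.values, grid.fixed)
    raise ConvergenceError(
        f"Gauss-Seidel did not reach tol={tol:g} in {max_iter} sweeps "
        f"(last update {maxd:.3e} V, residual {grid.residual:.3e} V)",
        grid.residual,
    )


def dep_force_field(grid: PotentialGrid) -> DepForceField:
    """Differentiate the solved potential into E, E2 and grad(E2)."""
    if not grid.solved:
        raise RuntimeError("potential grid is not solved")
    h = grid.spacing
    ex, ey, ez = (-g for g in np.gradient(grid.values, h, edge_order=2))
    e2 = ex * ex + ey * ey + ez * ez
    gx, gy, gz = np.gradient(e2, h, edge_order=2)
    return DepForceField(
        spacing=h,
        e_field=np.ascontiguousarray(np.stack([ex, ey, ez])),
        e2=e2,
        grad_e2=np.ascontiguousarray(np.stack([gx, gy, gz])),
    )


def sample_dep(position, field: DepForceField, geometry: DeviceGeometry) -> np.ndarray:
    """grad(E2) at an arbitrary channel position, V^2/m^3.

    The axial coordinate is reduced modulo the unit period while the
    position lies inside the electrode array [0, L_arr); downstream of the
    array the field is zero.  Cross-section positions outside
    [0, W_ch] x [0, H_ch] (or x < 0) raise :class:`OutOfDomainError`.
    """
    x, y, z = (float(c) for c in position)
    if not (0 <= y <= geometry.channel_width and 0 <= z <= geometry.channel_height):
        raise OutOfDomainError(f"(y={y}, z={z}) outside the channel cross-section")
    if x < 0:
        raise OutOfDomainError(f"x={x} upstream of the inlet")
    if x >= geometry.array_length:
        return np.zeros(3)
    lu = geometry.unit_period
    xr = x - lu * math.floor(x / lu)
    h = field.spacing
    return np.array(
        [trilinear(field.grad_e2[c], xr / h, y / h, z / h) for c in range(3)]
    )
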
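"""Two-dielectric continuum electrostatics on a regular grid.

The linearized Poisson–Boltzmann equation

    ∇·(ε(x) ∇φ) − ε_s κ²(x) φ = −4π λ ρ(x)

is discretised with a 7-point finite-difference stencil on a cubic grid and
solved by checkerboard successive over-relaxation (SOR). Potentials are
dimensionless thermal voltages (kT/e throughout); with charges in e and
lengths in Å the coupling constant λ = e²/(4π ε₀ k T) (~560.7 Å at
298.15 K) is computed from physical constants, never hard-coded.

The dielectric boundary is a grid-morphology approximation of the
solvent-excluded (molecular) surface: the van der Waals spheres are
inflated by the probe radius and the result eroded by the same probe, so
probe-inaccessible crevices stay inside the protein. Boundary faces take
the harmonic mean of the two dielectrics. Mobile ions are excluded from
the protein plus a Stern shell. Dirichlet boundary values are the sum of
single-atom Debye–Hückel potentials, which is also the analytic reference
solution used to validate the solver in a uniform dielectric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants as _const
from scipy.ndimage import distance_transform_edt

from .types import ChargedStructure, GagesdError, GridField


def coupling_constant(temperature: float) -> float:
    """λ = e²/(4π ε₀ k T) in Å: the vacuum Bjerrum length at T."""
    lam_m = _const.e ** 2 / (4.0 * np.pi * _const.epsilon_0
                             * _const.k * temperature)
    return lam_m * 1e10


def kappa_parameters(ionic_strength: float, eps_solvent: float,
                     temperature: float) -> tuple[float, float]:
    """(κ in 1/Å, ε_s·κ² in 1/Å²) for a 1:1 electrolyte at I mol/L."""
    lam = coupling_constant(temperature)
    n_per_A3 = ionic_strength * _const.N_A * 1e-27  # ion pairs / Å³
    eps_kappa2 = 8.0 * np.pi * lam * n_per_A3
    kappa = float(np.sqrt(eps_kappa2 / eps_solvent))
    return kappa, float(eps_kappa2)


@dataclass
class SolverParams:
    """Grid-electrostatics parameters.

    Defaults are the study conditions: water dielectric 78.0, protein
    dielectric 2.0, a 1.4 Å solvent probe, 1.0 Å grid spacing, 298.15 K.
    Ionic strength defaults to 0 M (pure-water comparison); the Stern shell
    keeps mobile ions 2 Å off the van der Waals surface when I > 0.
    ``omega=None`` selects the near-optimal SOR relaxation for the grid
    size; a fixed value (e.g. 1.6) may be supplied.
    """

    eps_solvent: float = 78.0
    eps_protein: float = 2.0
    probe_radius: float = 1.4
    spacing: float = 1.0
    temperature: float = 298.15
    ionic_strength: float = 0.0
    padding: float = 10.0
    stern_radius: float = 2.0
    omega: float | None = None
    tolerance: float = 1e-6
    max_iterations: int = 50000

    def __post_init__(self) -> None:
        if not (self.eps_solvent >= self.eps_protein > 0):
            raise ValueError("need eps_solvent >= eps_protein > 0")
        if self.spacing <= 0 or self.tolerance <= 0:
            raise ValueError("spacing and tolerance must be positive")


@dataclass
class DielectricMaps:
    """Region labels and face-centred dielectric / ion-accessibility maps."""

    protein: np.ndarray          # bool, per grid point
    eps_x: np.ndarray            # (nx-1, ny, nz) face dielectrics
    eps_y: np.ndarray
    eps_z: np.ndarray
    ion_accessible: np.ndarray   # bool, per grid point

    @property
    def solvent(self) -> np.ndarray:
        return ~self.protein


class SolverDiverged(GagesdError):
    def __init__(self, residuals: list[float]):
        super().__init__(
            f"LPB solver did not converge in {len(residuals)} iterations "
            f"(final relative residual {residuals[-1]:.3e})")
        self.residuals = residuals


def build_grid(structure: ChargedStructure | np.ndarray,
               params: SolverParams) -> GridField:
    """Axis-aligned grid: atom-centre bounding box expanded by the padding,
    dims snapped up to odd integers (extra slack on the + side)."""
    coords = structure.coords if isinstance(structure, ChargedStructure) \
        else np.asarray(structure, dtype=float)
    if coords.size == 0:
        raise GagesdError("cannot build a grid around an empty structure")
    lo = coords.min(axis=0) - params.padding
    hi = coords.max(axis=0) + params.padding
    h = params.spacing
    dims = []
    for d in range(3):
        n = int(np.floor((hi[d] - lo[d]) / h + 1e-9)) + 1
        if n % 2 == 0:
            n += 1
        dims.append(max(n, 1))
    return GridField(origin=lo, spacing=h, values=np.zeros(dims))


def _distance_to_atoms(grid: GridField, coords: np.ndarray,
                       radii: np.ndarray, offset: float) -> np.ndarray:
    """Boolean map of grid points within (radius + offset) of any atom."""
    nx, ny, nz = grid.dims
    h = grid.spacing
    mask = np.zeros(grid.dims, dtype=bool)
    ax_x, ax_y, ax_z = grid.axes()
    for (x, y, z), r in zip(coords, radii):
        reach = r + offset
        if reach <= 0:
            continue
        i0 = max(0, int(np.ceil((x - reach - grid.origin[0]) / h)))
        i1 = min(nx - 1, int(np.floor((x + reach - grid.origin[0]) / h)))
        j0 = max(0, int(np.ceil((y - reach - grid.origin[1]) / h)))
        j1 = min(ny - 1, int(np.floor((y + reach - grid.origin[1]) / h)))
        k0 = max(0, int(np.ceil((z - reach - grid.origin[2]) / h)))
        k1 = min(nz - 1, int(np.floor((z + reach - grid.origin[2]) / h)))
        if i0 > i1 or j0 > j1 or k0 > k1:
            continue
        dx2 = (ax_x[i0:i1 + 1] - x) ** 2
        dy2 = (ax_y[j0:j1 + 1] - y) ** 2
        dz2 = (ax_z[k0:k1 + 1] - z) ** 2
        local = (dx2[:, None, None] + dy2[None, :, None]
                 + dz2[None, None, :]) <= reach ** 2
        mask[i0:i1 + 1, j0:j1 + 1, k0:k1 + 1] |= local
    return mask


def dielectric_maps(structure: ChargedStructure, grid: GridField,
                    params: SolverParams) -> DielectricMaps:
    """Label grid points protein/solvent by the molecular-surface
    approximation and build face dielectrics and the ion map."""
    import warnings

    if params.spacing > params.probe_radius:
        warnings.warn("grid spacing exceeds the probe radius; the molecular "
                      "surface will be poorly resolved", stacklevel=2)
    coords = structure.coords
    radii = structure.radii
    inflated = _distance_to_atoms(grid, coords, radii, params.probe_radius)
    if inflated.any() and not inflated.all():
        # erode by the probe: distance from each inflated point to the
        # nearest solvent-accessible exterior point
        dist_to_exterior = distance_transform_edt(
            inflated, sampling=grid.spacing)
        protein = inflated & (dist_to_exterior > params.probe_radius)
    else:
        protein = inflated.copy()

    eps = np.where(protein, params.eps_protein, params.eps_solvent)

    def _face(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return 2.0 * a * b / (a + b)

    maps = DielectricMaps(
        protein=protein,
        eps_x=_face(eps[:-1, :, :], eps[1:, :, :]),
        eps_y=_face(eps[:, :-1, :], eps[:, 1:, :]),
        eps_z=_face(eps[:, :, :-1], eps[:, :, 1:]),
        ion_accessible=~_distance_to_atoms(grid, coords, radii,
                                           params.stern_radius) & ~protein,
    )
    return maps


def debye_huckel(charges: np.ndarray, coords: np.ndarray, radii: np.ndarray,
                 points: np.ndarray, eps: float, kappa: float,
                 temperature: float) -> np.ndarray:
    """Sum of single-atom Debye–Hückel potentials (kT/e) at ``points``.

    φ(x) = Σ_i q_i λ exp(−κ(r_i − a_i)) / (ε r_i (1 + κ a_i)); κ = 0
    reduces to Coulomb. Points coincident with a charge are an error.
    """
    lam = coupling_constant(temperature)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.zeros(len(pts))
    for q, c, a in zip(charges, coords, radii):
        if q == 0.0:
            continue
        r = np.linalg.norm(pts - c, axis=1)
        if (r < 1e-9).any():
            raise GagesdError("evaluation point coincides with a charge")
        out += q * lam * np.exp(-kappa * np.clip(r - a, 0.0, None)) \
            / (eps * r * (1.0 + kappa * a))
    return out


def _spread_charges(structure: ChargedStructure, grid: GridField
                    ) -> np.ndarray:
    """Trilinear spreading of point charges to the 8 surrounding nodes."""
    nx, ny, nz = grid.dims
    q_grid = np.zeros(grid.dims)
    g = (structure.coords - grid.origin) / grid.spacing
    for (gx, gy, gz), q in zip(g, structure.charges):
        if q == 0.0:
            continue
        i0, j0, k0 = int(np.floor(gx)), int(np.floor(gy)), int(np.floor(gz))
        if not (0 <= i0 < nx - 1 and 0 <= j0 < ny - 1 and 0 <= k0 < nz - 1):
            raise GagesdError("charged atom outside the grid interior; "
                              "increase padding")
        fx, fy, fz = gx - i0, gy - j0, gz - k0
        for di, wi in ((0, 1 - fx), (1, fx)):
            for dj, wj in ((0, 1 - fy), (1, fy)):
                for dk, wk in ((0, 1 - fz), (1, fz)):
                    q_grid[i0 + di, j0 + dj, k0 + dk] += q * wi * wj * wk
    return q_grid


def solve_lpb(structure: ChargedStructure, maps: DielectricMaps,
              params: SolverParams, grid: GridField | None = None
              ) -> tuple[GridField, dict]:
    """Solve the linearized PB equation; returns (potential, provenance).

    The potential grid is in kT/e. Provenance records iterations, the
    final relative residual, and the SOR relaxation used. Non-convergence
    raises :class:`SolverDiverged` carrying the residual history.
    """
    if grid is None:
        grid = build_grid(structure, params)
    nx, ny, nz = grid.dims
    if min(nx, ny, nz) < 3:
        raise GagesdError("grid too small to solve on (need >= 3 points "
                          "per axis)")
    h = params.spacing
    lam = coupling_constant(params.temperature)
    kappa, eps_kappa2 = kappa_parameters(
        params.ionic_strength, params.eps_solvent, params.temperature)

    q_grid = _spread_charges(structure, grid)
    source = 4.0 * np.pi * lam * q_grid / h  # already scaled by h²/h³

    kb2 = np.where(maps.ion_accessible, eps_kappa2, 0.0) * h * h

    phi = np.zeros(grid.dims)
    if not np.any(structure.charges):
        info = {"iterations": 0, "residual": 0.0, "omega": None,
                "kappa_invA": kappa, "lambda_A": lam}
        return GridField(grid.origin, h, phi), info

    # Dirichlet boundary from the Debye-Hückel superposition
    ax_x, ax_y, ax_z = grid.axes()
    X, Y, Z = np.meshgrid(ax_x, ax_y, ax_z, indexing="ij")
    boundary = np.zeros(grid.dims, dtype=bool)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    bpts = np.stack([X[boundary], Y[boundary], Z[boundary]], axis=1)
    phi[boundary] = debye_huckel(structure.charges, structure.coords,
                                 structure.radii, bpts, params.eps_solvent,
                                 kappa, params.temperature)

    ex, ey, ez = maps.eps_x, maps.eps_y, maps.eps_z
    # face dielectrics around each interior point
    e_w = ex[:-1, 1:-1, 1:-1]
    e_e = ex[1:, 1:-1, 1:-1]
    e_s = ey[1:-1, :-1, 1:-1]
    e_n = ey[1:-1, 1:, 1:-1]
    e_d = ez[1:-1, 1:-1, :-1]
    e_u = ez[1:-1, 1:-1, 1:]
    diag = e_w + e_e + e_s + e_n + e_d + e_u + kb2[1:-1, 1:-1, 1:-1]
    src = source[1:-1, 1:-1, 1:-1]

    ii, jj, kk = np.meshgrid(np.arange(1, nx - 1), np.arange(1, ny - 1),
                             np.arange(1, nz - 1), indexing="ij")
    red = (ii + jj + kk) % 2 == 0
    black = ~red

    omega = params.omega
    if omega is None:
        n_max = max(nx, ny, nz)
        omega = 2.0 / (1.0 + np.sin(np.pi / n_max))

    src_norm = np.linalg.norm(src)
    residuals: list[float] = []

    def _neighbour_sum() -> np.ndarray:
        return (e_w * phi[:-2, 1:-1, 1:-1] + e_e * phi[2:, 1:-1, 1:-1]
                + e_s * phi[1:-1, :-2, 1:-1] + e_n * phi[1:-1, 2:, 1:-1]
                + e_d * phi[1:-1, 1:-1, :-2] + e_u * phi[1:-1, 1:-1, 2:])

    interior = phi[1:-1, 1:-1, 1:-1]
    for iteration in range(1, params.max_iterations + 1):
        for mask in (red, black):
            gs = (_neighbour_sum() + src) / diag
            interior[mask] += omega * (gs[mask] - interior[mask])
        if iteration % 10 == 0 or iteration <= 2:
            resid = _neighbour_sum() + src - diag * interior
            rel = float(np.linalg.norm(resid) / src_norm)
            residuals.append(rel)
            if rel <= params.tolerance:
                info = {"iterations": iteration, "residual": rel,
                        "omega": float(omega), "kappa_invA": kappa,
                        "lambda_A": lam}
                return GridField(grid.origin, h, phi), info
    raise SolverDiverged(residuals)
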
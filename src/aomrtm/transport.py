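"""Transport processes: molecular diffusion, burial advection, bioirrigation.

All operators are assembled as sparse (tridiagonal) linear maps acting on
native-basis concentrations and returning *bulk* tendencies
(mol cm^-3 bulk yr^-1). The same matrices drive both the explicit tendency
functions used in tests and the implicit (backward-Euler) transport step in
the simulator, so the two cannot drift apart.

Conventions
-----------
* Depth increases downward; fluxes are positive downward (into the sediment).
* Solutes: tortuosity-corrected diffusion (Boudreau: D_s = D0/(1 - 2 ln phi)),
  porewater burial at w * phi_deep / phi (steady compaction), nonlocal
  bioirrigation exchange with bottom water in the upper ~10 cm.
* Solids and biomass: burial advection at constant velocity w, upwind.
* Upper boundary: Dirichlet bottom-water concentration for solutes,
  prescribed deposition flux for solids; lower boundary: no diffusive
  gradient, advective outflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid_and_state import Grid, SpeciesRegistry, State

#: mol cm^-2 yr^-1  ->  umol m^-2 d^-1
MOL_CM2_YR_TO_UMOL_M2_D = 1e6 * 1e4 / 365.25


@dataclass
class TransportParams:
    """Transport constants for one simulation.

    d0 : free-solution diffusion coefficients, cm^2 yr^-1, keyed by solute.
    w : burial (sedimentation) velocity, cm yr^-1.
    alpha0 : bioirrigation exchange intensity at the interface, yr^-1.
    z_irr : e-folding depth of the irrigation intensity, cm.
    irr_cutoff : hard cutoff depth below which irrigation is zero, cm.
    bottom_water : bottom-water concentration per solute, mol cm^-3.
    """

    d0: dict
    w: float = 2.75
    alpha0: float = 0.0
    z_irr: float = 5.0
    irr_cutoff: float = 10.0
    bottom_water: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.w < 0 or self.alpha0 < 0 or self.irr_cutoff < 0 or self.z_irr <= 0:
            raise ValueError("transport parameters must be non-negative (z_irr > 0)")
        for name, v in self.d0.items():
            if v < 0:
                raise ValueError(f"D0 for {name} must be >= 0")

    def d0_array(self, registry: SpeciesRegistry) -> np.ndarray:
        return np.array([self.d0[name] for name in registry.solutes])

    def bottom_water_array(self, registry: SpeciesRegistry) -> np.ndarray:
        return np.array([self.bottom_water.get(name, 0.0) for name in registry.solutes])


def effective_diffusivity(d0, porosity):
    """Tortuosity-corrected sediment diffusivity D_s = D0 / (1 - 2 ln phi)."""
    d0 = np.asarray(d0, dtype=float)
    porosity = np.asarray(porosity, dtype=float)
    if np.any(d0 < 0):
        raise ValueError("D0 must be >= 0")
    if np.any(porosity <= 0) or np.any(porosity >= 1):
        raise ValueError("porosity must lie in (0, 1)")
    return d0 / (1.0 - 2.0 * np.log(porosity))


def irrigation_intensity(params: TransportParams, grid: Grid) -> np.ndarray:
    """alpha(z) = alpha0 exp(-z / z_irr) above the cutoff depth, else 0 (yr^-1)."""
    z = grid.cell_centers
    alpha = params.alpha0 * np.exp(-z / params.z_irr)
    alpha[z > params.irr_cutoff] = 0.0
    return alpha


@dataclass
class SoluteOperator:
    """Tridiagonal linear operator: bulk tendency = A @ C + b.

    ``lower``, ``diag``, ``upper`` are the matrix bands; ``b`` carries the
    bottom-water boundary terms (without irrigation). ``b_irr`` and
    ``diag_irr`` hold the irrigation exchange separately so callers can
    include or exclude it.
    """

    lower: np.ndarray
    diag: np.ndarray
    upper: np.ndarray
    b: np.ndarray
    diag_irr: np.ndarray
    b_irr: np.ndarray

    def tendency(self, c: np.ndarray, with_irrigation: bool = True) -> np.ndarray:
        out = self.diag * c + self.b
        out[1:] += self.lower[:-1] * c[:-1]
        out[:-1] += self.upper[1:] * c[1:]
        if with_irrigation:
            out += self.diag_irr * c + self.b_irr
        return out


def build_solute_operator(
    d0: float, c_bw: float, params: TransportParams, grid: Grid
) -> SoluteOperator:
    """Assemble the finite-volume transport operator for one solute."""
    n = grid.n_cells
    dz = grid.dz
    zc = grid.cell_centers
    phi_e = grid.porosity_at_edges()
    ds_e = effective_diffusivity(d0, phi_e)

    # diffusive conductances at edges 0..n (cm yr^-1, bulk)
    g = np.zeros(n + 1)
    g[0] = phi_e[0] * ds_e[0] / zc[0]
    g[1:n] = phi_e[1:n] * ds_e[1:n] / (zc[1:] - zc[:-1])
    # porewater advection: steady compaction -> constant bulk coefficient
    a = params.w * grid.porosity[-1]

    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    b = np.zeros(n)

    # flux through top of cell i minus flux through its bottom, over dz
    for i in range(n):
        if i == 0:
            diag[0] += -g[0] / dz[0]
            b[0] += (g[0] + a) * c_bw / dz[0]
        else:
            diag[i] += -g[i] / dz[i]
            lower[i - 1] += (g[i] + a) / dz[i]
        if i < n - 1:
            diag[i] += -(g[i + 1] + a) / dz[i]
            upper[i + 1] += g[i + 1] / dz[i]
        else:
            diag[i] += -a / dz[i]

    alpha = irrigation_intensity(params, grid)
    diag_irr = -grid.porosity * alpha
    b_irr = grid.porosity * alpha * c_bw
    return SoluteOperator(lower, diag, upper, b, diag_irr, b_irr)


@dataclass
class SolidOperator:
    """Upwind burial operator for solids/biomass: bulk tendency = A @ S (+ deposition)."""

    diag: np.ndarray
    lower: np.ndarray
    dz: np.ndarray

    def tendency(self, s_bulk_velocity_scaled: np.ndarray) -> np.ndarray:
        out = self.diag * s_bulk_velocity_scaled
        out[1:] += self.lower[:-1] * s_bulk_velocity_scaled[:-1]
        return out


def build_solid_operator(params: TransportParams, grid: Grid, basis: str) -> SolidOperator:
    """Burial operator acting on native-basis contents, returning bulk tendencies.

    ``basis`` is 'solid' (mol g^-1) or 'microbe' (cells cm^-3 bulk).
    """
    n = grid.n_cells
    dz = grid.dz
    phi_e = grid.porosity_at_edges()
    if basis == "solid":
        coeff = params.w * (1.0 - phi_e) * grid.solid_density  # edge flux per unit content
    elif basis == "microbe":
        coeff = params.w * np.ones(n + 1)
    else:
        raise ValueError(f"basis {basis!r} not transported by burial operator")
    diag = np.zeros(n)
    lower = np.zeros(n)
    for i in range(n):
        diag[i] += -coeff[i + 1] / dz[i]  # outflow through bottom edge (upwind: own cell)
        if i > 0:
            lower[i - 1] += coeff[i] / dz[i]  # inflow from cell above
    return SolidOperator(diag=diag, lower=lower, dz=dz)


def diffusion_advection_tendency(
    state: State,
    params: TransportParams,
    grid: Grid,
    registry: SpeciesRegistry,
    deposition_flux: dict | None = None,
) -> dict:
    """Conservative transport tendencies on the bulk basis, without irrigation.

    Returns ``{"solutes": (9, n), "solids": (8, n), "microbes": (4, n)}`` in
    mol (or cells) cm^-3 bulk yr^-1. ``deposition_flux`` maps solid names to
    a downward flux through the interface in mol cm^-2 yr^-1.
    """
    deposition_flux = deposition_flux or {}
    n = grid.n_cells
    out_sol = np.zeros((len(registry.solutes), n))
    bw = params.bottom_water_array(registry)
    d0 = params.d0_array(registry)
    for k in range(len(registry.solutes)):
        op = build_solute_operator(d0[k], bw[k], params, grid)
        out_sol[k] = op.tendency(state.solutes[k], with_irrigation=False)

    op_solid = build_solid_operator(params, grid, "solid")
    out_solid = np.zeros((len(registry.solids), n))
    for k, name in enumerate(registry.solids):
        out_solid[k] = op_solid.tendency(state.solids[k])
        out_solid[k, 0] += deposition_flux.get(name, 0.0) / grid.dz[0]

    op_mic = build_solid_operator(params, grid, "microbe")
    out_mic = np.zeros((len(registry.microbes), n))
    for k in range(len(registry.microbes)):
        out_mic[k] = op_mic.tendency(state.microbes[k])
    return {"solutes": out_sol, "solids": out_solid, "microbes": out_mic}


def irrigation_tendency(
    state: State, params: TransportParams, grid: Grid, registry: SpeciesRegistry
) -> np.ndarray:
    """Nonlocal irrigation exchange, phi * alpha(z) * (C_bw - C), bulk basis."""
    alpha = irrigation_intensity(params, grid)
    bw = params.bottom_water_array(registry)
    return grid.porosity * alpha * (bw[:, None] - state.solutes)


def benthic_flux_components(
    state: State,
    params: TransportParams,
    grid: Grid,
    registry: SpeciesRegistry,
    solute: str,
) -> tuple:
    """(diffusive, irrigative) benthic release, umol m^-2 d^-1, positive out."""
    if solute not in registry.solutes:
        raise ValueError(f"unknown solute {solute!r}")
    k = registry.solute_index(solute)
    phi0 = grid.porosity_at_edges()[0]
    ds0 = effective_diffusivity(params.d0[solute], phi0)
    c_bw = params.bottom_water.get(solute, 0.0)
    diff_out = phi0 * ds0 * (state.solutes[k, 0] - c_bw) / grid.cell_centers[0]
    alpha = irrigation_intensity(params, grid)
    irr_out = float(
        np.sum(grid.porosity * alpha * (state.solutes[k] - c_bw) * grid.dz)
    )
    return (diff_out * MOL_CM2_YR_TO_UMOL_M2_D,
            irr_out * MOL_CM2_YR_TO_UMOL_M2_D)


def benthic_flux(
    state: State,
    params: TransportParams,
    grid: Grid,
    registry: SpeciesRegistry,
    solute: str,
) -> float:
    """Benthic release of a solute in umol m^-2 d^-1 (positive = out of sediment).

    Diffusive flux across the sediment-water interface (two-point gradient
    over the top half-cell) plus the depth-integrated irrigation exchange.
    """
    diff_out, irr_out = benthic_flux_components(state, params, grid, registry,
                                                solute)
    return diff_out + irr_out
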
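"""Gene-based guild dynamics for the four methane-oxidizing functional groups.

Each guild carries an explicit biomass state (cells cm^-3 bulk). The bulk
catalytic rate is

    R = Gamma * H_max * monod * inhibition * F_T     [mol CH4 cm^-3 yr^-1]

and biomass evolves as

    dGamma/dt = Gamma * (Z / c) * H_max * monod * inhibition * F_T - q * Gamma

with Z the biomass production coefficient (g dry mass per mol CH4), c the
dry mass per cell (g), q the first-order death rate (yr^-1) and H_max the
maximum cell-specific reaction rate (mol CH4 yr^-1 cell^-1).

The thermodynamic potential factor F_T = max(0, 1 - exp((dG + dG_min)/RT))
switches the metabolism off once the in-situ Gibbs energy dG of the guild's
catabolic reaction rises above -dG_min (the minimum energy quantum a cell
must conserve). dG = dG0' + RT ln Q with solute concentrations (converted to
mol L^-1, floored) acting as activities; solids and water have unit
activity, and protons are absorbed into dG0' (the primed standard state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geochemistry import Reaction
from .grid_and_state import Grid, SpeciesRegistry, State, to_bulk

R_GAS = 8.314462618e-3  # kJ mol^-1 K^-1

#: floor applied to solute activities inside ln Q, mol cm^-3
ACTIVITY_FLOOR = 1e-12

#: mol cm^-3 (porewater) -> mol L^-1
MOL_CM3_TO_MOL_L = 1e3

DAYS_PER_YEAR = 365.25


@dataclass
class Guild:
    """Parameters of one methane-oxidizing guild.

    km maps substrate names to half-saturation constants: solutes in
    mol cm^-3 porewater, solids in mol cm^-3 bulk. inhibitors likewise maps
    inhibiting solutes to K_in.
    """

    name: str
    h_max: float  # mol CH4 yr^-1 cell^-1
    z_yield: float  # g dry biomass per mol CH4
    cell_mass: float  # g per cell
    q: float  # death rate, yr^-1
    km: dict
    reaction: Reaction
    dg0: float  # kJ per mol CH4, primed standard state
    dg_min: float = 15.0  # kJ per mol CH4, energy quantum (positive)
    inhibitors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.h_max, self.z_yield, self.cell_mass, self.q) <= 0:
            raise ValueError("h_max, z_yield, cell_mass and q must be positive")
        if any(k <= 0 for k in self.km.values()):
            raise ValueError("half-saturation constants must be positive")

    @property
    def mu_max(self) -> float:
        """Maximum gross per-capita growth rate (Z/c) H_max, yr^-1."""
        return self.z_yield / self.cell_mass * self.h_max


@dataclass
class Limiters:
    """Dimensionless rate-limitation factors, each in [0, 1]."""

    monod: np.ndarray
    inhibition: np.ndarray
    f_t: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.monod * self.inhibition * self.f_t


def monod(c, km):
    """Michaelis-Menten limitation C / (K_m + C)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    if np.any(np.asarray(km) <= 0):
        raise ValueError("K_m must be positive")
    return c / (km + c)


def inhibition(c, kin):
    """Inhibition factor K_in / (K_in + C)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    if np.any(np.asarray(kin) <= 0):
        raise ValueError("K_in must be positive")
    return kin / (kin + c)


def gibbs_energy(guild: Guild, concentrations: dict, temperature: float):
    """In-situ Gibbs energy of the guild's reaction, kJ per mol CH4.

    ``concentrations`` maps solute names to mol cm^-3 porewater (scalars or
    arrays). Only solutes enter the activity quotient; solids, water and
    protons are at unit/absorbed activity.
    """
    ln_q = 0.0
    for species, coeff in guild.reaction.stoichiometry.items():
        if species not in concentrations:
            continue
        act = np.maximum(np.asarray(concentrations[species], dtype=float),
                         ACTIVITY_FLOOR) * MOL_CM3_TO_MOL_L
        ln_q = ln_q + coeff * np.log(act)
    return guild.dg0 + R_GAS * temperature * ln_q


def thermodynamic_factor(dg, dg_min: float, temperature: float):
    """F_T = max(0, 1 - exp((dG + dG_min) / RT)), dimensionless in [0, 1]."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    x = (np.asarray(dg, dtype=float) + dg_min) / (R_GAS * temperature)
    # exp only evaluated where it cannot overflow; F_T is 0 for any x >= 0
    return np.maximum(0.0, 1.0 - np.exp(np.minimum(x, 50.0)))


def guild_limiters(
    guild: Guild,
    state: State,
    grid: Grid,
    registry: SpeciesRegistry,
    temperature: float,
) -> Limiters:
    """Evaluate Monod, inhibition and thermodynamic factors on the grid."""
    mon = np.ones(grid.n_cells)
    for substrate, km_val in guild.km.items():
        basis = registry.basis_of(substrate)
        if basis == "solute":
            c = state.solutes[registry.solute_index(substrate)]
        else:
            c = to_bulk(state.solids[registry.solid_index(substrate)], "solid", grid)
        mon = mon * monod(c, km_val)
    inh = np.ones(grid.n_cells)
    for inhibitor, kin_val in guild.inhibitors.items():
        c = state.solutes[registry.solute_index(inhibitor)]
        inh = inh * inhibition(c, kin_val)
    conc = {name: state.solutes[registry.solute_index(name)]
            for name in registry.solutes}
    dg = gibbs_energy(guild, conc, temperature)
    f_t = thermodynamic_factor(dg, guild.dg_min, temperature)
    return Limiters(monod=mon, inhibition=inh, f_t=f_t)


def guild_rate(guild: Guild, gamma, limiters: Limiters | np.ndarray):
    """Bulk catalytic rate R = Gamma H_max (limiter product), mol CH4 cm^-3 yr^-1."""
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma < 0):
        raise ValueError("abundance must be >= 0")
    total = limiters.total if isinstance(limiters, Limiters) else np.asarray(limiters)
    return gamma * guild.h_max * total


def biomass_tendency(guild: Guild, gamma, limiters: Limiters | np.ndarray):
    """dGamma/dt = Gamma ((Z/c) H_max ltot - q), cells cm^-3 yr^-1."""
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma < 0):
        raise ValueError("abundance must be >= 0")
    total = limiters.total if isinstance(limiters, Limiters) else np.asarray(limiters)
    return gamma * (guild.mu_max * total - guild.q)


def doubling_time(guild: Guild, limiters: Limiters | np.ndarray | float = 1.0):
    """Doubling time ln 2 / mu in days; inf where growth is not positive.

    With the default ``limiters=1`` this is the fastest doubling time the
    guild can achieve; pass in-situ limiter products for local values.
    """
    if isinstance(limiters, Limiters):
        total = limiters.total
    else:
        total = np.asarray(limiters, dtype=float)
    mu = guild.mu_max * total  # gross per-capita growth, yr^-1
    with np.errstate(divide="ignore"):
        t_d = np.where(mu > 0, math.log(2.0) / np.maximum(mu, 1e-300) * DAYS_PER_YEAR,
                       np.inf)
    if t_d.ndim == 0:
        return float(t_d)
    return t_d
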
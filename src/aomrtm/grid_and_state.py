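"""Spatial grid, species registry and model state.

The model describes a 1-D sediment column below the sediment--water
interface. Dissolved species are tracked as concentrations per unit
porewater volume, particulate species per gram of dry sediment, and
microbial guilds as cell densities per unit bulk sediment volume.
Reaction rates are always assembled on the common *bulk* basis
(mol per cm^3 of whole sediment), so conversions between bases live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Grid",
    "SpeciesRegistry",
    "State",
    "build_grid",
    "to_bulk",
    "from_bulk",
    "validate_state",
    "DEFAULT_SOLUTES",
    "DEFAULT_SOLIDS",
    "DEFAULT_GUILDS",
]

#: Dissolved species (porewater basis, mol cm^-3 porewater).
DEFAULT_SOLUTES = ("O2", "NO3", "NH4", "SO4", "H2S", "Fe2", "Mn2", "CH4", "DIC")

#: Particulate species (solid basis, mol g^-1 dry sediment). Three organic
#: matter pools (multi-G), reactive metal oxides and reduced sulfur phases.
DEFAULT_SOLIDS = ("OM_fast", "OM_slow", "OM_refractory", "FeOx", "MnOx", "FeS", "FeS2", "S0")

#: Methane-oxidizing guilds carried with explicit biomass (cells cm^-3 bulk).
DEFAULT_GUILDS = ("aerobic_MOx", "SO4_ANME", "FeOx_ANME", "MnOx_ANME")

N_SOLUTES = 9
N_SOLIDS = 8
N_GUILDS = 4


@dataclass(frozen=True)
class Grid:
    """Uniform-edge 1-D finite-volume grid with an exponential porosity profile.

    Attributes
    ----------
    cell_centers, cell_edges : depth in cm below the sediment-water interface.
    porosity : porewater volume fraction at cell centers.
    solid_density : dry-solid density, g cm^-3.
    """

    n_cells: int
    cell_centers: np.ndarray
    cell_edges: np.ndarray
    porosity: np.ndarray
    solid_density: float = 2.65

    def __post_init__(self) -> None:
        edges = np.asarray(self.cell_edges, dtype=float)
        centers = np.asarray(self.cell_centers, dtype=float)
        por = np.asarray(self.porosity, dtype=float)
        if self.n_cells < 1 or len(centers) != self.n_cells or len(edges) != self.n_cells + 1:
            raise ValueError("grid shape mismatch: need n_cells centers and n_cells+1 edges")
        if edges[0] != 0.0 or np.any(np.diff(edges) <= 0):
            raise ValueError("cell_edges must be strictly increasing and start at 0")
        if np.any(por <= 0.0) or np.any(por >= 1.0):
            raise ValueError("porosity must lie strictly in (0, 1)")
        if self.solid_density <= 0:
            raise ValueError("solid_density must be positive")
        object.__setattr__(self, "cell_centers", centers)
        object.__setattr__(self, "cell_edges", edges)
        object.__setattr__(self, "porosity", por)

    @property
    def dz(self) -> np.ndarray:
        """Cell thicknesses, cm."""
        return np.diff(self.cell_edges)

    @property
    def solid_fraction(self) -> np.ndarray:
        """Solid volume fraction (1 - porosity)."""
        return 1.0 - self.porosity

    def porosity_at_edges(self) -> np.ndarray:
        """Porosity interpolated to cell edges (ends extrapolated flat)."""
        phi = self.porosity
        out = np.empty(self.n_cells + 1)
        out[1:-1] = 0.5 * (phi[:-1] + phi[1:])
        out[0] = phi[0]
        out[-1] = phi[-1]
        return out


@dataclass(frozen=True)
class SpeciesRegistry:
    """Fixed-size registry: 9 solutes, 8 solids, 4 microbial guilds."""

    solutes: tuple = DEFAULT_SOLUTES
    solids: tuple = DEFAULT_SOLIDS
    microbes: tuple = DEFAULT_GUILDS

    def __post_init__(self) -> None:
        object.__setattr__(self, "solutes", tuple(self.solutes))
        object.__setattr__(self, "solids", tuple(self.solids))
        object.__setattr__(self, "microbes", tuple(self.microbes))
        if len(self.solutes) != N_SOLUTES:
            raise ValueError(f"registry requires exactly {N_SOLUTES} solutes")
        if len(self.solids) != N_SOLIDS:
            raise ValueError(f"registry requires exactly {N_SOLIDS} solids")
        if len(self.microbes) != N_GUILDS:
            raise ValueError(f"registry requires exactly {N_GUILDS} microbial guilds")
        names = self.solutes + self.solids + self.microbes
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")

    def solute_index(self, name: str) -> int:
        return self.solutes.index(name)

    def solid_index(self, name: str) -> int:
        return self.solids.index(name)

    def microbe_index(self, name: str) -> int:
        return self.microbes.index(name)

    @property
    def all_names(self) -> tuple:
        return self.solutes + self.solids + self.microbes

    def basis_of(self, name: str) -> str:
        if name in self.solutes:
            return "solute"
        if name in self.solids:
            return "solid"
        if name in self.microbes:
            return "microbe"
        raise KeyError(name)


@dataclass
class State:
    """Concentrations of all species on the grid at one instant.

    solutes : (9, n_cells) mol cm^-3 porewater
    solids : (8, n_cells) mol g^-1 dry sediment
    microbes : (4, n_cells) cells cm^-3 bulk sediment
    time : yr
    """

    solutes: np.ndarray
    solids: np.ndarray
    microbes: np.ndarray
    time: float = 0.0

    @classmethod
    def zeros(cls, grid: Grid, registry: SpeciesRegistry, time: float = 0.0) -> "State":
        n = grid.n_cells
        return cls(
            solutes=np.zeros((len(registry.solutes), n)),
            solids=np.zeros((len(registry.solids), n)),
            microbes=np.zeros((len(registry.microbes), n)),
            time=time,
        )

    def copy(self) -> "State":
        return State(
            solutes=self.solutes.copy(),
            solids=self.solids.copy(),
            microbes=self.microbes.copy(),
            time=self.time,
        )


def build_grid(
    depth_max: float,
    n_cells: int,
    porosity_surface: float = 0.95,
    porosity_deep: float = 0.85,
    attenuation: float = 10.0,
    solid_density: float = 2.65,
) -> Grid:
    """Build a uniform grid with porosity phi(z) = phi_inf + (phi_0 - phi_inf) exp(-z/attenuation).

    Parameters are in cm; porosities are volume fractions evaluated at cell
    centers.
    """
    if depth_max <= 0:
        raise ValueError("depth_max must be positive")
    if attenuation <= 0:
        raise ValueError("attenuation must be positive")
    if n_cells < 2:
        raise ValueError("n_cells must be at least 2")
    if not (0.0 < porosity_deep <= porosity_surface < 1.0):
        raise ValueError("need 0 < porosity_deep <= porosity_surface < 1")
    edges = np.linspace(0.0, depth_max, n_cells + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    por = porosity_deep + (porosity_surface - porosity_deep) * np.exp(-centers / attenuation)
    return Grid(
        n_cells=n_cells,
        cell_centers=centers,
        cell_edges=edges,
        porosity=por,
        solid_density=solid_density,
    )


def to_bulk(value, basis: str, grid: Grid):
    """Convert a per-cell amount from its native basis to mol cm^-3 bulk.

    Solutes (mol cm^-3 porewater) are scaled by porosity; solids
    (mol g^-1 dry) by (1 - porosity) * solid_density. Microbial densities are
    already per bulk volume.
    """
    value = np.asarray(value, dtype=float)
    if basis == "solute":
        return value * grid.porosity
    if basis == "solid":
        return value * grid.solid_fraction * grid.solid_density
    if basis == "microbe":
        return value
    raise ValueError(f"unknown basis {basis!r}")


def from_bulk(value, basis: str, grid: Grid):
    """Inverse of :func:`to_bulk` (exact round-trip)."""
    value = np.asarray(value, dtype=float)
    if basis == "solute":
        return value / grid.porosity
    if basis == "solid":
        return value / (grid.solid_fraction * grid.solid_density)
    if basis == "microbe":
        return value
    raise ValueError(f"unknown basis {basis!r}")


def validate_state(state: State, grid: Grid, registry: SpeciesRegistry) -> list:
    """Check state invariants; returns a list of human-readable violations.

    Never raises: shape problems and negative concentrations are reported as
    strings naming the species, the cell and the broken rule.
    """
    violations: list = []
    n = grid.n_cells
    blocks = (
        ("solute", registry.solutes, state.solutes),
        ("solid", registry.solids, state.solids),
        ("microbe", registry.microbes, state.microbes),
    )
    for kind, names, arr in blocks:
        arr = np.asarray(arr)
        if arr.shape != (len(names), n):
            violations.append(
                f"{kind} block has shape {arr.shape}, expected {(len(names), n)}"
            )
            continue
        if not np.all(np.isfinite(arr)):
            for i, name in enumerate(names):
                bad = np.flatnonzero(~np.isfinite(arr[i]))
                for cell in bad:
                    violations.append(f"{name}: non-finite value in cell {cell}")
        neg = arr < 0
        if np.any(neg):
            for i, name in enumerate(names):
                for cell in np.flatnonzero(neg[i]):
                    violations.append(
                        f"{name}: negative concentration in cell {cell} "
                        f"({arr[i, cell]:.3e})"
                    )
    return violations
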
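"""Derived quantities: SMTZ depth, integrated rates, pathway fractions,
guild profiles and heatmap exports.

"Final-year" quantities are annual means over the requested calendar year
of the transient run. The SMTZ is reported at the first cell center
(ordered by depth) where sulfate drops below 0.1 mmol/L, without sub-cell
interpolation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import microbes as mb
from .grid_and_state import Grid
from .simulator import Trajectory

#: SMTZ threshold: 0.1 mmol/L in porewater = 1e-7 mol cm^-3
SMTZ_THRESHOLD = 1e-7

#: mol cm^-2 yr^-1 -> mmol m^-2 d^-1
MOL_CM2_YR_TO_MMOL_M2_D = 1e3 * 1e4 / 365.25

#: mol cm^-3 yr^-1 -> nmol cm^-3 d^-1
MOL_CM3_YR_TO_NMOL_CM3_D = 1e9 / 365.25

#: mol yr^-1 cell^-1 -> fmol d^-1 cell^-1
MOL_YR_TO_FMOL_D = 1e15 / 365.25


def smtz_depth(so4_profile, depths) -> float | None:
    """Shallowest depth (cm) where sulfate falls below 0.1 mmol/L, else None.

    ``so4_profile`` is in mol cm^-3 porewater, ordered by increasing depth.
    """
    so4 = np.asarray(so4_profile, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if so4.size == 0 or so4.size != depths.size:
        raise ValueError("profile must be non-empty and match the depth axis")
    below = np.flatnonzero(so4 < SMTZ_THRESHOLD)
    if below.size == 0:
        return None
    return float(depths[below[0]])


def integrated_rate(rate_field, grid: Grid) -> float:
    """Depth-integrate a bulk rate field (mol cm^-3 yr^-1) to mmol m^-2 d^-1."""
    rate_field = np.asarray(rate_field, dtype=float)
    return float(rate_field @ grid.dz) * MOL_CM2_YR_TO_MMOL_M2_D


def _year_index(traj: Trajectory, year: float) -> int:
    years = np.asarray(traj.annual.years, dtype=float)
    hits = np.flatnonzero(years == float(year))
    if hits.size == 0:
        raise ValueError(f"year {year} not in trajectory ({years.min()}..{years.max()})")
    return int(hits[0])


def pathway_fractions(traj: Trajectory, year: float) -> dict:
    """Fractions of depth- and year-integrated rates, per pathway.

    Returns ``{"ch4_oxidation": {guild: fraction}, "om_degradation":
    {pathway: fraction}}``; each group sums to 1 when its total is positive.
    A zero total yields an empty dict for that group (flagged as None).
    """
    i = _year_index(traj, year)
    aom = np.asarray(traj.annual.aom_integrals[i], dtype=float)
    out: dict = {}
    tot = aom.sum()
    out["ch4_oxidation"] = (
        {name: float(v / tot) for name, v in zip(traj.guild_names, aom)}
        if tot > 0 else None
    )
    from .geochemistry import OM_PATHWAYS

    om = np.asarray(traj.annual.om_integrals[i], dtype=float)
    tot_om = om.sum()
    out["om_degradation"] = (
        {name: float(v / tot_om) for name, v in zip(OM_PATHWAYS, om)}
        if tot_om > 0 else None
    )
    return out


def guild_profiles(traj: Trajectory, year: float, guilds: list) -> pd.DataFrame:
    """Tidy per-guild depth table for one year (annual means).

    Columns: guild, depth_cm, abundance_cells_cm3, cell_specific_fmol_d
    (bulk rate divided by abundance, so bulk = abundance x cell-specific
    exactly), doubling_time_d (ln 2 / gross per-capita growth from the
    annual-mean limiter product; inf where growth is zero), and
    bulk_rate_nmol_cm3_d.
    """
    i = _year_index(traj, year)
    grid = traj.grid
    gamma = np.asarray(traj.annual.microbes[i], dtype=float)
    rates = np.asarray(traj.annual.aom_rates[i], dtype=float)
    ltot = np.asarray(traj.annual.ltot[i], dtype=float)
    frames = []
    for g, guild in enumerate(guilds):
        with np.errstate(divide="ignore", invalid="ignore"):
            cell_specific = np.where(gamma[g] > 0, rates[g] / np.maximum(gamma[g], 1e-300), 0.0)
        td = mb.doubling_time(guild, ltot[g])
        frames.append(pd.DataFrame({
            "guild": guild.name,
            "depth_cm": grid.cell_centers,
            "abundance_cells_cm3": gamma[g],
            "cell_specific_fmol_d": cell_specific * MOL_YR_TO_FMOL_D,
            "doubling_time_d": td,
            "bulk_rate_nmol_cm3_d": rates[g] * MOL_CM3_YR_TO_NMOL_CM3_D,
        }))
    return pd.concat(frames, ignore_index=True)


def heatmap(traj: Trajectory, solute: str) -> pd.DataFrame:
    """Time x depth matrix of a saved solute (annual means, mol cm^-3).

    Rows are years, columns are cell-center depths (cm).
    """
    if solute not in traj.registry.solutes:
        raise ValueError(f"unknown solute {solute!r}")
    k = traj.registry.solute_index(solute)
    mat = np.array([sol[k] for sol in traj.annual.solutes])
    return pd.DataFrame(
        mat,
        index=pd.Index(traj.annual.years, name="year"),
        columns=pd.Index(np.round(traj.grid.cell_centers, 6), name="depth_cm"),
    )


def heatmap_export(traj: Trajectory, solute: str, path) -> None:
    """Write the heatmap matrix as CSV (lossless round-trip with the reader)."""
    heatmap(traj, solute).to_csv(path, float_format="%.17g")


def heatmap_read(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.columns = pd.Index([float(c) for c in df.columns], name="depth_cm")
    df.index = pd.Index(df.index.astype(float), name="year")
    return df


def benthic_flux_series(traj: Trajectory) -> pd.DataFrame:
    """Benthic CH4 flux per outer step, umol m^-2 d^-1 (positive = release)."""
    return pd.DataFrame({
        "time_yr": traj.step_times,
        "benthic_CH4_umol_m2_d": traj.step_benthic_ch4,
    })


def benthic_flux_table(traj: Trajectory, params) -> pd.DataFrame:
    """Final-state benthic flux per solute: diffusive, irrigative and total
    release (umol m^-2 d^-1, positive out of the sediment)."""
    from .transport import benthic_flux_components

    st = traj.states[-1]
    rows = []
    for name in traj.registry.solutes:
        diff, irr = benthic_flux_components(st, params.transport, traj.grid,
                                            traj.registry, name)
        rows.append((st.time, name, diff, irr, diff + irr))
    return pd.DataFrame(rows, columns=["time_yr", "solute", "diffusive",
                                       "irrigative", "total"])


def smtz_series(traj: Trajectory) -> pd.DataFrame:
    """Annual-mean SMTZ depth time series."""
    k = traj.registry.solute_index("SO4")
    rows = []
    for year, sol in zip(traj.annual.years, traj.annual.solutes):
        rows.append((year, smtz_depth(sol[k], traj.grid.cell_centers)))
    return pd.DataFrame(rows, columns=["year", "smtz_depth_cm"])


def state_to_frame(traj: Trajectory, index: int = -1) -> pd.DataFrame:
    """Tidy snapshot of a saved state: depth_cm, species, value, basis, time_yr."""
    st = traj.states[index]
    reg = traj.registry
    grid = traj.grid
    rows = []
    blocks = (
        ("solute", reg.solutes, st.solutes, "mol_cm3_porewater"),
        ("solid", reg.solids, st.solids, "mol_g_dry"),
        ("microbe", reg.microbes, st.microbes, "cells_cm3_bulk"),
    )
    for basis, names, arr, unit in blocks:
        for i, name in enumerate(names):
            for z, v in zip(grid.cell_centers, arr[i]):
                rows.append((z, name, v, basis, unit, st.time))
    return pd.DataFrame(
        rows, columns=["depth_cm", "species", "value", "basis", "units", "time_yr"]
    )


def trajectory_to_dataset(traj: Trajectory):
    """Annual-mean fields as an xarray Dataset (for NetCDF export)."""
    import xarray as xr

    reg = traj.registry
    years = np.asarray(traj.annual.years, dtype=float)
    depth = traj.grid.cell_centers
    ds = xr.Dataset(
        {
            "solutes": (("year", "solute", "depth"), np.array(traj.annual.solutes)),
            "solids": (("year", "solid", "depth"), np.array(traj.annual.solids)),
            "microbes": (("year", "guild", "depth"), np.array(traj.annual.microbes)),
            "aom_rate": (("year", "guild", "depth"), np.array(traj.annual.aom_rates)),
            "benthic_CH4": (("year",), np.array(traj.annual.benthic_ch4)),
        },
        coords={
            "year": years,
            "depth": ("depth", depth, {"units": "cm"}),
            "solute": list(reg.solutes),
            "solid": list(reg.solids),
            "guild": list(reg.microbes),
        },
        attrs={
            "solutes_units": "mol cm-3 porewater",
            "solids_units": "mol g-1 dry",
            "microbes_units": "cells cm-3 bulk",
            "aom_rate_units": "mol CH4 cm-3 bulk yr-1",
            "benthic_CH4_units": "umol m-2 d-1",
        },
    )
    return ds
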
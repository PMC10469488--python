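"""One-at-a-time environmental sensitivity sweeps.

Each sweep member perturbs the baseline configuration, reruns the full
transient scenario (fresh spin-up per member, so members are independent)
and is summarized by the mean benthic CH4 flux and depth-integrated
oxidation rate per pathway over the last ``summary_window`` years, plus
final-year guild relative abundances.

Perturbation mapping:

* ``salinity`` — bottom-water sulfate rescaled by conservative dilution of a
  28 mmol/L seawater endmember at salinity 35 (SO4 = 28 * S / 35 mmol/L);
  other boundary solutes are left unchanged.
* ``bw_O2`` — bottom-water O2 boundary concentration, value in umol/L.
* ``om_factor`` / ``metal_factor`` — multiply the organic-matter
  (fast/slow/refractory) or metal-oxide (FeOx/MnOx) deposition fluxes.
* ``growth_mult`` / ``death_mult`` — multiply every guild's maximum
  per-capita growth (Z/c)H_max (via the yield Z) or death rate q.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import build_params
from .simulator import Simulator, mass_audit

SWEEP_PARAMETERS = ("salinity", "bw_O2", "om_factor", "metal_factor",
                    "growth_mult", "death_mult")

#: seawater sulfate endmember: 28 mmol/L at salinity 35
SO4_PER_SALINITY = 28.0e-6 / 35.0  # mol cm^-3 per salinity unit

#: multiplier set used for the growth/death-rate analysis
GROWTH_DEATH_MULTIPLIERS = (0.5, 0.75, 0.9, 1.1, 1.25, 1.5)

OM_POOL_SPECIES = ("OM_fast", "OM_slow", "OM_refractory")
METAL_SPECIES = ("FeOx", "MnOx")


@dataclass
class SweepSpec:
    """One-at-a-time sweep over a single recognized parameter."""

    parameter: str
    values: tuple
    summary_window: float = 50.0  # yr

    def __post_init__(self) -> None:
        if self.parameter not in SWEEP_PARAMETERS:
            raise ValueError(
                f"unknown sweep parameter {self.parameter!r}; "
                f"choose from {SWEEP_PARAMETERS}"
            )
        self.values = tuple(float(v) for v in self.values)
        if not self.values:
            raise ValueError("sweep needs at least one value")


def apply_perturbation(base_config: dict, parameter: str, value: float) -> dict:
    """Return a deep-copied configuration with one parameter perturbed."""
    if parameter not in SWEEP_PARAMETERS:
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    cfg = copy.deepcopy(base_config)
    if parameter == "salinity":
        cfg["bottom_water"]["SO4"]["value"] = SO4_PER_SALINITY * value
    elif parameter == "bw_O2":
        cfg["bottom_water"]["O2"]["value"] = value * 1e-9  # umol/L -> mol/cm^3
    elif parameter == "om_factor":
        for sp in OM_POOL_SPECIES:
            cfg["scenario"]["baseline"][sp]["value"] *= value
    elif parameter == "metal_factor":
        for sp in METAL_SPECIES:
            cfg["scenario"]["baseline"][sp]["value"] *= value
    elif parameter == "growth_mult":
        for g in cfg["microbes"]["guilds"]:
            g["z_yield"]["value"] *= value
    elif parameter == "death_mult":
        for g in cfg["microbes"]["guilds"]:
            g["q"]["value"] *= value
    return cfg


def _summarize(traj, sim, window: float) -> dict:
    years = np.asarray(traj.annual.years, dtype=float)
    sel = years >= years[-1] + 1 - window
    aom = np.asarray(traj.annual.aom_integrals)[sel]  # mol cm^-2 yr^-1
    conv = 1e3 * 1e4 / 365.25  # -> mmol m^-2 d^-1
    flux = float(np.mean(np.asarray(traj.annual.benthic_ch4)[sel]))
    out = {"benthic_CH4_umol_m2_d": flux}
    for i, name in enumerate(traj.guild_names):
        out[f"rate_{name}_mmol_m2_d"] = float(aom[:, i].mean()) * conv
    gamma = np.asarray(traj.annual.microbes[-1])  # final year
    inv = gamma @ traj.grid.dz
    tot = inv.sum()
    for i, name in enumerate(traj.guild_names):
        out[f"relabund_{name}"] = float(inv[i] / tot) if tot > 0 else np.nan
    return out


def run_member(base_config: dict, parameter: str, value: float,
               summary_window: float = 50.0, audit_tol: float = 1e-6,
               progress=None) -> dict:
    """Run one perturbed member and summarize it; flags audit failures."""
    cfg = apply_perturbation(base_config, parameter, value)
    params, scenario = build_params(cfg)
    sim = Simulator(params, scenario)
    traj = sim.run(progress=progress)
    row = {"parameter": parameter, "value": value}
    row.update(_summarize(traj, sim, summary_window))
    aud = mass_audit(traj, sim)
    row["audit_max_residual"] = float(aud["max_residual"].max())
    row["audit_ok"] = bool(row["audit_max_residual"] < audit_tol)
    row["clip_fraction"] = traj.clip_fraction
    return row


def run_sweep(spec: SweepSpec, base_config: dict, progress=None) -> pd.DataFrame:
    """Run every member of a sweep; rows keyed by parameter value.

    Members are independent full runs (each with its own spin-up); a member
    whose mass audit fails is flagged in the ``audit_ok`` column and the
    sweep continues.
    """
    rows = []
    for value in spec.values:
        if progress:
            progress(f"sweep {spec.parameter} = {value}")
        try:
            rows.append(run_member(base_config, spec.parameter, value,
                                   spec.summary_window))
        except Exception as exc:  # a failed member must not kill the sweep
            rows.append({"parameter": spec.parameter, "value": value,
                         "audit_ok": False, "error": str(exc)})
    return pd.DataFrame(rows)
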
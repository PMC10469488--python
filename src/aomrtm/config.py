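"""Structured configuration: YAML with explicit unit strings, validated at load.

Every dimensioned quantity in a configuration file is written as a mapping
``{value: <number>, units: "<unit string>"}``; the loader checks the unit
string against the expected unit for that key and raises on mismatch, so a
config edited with the wrong units fails fast instead of running silently
wrong. Dimensionless quantities are plain numbers.
"""

from __future__ import annotations

import copy

import yaml
import numpy as np

from . import geochemistry as gc
from . import transport as tr
from .grid_and_state import SpeciesRegistry, build_grid
from .microbes import Guild
from .simulator import ModelParams, Numerics, Scenario


class ConfigError(ValueError):
    pass


def _q(section: dict, key: str, units: str, default=None):
    """Fetch a dimensioned quantity and validate its unit string."""
    if key not in section:
        if default is not None:
            return default
        raise ConfigError(f"missing required quantity {key!r}")
    node = section[key]
    if not isinstance(node, dict) or "value" not in node or "units" not in node:
        raise ConfigError(
            f"quantity {key!r} must be a mapping {{value, units}} (expected units {units!r})"
        )
    if node["units"] != units:
        raise ConfigError(
            f"quantity {key!r} has units {node['units']!r}, expected {units!r}"
        )
    return float(node["value"])


def _qmap(section: dict, units: str) -> dict:
    return {k: _q(section, k, units) for k in section}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration root must be a mapping")
    return cfg


def quantity(value: float, units: str) -> dict:
    """Helper for programmatic config construction."""
    return {"value": float(value), "units": units}


def build_params(cfg: dict) -> tuple:
    """Validate a configuration dict and build (ModelParams, Scenario)."""
    cfg = copy.deepcopy(cfg)
    try:
        g = cfg["grid"]
        grid = build_grid(
            depth_max=_q(g, "depth_max", "cm"),
            n_cells=int(g["n_cells"]),
            porosity_surface=float(g["porosity_surface"]),
            porosity_deep=float(g["porosity_deep"]),
            attenuation=_q(g, "attenuation", "cm"),
            solid_density=_q(g, "solid_density", "g cm-3"),
        )
        registry = SpeciesRegistry()

        t = cfg["transport"]
        transport = tr.TransportParams(
            d0={k: _q(t["d0"], k, "cm2 yr-1") for k in t["d0"]},
            w=_q(t, "w", "cm yr-1"),
            alpha0=_q(t, "alpha0", "yr-1"),
            z_irr=_q(t, "z_irr", "cm"),
            irr_cutoff=_q(t, "irr_cutoff", "cm"),
            bottom_water={k: _q(cfg["bottom_water"], k, "mol cm-3")
                          for k in cfg["bottom_water"]},
        )
        missing = set(registry.solutes) - set(transport.d0)
        if missing:
            raise ConfigError(f"d0 missing for solutes: {sorted(missing)}")

        kin = cfg["kinetics"]
        pools = [
            gc.OMPool(
                label=p["label"],
                k=_q(p, "k", "yr-1"),
                cn_ratio=float(p.get("cn_ratio", 10.0)),
            )
            for p in kin["pools"]
        ]
        if {p.label for p in pools} != {"fast", "slow", "refractory"}:
            raise ConfigError("pools must be labelled fast, slow, refractory")
        lad = kin["ladder"]
        lad_kwargs = {k: _q(lad, k, "mol cm-3") for k in lad
                      if k != "meth_factor"}
        if "meth_factor" in lad:
            lad_kwargs["meth_factor"] = float(lad["meth_factor"])
        ladder = gc.LadderKinetics(**lad_kwargs)
        secondary = {k: _q(kin["secondary"], k, "cm3 mol-1 yr-1")
                     for k in kin["secondary"]}
        known = {name for name, *_ in gc.SECONDARY_REACTIONS}
        unknown = set(secondary) - known
        if unknown:
            raise ConfigError(f"unknown secondary reactions: {sorted(unknown)}")

        network = gc.build_network(pools)  # balance check runs here

        m = cfg["microbes"]
        guilds = []
        for gd in m["guilds"]:
            name = gd["name"]
            if name not in registry.microbes:
                raise ConfigError(f"unknown guild {name!r}")
            guilds.append(Guild(
                name=name,
                h_max=_q(gd, "h_max", "mol yr-1 cell-1"),
                z_yield=_q(gd, "z_yield", "g mol-1"),
                cell_mass=_q(gd, "cell_mass", "g"),
                q=_q(gd, "q", "yr-1"),
                km={k: _q(gd["km"], k, "mol cm-3") for k in gd["km"]},
                inhibitors={k: _q(gd.get("inhibitors", {}), k, "mol cm-3")
                            for k in gd.get("inhibitors", {})},
                reaction=network[f"AOM:{name}"],
                dg0=_q(gd, "dg0", "kJ mol-1"),
                dg_min=_q(gd, "dg_min", "kJ mol-1"),
            ))
        if [g.name for g in guilds] != list(registry.microbes):
            raise ConfigError("guilds must cover the registry in order")

        th = cfg["thermodynamics"]
        num = cfg.get("numerics", {})
        numerics = Numerics(
            dt=_q(num, "dt", "yr", default=0.02),
            substep_safety=float(num.get("substep_safety", 0.3)),
            max_substeps=int(num.get("max_substeps", 200)),
            solute_floor=float(num.get("solute_floor", 1e-10)),
            save_every=_q(num, "save_every", "yr", default=1.0),
            reaction_backend=str(num.get("reaction_backend", "auto")),
        )
        params = ModelParams(
            grid=grid,
            registry=registry,
            transport=transport,
            pools=pools,
            ladder=ladder,
            secondary_k=secondary,
            guilds=guilds,
            temperature=_q(th, "temperature", "K"),
            biomass_carbon_fraction=float(m.get("carbon_fraction", 0.5)),
            seed_floor=_q(m, "seed_floor", "cells cm-3", default=100.0),
            biomass_burial=bool(m.get("biomass_burial", True)),
            numerics=numerics,
        )

        s = cfg["scenario"]
        scenario = Scenario(
            start_year=_q(s, "start_year", "yr"),
            end_year=_q(s, "end_year", "yr"),
            baseline={k: _q(s["baseline"], k, "mol cm-2 yr-1") for k in s["baseline"]},
            pulse_period=_q(s, "pulse_period", "yr"),
            pulse_duration=_q(s, "pulse_duration", "yr"),
            pulse_offset=_q(s, "pulse_offset", "yr"),
            amplitudes={k: float(v) for k, v in s.get("amplitudes", {}).items()},
            spinup_max_cycles=int(s.get("spinup_max_cycles", 12)),
            spinup_tol=float(s.get("spinup_tol", 0.01)),
        )
        bad = set(scenario.baseline) - set(registry.solids)
        if bad:
            raise ConfigError(f"deposition given for unknown solids: {sorted(bad)}")
    except KeyError as exc:
        raise ConfigError(f"missing configuration section/key: {exc}") from exc
    return params, scenario


def load_params(path) -> tuple:
    """Load a YAML config file and build (ModelParams, Scenario)."""
    return build_params(load_config(path))
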
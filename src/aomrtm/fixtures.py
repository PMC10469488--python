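"""Shipped reference calibration and small test fixtures.

``nb8_baseline`` loads the packaged NB8 reference configuration: an
Öre-Estuary-like brackish coastal site (bottom-water salinity ~6, hence
bottom-water sulfate ~4.8 mmol/L by conservative dilution of a 28 mmol/L
seawater endmember), sedimentation at 2.75 cm/yr, bioirrigation to ~10 cm,
and a transient scenario with organic-matter/metal-oxide deposition pulses
every 20 years ending in 2019. The kinetic and microbial parameters are a
reference calibration tuned to reproduce published headline model outputs
(pathway shares, peak benthic CH4 efflux, guild doubling times and rates);
they are calibration outputs, not site measurements.

``toy_column`` is a miniature (20 cells, 20 cm, 4-year scenario) used by the
fast tests; ``synthetic_profiles`` generates smooth noisy depth profiles with
the qualitative structure of the measured porewater data, for
calibration-comparison plumbing. Both are synthetic objects, never data
claims.
"""

from __future__ import annotations

import copy
import importlib.resources

import numpy as np
import pandas as pd

from .config import build_params, load_config

__all__ = ["nb8_config", "nb8_baseline", "toy_column", "synthetic_profiles"]


def nb8_config() -> dict:
    """The NB8 reference configuration as a plain dict (deep copy)."""
    ref = importlib.resources.files("aomrtm") / "data" / "nb8.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_config(path)


def nb8_baseline() -> tuple:
    """Load and validate the NB8 reference calibration -> (ModelParams, Scenario)."""
    return build_params(nb8_config())


def toy_column() -> tuple:
    """A fast miniature column for tests: 20 cells over 20 cm, 4-year scenario.

    Keeps the full 9/8/4 species registry (a fixed model-size invariant) but
    shrinks the grid, shortens the scenario and reduces spin-up so a full run
    completes in a few seconds.
    """
    cfg = toy_config()
    return build_params(cfg)


def toy_config() -> dict:
    cfg = copy.deepcopy(nb8_config())
    cfg["grid"]["depth_max"]["value"] = 20.0
    cfg["grid"]["n_cells"] = 20
    sc = cfg["scenario"]
    sc["start_year"]["value"] = 2000.0
    sc["end_year"]["value"] = 2004.0
    sc["pulse_period"]["value"] = 4.0
    sc["pulse_duration"]["value"] = 1.0
    sc["pulse_offset"]["value"] = 1.0
    sc["spinup_max_cycles"] = 2
    cfg["numerics"]["dt"]["value"] = 0.05
    return cfg


def synthetic_profiles(seed: int) -> pd.DataFrame:
    """Synthetic observed-profile tables (depth vs concentration), reproducible.

    Emulates the qualitative shapes of the measured porewater profiles:
    O2 depleted within ~0.7 cm, NO3 within ~4 cm, SO4 crossing
    0.1 mmol/L near 20 cm, CH4 rising below the SMTZ, dissolved Fe and Mn
    maxima at depth. Values are synthetic; columns: depth_cm, species,
    value_mmol_L.
    """
    rng = np.random.default_rng(seed)
    depth = np.arange(0.25, 60.0, 0.5)
    rows = []

    def add(species, values, noise):
        vals = np.maximum(values + rng.normal(0.0, noise, size=depth.size), 0.0)
        for z, v in zip(depth, vals):
            rows.append((z, species, v))

    add("O2", 0.25 * np.exp(-depth / 0.22), 0.0003)
    add("NO3", 0.010 * np.exp(-depth / 1.2), 0.0002)
    add("SO4", 4.8 / (1.0 + np.exp((depth - 14.0) / 2.0)), 0.03)
    add("CH4", 6.0 / (1.0 + np.exp(-(depth - 24.0) / 3.0)), 0.05)
    add("NH4", 3.0 * depth / (depth + 15.0), 0.03)
    add("H2S", 0.05 * np.exp(-0.5 * ((depth - 16.0) / 3.0) ** 2), 0.001)
    add("Fe2", 2.8 * (depth / 60.0) ** 1.5, 0.03)
    add("Mn2", 0.6 * (depth / 60.0) ** 1.2, 0.01)
    return pd.DataFrame(rows, columns=["depth_cm", "species", "value_mmol_L"])


SYNTHETIC_HEADER = (
    "# SYNTHETIC profiles generated by aomrtm.fixtures.synthetic_profiles --"
    " qualitative shapes only, not measurements\n"
)


def write_synthetic_profiles(path, seed: int) -> None:
    df = synthetic_profiles(seed)
    with open(path, "w") as fh:
        fh.write(SYNTHETIC_HEADER)
        df.to_csv(fh, index=False)
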
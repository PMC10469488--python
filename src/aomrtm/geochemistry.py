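"""Geochemical reaction network: organic-matter degradation and secondary redox.

Organic matter is a multi-G mixture of three pools (fast, slow, refractory)
degraded by first-order kinetics. The carbon released is partitioned over
the classical electron-acceptor ladder (aerobic respiration, denitrification,
Mn- and Fe-oxide reduction, sulfate reduction) with Monod limitation and
inhibition by the acceptors above; methanogenesis closes the residual.
Secondary redox reactions (nitrification, metal and sulfide re-oxidation,
iron-sulfide precipitation) use bimolecular rate laws.

All stoichiometries are element- and charge-balanced; the balance is checked
numerically whenever a :class:`Reaction` is constructed, including for
networks loaded from user-edited configuration files. Water, protons, N2 and
H2 appear in the stoichiometries for bookkeeping but are not prognostic
("virtual" species); pH is not modelled.

Rate bases: solute concentrations enter rate laws in mol cm^-3 porewater and
solids in mol cm^-3 bulk; all returned rates are mol cm^-3 bulk yr^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid_and_state import Grid, SpeciesRegistry, State, to_bulk

#: Elemental composition and charge of every species that may appear in a
#: stoichiometry. Organic-matter pools are added per-network because their
#: N content depends on the configured C:N ratio.
BASE_COMPOSITION = {
    "O2": {"O": 2},
    "NO3": {"N": 1, "O": 3, "charge": -1},
    "NH4": {"N": 1, "H": 4, "charge": 1},
    "SO4": {"S": 1, "O": 4, "charge": -2},
    "H2S": {"S": 1, "H": 2},
    "Fe2": {"Fe": 1, "charge": 2},
    "Mn2": {"Mn": 1, "charge": 2},
    "CH4": {"C": 1, "H": 4},
    "DIC": {"C": 1, "O": 2},  # bookkept as CO2
    "FeOx": {"Fe": 1, "O": 3, "H": 3},  # Fe(OH)3
    "MnOx": {"Mn": 1, "O": 2},  # MnO2
    "FeS": {"Fe": 1, "S": 1},
    "FeS2": {"Fe": 1, "S": 2},
    "S0": {"S": 1},
    # virtual (non-prognostic) species
    "H2O": {"H": 2, "O": 1},
    "Hplus": {"H": 1, "charge": 1},
    "N2": {"N": 2},
    "H2": {"H": 2},
}

VIRTUAL_SPECIES = ("H2O", "Hplus", "N2", "H2")

ELEMENTS = ("C", "N", "S", "Fe", "Mn", "O", "H", "charge")

BALANCE_TOL = 1e-9


def om_composition(cn_ratio: float) -> dict:
    """Composition of one mole of organic carbon, CH2O(NH3)_{1/CN}."""
    nc = 1.0 / cn_ratio
    return {"C": 1, "H": 2 + 3 * nc, "O": 1, "N": nc}


@dataclass(frozen=True)
class Reaction:
    """A stoichiometrically closed reaction (coefficients: negative = consumed)."""

    name: str
    stoichiometry: dict
    rate_law: str = "bimolecular"
    constants: dict = field(default_factory=dict)
    composition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        comp = dict(BASE_COMPOSITION)
        comp.update(self.composition)
        for element in ELEMENTS:
            total = 0.0
            for species, coeff in self.stoichiometry.items():
                if species not in comp:
                    raise ValueError(f"{self.name}: unknown species {species!r}")
                total += coeff * comp[species].get(element, 0.0)
            if abs(total) > BALANCE_TOL:
                raise ValueError(
                    f"reaction {self.name!r} is not balanced in {element}: "
                    f"residual {total:+.3e}"
                )


@dataclass(frozen=True)
class OMPool:
    """One organic-matter pool of the multi-G model."""

    label: str
    k: float  # first-order decay constant, yr^-1
    cn_ratio: float = 10.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("decay constant must be >= 0")
        if self.label == "refractory" and self.k != 0:
            raise ValueError("refractory pool must have k = 0")


#: OM degradation pathways in ladder order; the last is the residual.
OM_PATHWAYS = ("aerobic", "denitrification", "MnOx_reduction", "FeOx_reduction",
               "SO4_reduction", "methanogenesis")


def om_pathway_stoichiometry(pathway: str, pool_name: str, cn_ratio: float) -> dict:
    """Stoichiometry per mole of pool carbon degraded through ``pathway``."""
    nc = 1.0 / cn_ratio
    base = {pool_name: -1.0, "NH4": nc, "Hplus": -nc}
    if pathway == "aerobic":
        extra = {"O2": -1.0, "DIC": 1.0, "H2O": 1.0}
    elif pathway == "denitrification":
        extra = {"NO3": -0.8, "Hplus": -0.8, "DIC": 1.0, "N2": 0.4, "H2O": 1.4}
    elif pathway == "MnOx_reduction":
        extra = {"MnOx": -2.0, "Hplus": -4.0, "DIC": 1.0, "Mn2": 2.0, "H2O": 3.0}
    elif pathway == "FeOx_reduction":
        extra = {"FeOx": -4.0, "Hplus": -8.0, "DIC": 1.0, "Fe2": 4.0, "H2O": 11.0}
    elif pathway == "SO4_reduction":
        extra = {"SO4": -0.5, "Hplus": -1.0, "DIC": 1.0, "H2S": 0.5, "H2O": 1.0}
    elif pathway == "methanogenesis":
        extra = {"CH4": 0.5, "DIC": 0.5}
    else:
        raise ValueError(f"unknown pathway {pathway!r}")
    for sp, coeff in extra.items():
        base[sp] = base.get(sp, 0.0) + coeff
    return base


#: Secondary redox reactions: (name, stoichiometry, (reactant_A, basis), (reactant_B, basis))
SECONDARY_REACTIONS = (
    ("nitrification",
     {"NH4": -1, "O2": -2, "NO3": 1, "H2O": 1, "Hplus": 2}, "NH4", "O2"),
    ("Fe2_oxidation_O2",
     {"Fe2": -1, "O2": -0.25, "H2O": -2.5, "FeOx": 1, "Hplus": 2}, "Fe2", "O2"),
    ("Fe2_oxidation_MnOx",
     {"Fe2": -1, "MnOx": -0.5, "H2O": -2, "FeOx": 1, "Mn2": 0.5, "Hplus": 1}, "Fe2", "MnOx"),
    ("Mn2_oxidation_O2",
     {"Mn2": -1, "O2": -0.5, "H2O": -1, "MnOx": 1, "Hplus": 2}, "Mn2", "O2"),
    ("H2S_oxidation_O2",
     {"H2S": -1, "O2": -2, "SO4": 1, "Hplus": 2}, "H2S", "O2"),
    ("H2S_oxidation_FeOx",
     {"H2S": -1, "FeOx": -2, "Hplus": -4, "S0": 1, "Fe2": 2, "H2O": 6}, "H2S", "FeOx"),
    ("H2S_oxidation_MnOx",
     {"H2S": -1, "MnOx": -1, "Hplus": -2, "S0": 1, "Mn2": 1, "H2O": 2}, "H2S", "MnOx"),
    ("FeS_precipitation",
     {"Fe2": -1, "H2S": -1, "FeS": 1, "Hplus": 2}, "Fe2", "H2S"),
    ("pyrite_formation",
     {"FeS": -1, "H2S": -1, "FeS2": 1, "H2": 1}, "FeS", "H2S"),
)

#: Methane oxidation stoichiometries used by the microbial guilds (per mol CH4).
AOM_REACTIONS = {
    "aerobic_MOx": {"CH4": -1, "O2": -2, "DIC": 1, "H2O": 2},
    "SO4_ANME": {"CH4": -1, "SO4": -1, "Hplus": -2, "DIC": 1, "H2S": 1, "H2O": 2},
    "FeOx_ANME": {"CH4": -1, "FeOx": -8, "Hplus": -16, "DIC": 1, "Fe2": 8, "H2O": 22},
    "MnOx_ANME": {"CH4": -1, "MnOx": -4, "Hplus": -8, "DIC": 1, "Mn2": 4, "H2O": 6},
}


@dataclass
class LadderKinetics:
    """Half-saturation and inhibition constants of the acceptor ladder.

    Solute constants (`k_o2`, `k_no3`, `k_so4` and the matching inhibition
    constants) are in mol cm^-3 porewater; solid constants (`k_mnox`,
    `k_feox`) in mol cm^-3 bulk.
    """

    k_o2: float = 8e-9
    k_no3: float = 5e-9
    k_mnox: float = 2e-6
    k_feox: float = 1e-5
    k_so4: float = 1e-7
    kin_o2: float = 8e-9
    kin_no3: float = 5e-9
    kin_mnox: float = 2e-6
    kin_feox: float = 1e-5
    kin_so4: float = 1e-7
    #: rate multiplier on the methanogenic (residual) pathway: organic
    #: matter that only methanogenesis can degrade decays this much slower
    #: than acceptor-coupled degradation (dimensionless, (0, 1])
    meth_factor: float = 1.0


def _monod(c, k):
    return c / (k + c)


def _inhib(c, k):
    return k / (k + c)


def om_pathway_fractions(
    state: State, grid: Grid, registry: SpeciesRegistry, ladder: LadderKinetics
) -> np.ndarray:
    """Fractional partitioning of OM degradation over the ladder, per cell.

    Returns an array of shape (6, n_cells) ordered as :data:`OM_PATHWAYS`;
    columns sum to 1. Methanogenesis takes the residual; if the explicit
    terms sum above 1 (possible when inhibition constants are edited away
    from the matching half-saturations) they are renormalized.
    """
    o2 = state.solutes[registry.solute_index("O2")]
    no3 = state.solutes[registry.solute_index("NO3")]
    so4 = state.solutes[registry.solute_index("SO4")]
    mnox = to_bulk(state.solids[registry.solid_index("MnOx")], "solid", grid)
    feox = to_bulk(state.solids[registry.solid_index("FeOx")], "solid", grid)

    i_o2 = _inhib(o2, ladder.kin_o2)
    i_no3 = _inhib(no3, ladder.kin_no3)
    i_mn = _inhib(mnox, ladder.kin_mnox)
    i_fe = _inhib(feox, ladder.kin_feox)

    f = np.zeros((len(OM_PATHWAYS), grid.n_cells))
    f[0] = _monod(o2, ladder.k_o2)
    f[1] = _monod(no3, ladder.k_no3) * i_o2
    f[2] = _monod(mnox, ladder.k_mnox) * i_o2 * i_no3
    f[3] = _monod(feox, ladder.k_feox) * i_o2 * i_no3 * i_mn
    f[4] = _monod(so4, ladder.k_so4) * i_o2 * i_no3 * i_mn * i_fe
    explicit = f[:5].sum(axis=0)
    over = explicit > 1.0
    if np.any(over):
        f[:5, over] /= explicit[over]
        explicit = np.minimum(explicit, 1.0)
    f[5] = 1.0 - np.minimum(explicit, 1.0)
    return f


def om_pathway_rates(
    state: State,
    grid: Grid,
    registry: SpeciesRegistry,
    pools: list,
    ladder: LadderKinetics,
) -> dict:
    """Per-pool, per-pathway carbon degradation rates, mol C cm^-3 bulk yr^-1.

    Returns ``{"fractions": (6, n), "totals": {pool: (n,)}, "rates": {(pathway, pool): (n,)}}``.
    """
    fractions = om_pathway_fractions(state, grid, registry, ladder)
    totals = {}
    rates = {}
    for pool in pools:
        name = f"OM_{pool.label}"
        om_bulk = to_bulk(state.solids[registry.solid_index(name)], "solid", grid)
        nominal = pool.k * om_bulk
        for p, pathway in enumerate(OM_PATHWAYS):
            factor = ladder.meth_factor if pathway == "methanogenesis" else 1.0
            rates[(pathway, name)] = factor * fractions[p] * nominal
        # realized total: degradation slows where only methanogenesis remains
        totals[name] = nominal * (fractions[:5].sum(axis=0)
                                  + ladder.meth_factor * fractions[5])
    return {"fractions": fractions, "totals": totals, "rates": rates}


def secondary_redox_rates(
    state: State,
    grid: Grid,
    registry: SpeciesRegistry,
    rate_constants: dict,
) -> dict:
    """Bimolecular secondary redox rates r = k [A][B] on the bulk basis.

    ``rate_constants`` maps reaction names to k in (mol cm^-3 bulk)^-1 yr^-1.
    """

    def bulk_of(name: str) -> np.ndarray:
        basis = registry.basis_of(name)
        if basis == "solute":
            return to_bulk(state.solutes[registry.solute_index(name)], "solute", grid)
        return to_bulk(state.solids[registry.solid_index(name)], "solid", grid)

    out = {}
    for name, _stoich, a, b in SECONDARY_REACTIONS:
        k = rate_constants.get(name, 0.0)
        out[name] = k * bulk_of(a) * bulk_of(b)
    return out


def methanogenesis_partition(rate_total):
    """Split a methanogenic carbon flux 2 CH2O -> CH4 + CO2 into source terms."""
    rate_total = np.asarray(rate_total, dtype=float)
    if np.any(rate_total < 0):
        raise ValueError("methanogenesis rate must be >= 0")
    return 0.5 * rate_total, 0.5 * rate_total


def build_network(pools: list, cn_override: dict | None = None) -> dict:
    """Construct (and balance-check) every Reaction of the shipped network.

    Returns a dict name -> :class:`Reaction`. OM pathway reactions are
    instantiated per pool as ``"<pathway>:<OM_pool>"``.
    """
    network: dict = {}
    for pool in pools:
        pool_sp = f"OM_{pool.label}"
        comp = {pool_sp: om_composition(pool.cn_ratio)}
        for pathway in OM_PATHWAYS:
            name = f"{pathway}:{pool_sp}"
            network[name] = Reaction(
                name=name,
                stoichiometry=om_pathway_stoichiometry(pathway, pool_sp, pool.cn_ratio),
                rate_law="first_order_partitioned",
                composition=comp,
            )
    for name, stoich, a, b in SECONDARY_REACTIONS:
        network[name] = Reaction(name=name, stoichiometry=stoich, rate_law="bimolecular")
    for guild, stoich in AOM_REACTIONS.items():
        network[f"AOM:{guild}"] = Reaction(
            name=f"AOM:{guild}", stoichiometry=stoich, rate_law="guild"
        )
    return network


def assemble_source_terms(
    rates: dict,
    network: dict,
    registry: SpeciesRegistry,
    n_cells: int,
) -> dict:
    """Sum stoichiometry-weighted rates into per-species bulk tendencies.

    ``rates`` maps reaction names to per-cell rates (mol cm^-3 bulk yr^-1, all
    >= 0); unknown reaction names raise. Virtual species are skipped.
    Returns ``{"solutes": (9, n), "solids": (8, n)}``.
    """
    out_sol = np.zeros((len(registry.solutes), n_cells))
    out_solid = np.zeros((len(registry.solids), n_cells))
    for name, rate in rates.items():
        if name not in network:
            raise KeyError(f"rate given for unknown reaction {name!r}")
        rate = np.asarray(rate, dtype=float)
        if np.any(rate < -BALANCE_TOL):
            raise ValueError(f"negative rate for reaction {name!r}")
        for species, coeff in network[name].stoichiometry.items():
            if species in VIRTUAL_SPECIES:
                continue
            basis = registry.basis_of(species)
            if basis == "solute":
                out_sol[registry.solute_index(species)] += coeff * rate
            elif basis == "solid":
                out_solid[registry.solid_index(species)] += coeff * rate
    return {"solutes": out_sol, "solids": out_solid}
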
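import numpy as np
import pytest

from aomrtm import geochemistry as gc
from aomrtm.grid_and_state import State, to_bulk
from .conftest import random_state

POOLS = [
    gc.OMPool("fast", 3.0, cn_ratio=8.0),
    gc.OMPool("slow", 0.1, cn_ratio=10.0),
    gc.OMPool("refractory", 0.0, cn_ratio=12.0),
]


@pytest.fixture(scope="module")
def network():
    return gc.build_network(POOLS)


class TestReactionBalance:
    def test_shipped_network_is_balanced(self, network):
        # constructing a Reaction runs the numerical element/charge check,
        # so reaching here means every shipped stoichiometry is closed
        assert len(network) >= 6 * 3 + 9 + 4

    def test_unbalanced_reaction_rejected(self):
        with pytest.raises(ValueError, match="not balanced"):
            gc.Reaction("bad", {"CH4": -1, "DIC": 1})  # loses H, O

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            gc.Reaction("bad", {"Unobtainium": -1})

    def test_refractory_pool_must_be_inert(self):
        with pytest.raises(ValueError):
            gc.OMPool("refractory", 0.5)


class TestPathwayLadder:
    def _state(self, grid, registry, **conc):
        st = State.zeros(grid, registry)
        for name, value in conc.items():
            if name in registry.solutes:
                st.solutes[registry.solute_index(name)] = value
            else:
                st.solids[registry.solid_index(name)] = value
        return st

    def test_oxygen_saturated_top_of_ladder(self, flat_grid, registry):
        ladder = gc.LadderKinetics()
        st = self._state(flat_grid, registry, O2=1e-3)  # O2 >> K_O2
        f = gc.om_pathway_fractions(st, flat_grid, registry, ladder)
        assert np.all(f[0] > 0.999)
        assert np.all(f[1:].sum(axis=0) < 1e-3)

    def test_no_acceptors_all_methanogenesis(self, flat_grid, registry):
        ladder = gc.LadderKinetics()
        st = State.zeros(flat_grid, registry)
        f = gc.om_pathway_fractions(st, flat_grid, registry, ladder)
        assert np.allclose(f[5], 1.0)

    def test_half_saturation_split(self, flat_grid, registry):
        ladder = gc.LadderKinetics()
        st = self._state(flat_grid, registry, O2=ladder.k_o2)
        f = gc.om_pathway_fractions(st, flat_grid, registry, ladder)
        assert np.allclose(f[0], 0.5)
        assert np.allclose(f[5], 0.5)

    def test_fractions_sum_to_one_any_state(self, grid, registry, rng):
        ladder = gc.LadderKinetics()
        st = random_state(grid, registry, rng)
        f = gc.om_pathway_fractions(st, grid, registry, ladder)
        assert np.allclose(f.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(f >= 0)

    def test_rates_scale_with_pool_inventory(self, flat_grid, registry):
        ladder = gc.LadderKinetics()
        st = self._state(flat_grid, registry, OM_fast=1e-5)
        out = gc.om_pathway_rates(st, flat_grid, registry, POOLS, ladder)
        om_bulk = to_bulk(st.solids[registry.solid_index("OM_fast")],
                          "solid", flat_grid)
        assert np.allclose(out["totals"]["OM_fast"], 3.0 * om_bulk)
        assert np.allclose(out["totals"]["OM_refractory"], 0.0)


class TestSecondaryRedox:
    def test_zero_reactant_zero_rate(self, flat_grid, registry):
        st = State.zeros(flat_grid, registry)
        st.solutes[registry.solute_index("O2")] = 1e-7
        rates = gc.secondary_redox_rates(st, flat_grid, registry,
                                         {"nitrification": 1e10})
        assert np.allclose(rates["nitrification"], 0.0)

    def test_bilinearity_in_each_reactant(self, flat_grid, registry):
        st = State.zeros(flat_grid, registry)
        st.solutes[registry.solute_index("H2S")] = 1e-7
        st.solutes[registry.solute_index("O2")] = 2e-7
        k = {"H2S_oxidation_O2": 5e9}
        r1 = gc.secondary_redox_rates(st, flat_grid, registry, k)["H2S_oxidation_O2"]
        st.solutes[registry.solute_index("H2S")] *= 2
        r2 = gc.secondary_redox_rates(st, flat_grid, registry, k)["H2S_oxidation_O2"]
        assert np.allclose(r2, 2 * r1)

    def test_rate_arithmetic(self, registry):
        # k = 100 yr^-1 (mol cm^-3)^-1 with both reactants at 1e-6 mol/cm3
        # bulk gives r = 1e-10 mol cm^-3 yr^-1
        from aomrtm.grid_and_state import build_grid
        g = build_grid(1.0, 2, porosity_surface=0.5, porosity_deep=0.5,
                       solid_density=2.0)
        st = State.zeros(g, registry)
        st.solutes[registry.solute_index("Fe2")] = 2e-6  # bulk: *0.5 -> 1e-6
        st.solutes[registry.solute_index("H2S")] = 2e-6
        r = gc.secondary_redox_rates(st, g, registry,
                                     {"FeS_precipitation": 100.0})
        assert np.allclose(r["FeS_precipitation"], 1e-10)

    def test_all_rates_nonnegative(self, grid, registry, rng):
        st = random_state(grid, registry, rng)
        ks = {name: 1e9 for name, *_ in gc.SECONDARY_REACTIONS}
        rates = gc.secondary_redox_rates(st, grid, registry, ks)
        for r in rates.values():
            assert np.all(r >= 0)


class TestMethanogenesisPartition:
    @pytest.mark.parametrize("rate", [0.0, 1.0, 3.7e-6])
    def test_equal_split_and_carbon_closure(self, rate):
        ch4, dic = gc.methanogenesis_partition(rate)
        assert ch4 == pytest.approx(rate / 2)
        assert dic == pytest.approx(rate / 2)
        assert ch4 + dic == pytest.approx(rate)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            gc.methanogenesis_partition(-1.0)


class TestAssembleSourceTerms:
    def test_zero_rates_zero_tendency(self, network, registry):
        out = gc.assemble_source_terms({}, network, registry, 5)
        assert np.allclose(out["solutes"], 0.0)
        assert np.allclose(out["solids"], 0.0)

    def test_single_reaction_matches_stoichiometry(self, network, registry):
        out = gc.assemble_source_terms({"FeS_precipitation": np.ones(3)},
                                       network, registry, 3)
        assert np.allclose(out["solutes"][registry.solute_index("Fe2")], -1.0)
        assert np.allclose(out["solutes"][registry.solute_index("H2S")], -1.0)
        assert np.allclose(out["solids"][registry.solid_index("FeS")], 1.0)

    def test_element_conservation_brute_force(self, network, registry, rng):
        """Random positive rates: element totals across the full network
        close to 1e-10, bookkeeping N2/H2 as explicit sinks."""
        comp = dict(gc.BASE_COMPOSITION)
        for pool in POOLS:
            comp[f"OM_{pool.label}"] = gc.om_composition(pool.cn_ratio)
        rates = {name: rng.uniform(0, 1e-6, 4) for name in network}
        out = gc.assemble_source_terms(rates, network, registry, 4)
        for element in ("C", "N", "S", "Fe", "Mn"):
            total = np.zeros(4)
            for k, name in enumerate(registry.solutes):
                total += out["solutes"][k] * comp[name].get(element, 0.0)
            for k, name in enumerate(registry.solids):
                total += out["solids"][k] * comp[name].get(element, 0.0)
            # independent bookkeeping of the virtual sinks
            for name, reaction in network.items():
                for sp, coeff in reaction.stoichiometry.items():
                    if sp in gc.VIRTUAL_SPECIES:
                        total += coeff * rates[name] * comp[sp].get(element, 0.0)
            assert np.max(np.abs(total)) < 1e-10

    def test_unknown_reaction_rejected(self, network, registry):
        with pytest.raises(KeyError):
            gc.assemble_source_terms({"warp_drive": np.ones(2)}, network,
                                     registry, 2)

    def test_negative_rate_rejected(self, network, registry):
        with pytest.raises(ValueError):
            gc.assemble_source_terms({"nitrification": -np.ones(2)}, network,
                                     registry, 2)
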
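import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aomrtm import microbes as mb
from aomrtm.geochemistry import AOM_REACTIONS, Reaction

R_GAS = mb.R_GAS
T = 277.15


@pytest.fixture(scope="module")
def so4_guild():
    """SO4-driven anaerobic methanotroph with a 124-day fastest doubling."""
    mu_max = math.log(2.0) * 365.25 / 124.0  # yr^-1
    h_max = 1.8e-15 * 365.25  # 1.8 fmol cell^-1 d^-1
    cell_mass = 1e-14
    return mb.Guild(
        name="SO4_ANME",
        h_max=h_max,
        z_yield=mu_max * cell_mass / h_max,
        cell_mass=cell_mass,
        q=1.0,
        km={"CH4": 1.5e-8, "SO4": 3e-7},
        reaction=Reaction("AOM:SO4_ANME", AOM_REACTIONS["SO4_ANME"]),
        dg0=-30.0,
        dg_min=12.0,
    )


class TestMonodInhibition:
    @pytest.mark.parametrize("c,km,expected", [
        (0.0, 1e-7, 0.0),
        (1e-7, 1e-7, 0.5),
        (3e-7, 1e-7, 0.75),
    ])
    def test_monod_limit_cases(self, c, km, expected):
        assert mb.monod(c, km) == pytest.approx(expected)

    @pytest.mark.parametrize("c,kin,expected", [
        (0.0, 1e-7, 1.0),
        (1e-7, 1e-7, 0.5),
        (1e3, 1e-7, 0.0),
    ])
    def test_inhibition_limit_cases(self, c, kin, expected):
        assert mb.inhibition(c, kin) == pytest.approx(expected, abs=1e-9)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            mb.monod(-1.0, 1e-7)
        with pytest.raises(ValueError):
            mb.inhibition(-1.0, 1e-7)

    @given(c=st.floats(0, 1e-3), km=st.floats(1e-12, 1e-3))
    @settings(max_examples=200, deadline=None)
    def test_factors_in_unit_interval(self, c, km):
        m = mb.monod(c, km)
        i = mb.inhibition(c, km)
        assert 0.0 <= m < 1.0
        assert 0.0 < i <= 1.0
        assert 0.0 <= m * i <= 1.0


class TestThermodynamicFactor:
    def test_zero_at_threshold(self):
        assert mb.thermodynamic_factor(-12.0, 12.0, T) == 0.0

    def test_zero_above_threshold(self):
        assert mb.thermodynamic_factor(-5.0, 12.0, T) == 0.0
        assert mb.thermodynamic_factor(+40.0, 12.0, T) == 0.0

    def test_limit_to_one(self):
        assert mb.thermodynamic_factor(-1e4, 12.0, T) == pytest.approx(1.0)

    def test_one_rt_below_threshold(self):
        # dG + dG_min = -RT gives F_T = 1 - 1/e
        dg = -12.0 - R_GAS * T
        assert mb.thermodynamic_factor(dg, 12.0, T) == pytest.approx(1 - math.exp(-1))

    def test_continuity_near_threshold(self):
        dgs = np.linspace(-13.0, -11.0, 2001)
        ft = mb.thermodynamic_factor(dgs, 12.0, T)
        assert np.all(np.abs(np.diff(ft)) < 1e-3)
        assert np.all(ft[dgs >= -12.0] == 0.0)

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            mb.thermodynamic_factor(-30.0, 12.0, 0.0)


class TestGibbsEnergy:
    def test_unit_quotient_returns_standard_value(self, so4_guild):
        # all solute activities at 1 mol/L -> ln Q = 0
        conc = {name: 1e-3 for name in ("CH4", "SO4", "H2S", "DIC")}
        assert mb.gibbs_energy(so4_guild, conc, T) == pytest.approx(-30.0)

    def test_products_raise_dg(self, so4_guild):
        base = {"CH4": 1e-6, "SO4": 1e-6, "H2S": 1e-8, "DIC": 1e-6}
        dg0 = mb.gibbs_energy(so4_guild, base, T)
        base["H2S"] = 1e-6
        assert mb.gibbs_energy(so4_guild, base, T) > dg0

    def test_rt_lnq_arithmetic(self, so4_guild):
        # choose concentrations so RT ln Q = +10 exactly
        lnq = 10.0 / (R_GAS * T)
        conc = {"CH4": 1e-3, "SO4": 1e-3, "DIC": 1e-3 * math.exp(lnq), "H2S": 1e-3}
        assert mb.gibbs_energy(so4_guild, conc, T) == pytest.approx(-20.0, abs=1e-9)

    def test_activity_floor_applied(self, so4_guild):
        conc = {"CH4": 0.0, "SO4": 0.0, "H2S": 0.0, "DIC": 0.0}
        assert np.isfinite(mb.gibbs_energy(so4_guild, conc, T))


class TestGuildRate:
    def test_zero_abundance(self, so4_guild):
        assert mb.guild_rate(so4_guild, 0.0, 1.0) == 0.0

    def test_unit_arithmetic(self):
        # 1e8 cells at 1.5 fmol cell^-1 d^-1, unlimited -> 150 nmol cm^-3 d^-1
        g = mb.Guild(
            name="aerobic_MOx", h_max=1.5e-15 * 365.25, z_yield=1.0,
            cell_mass=1e-14, q=1.0, km={"CH4": 1e-8},
            reaction=Reaction("AOM:aerobic_MOx", AOM_REACTIONS["aerobic_MOx"]),
            dg0=-820.0,
        )
        rate = mb.guild_rate(g, 1e8, 1.0)  # mol cm^-3 yr^-1
        assert rate * 1e9 / 365.25 == pytest.approx(150.0)

    def test_linearity_in_limiters(self, so4_guild):
        full = mb.guild_rate(so4_guild, 1e8, 0.8)
        half = mb.guild_rate(so4_guild, 1e8, 0.4)
        assert half == pytest.approx(full / 2)

    def test_growth_rate_consistency(self, so4_guild, rng):
        """Gross growth equals (Z/c) times the catalytic rate (Eq.1 <-> Eq.2)."""
        gamma = rng.uniform(0, 1e9, 50)
        ltot = rng.uniform(0, 1, 50)
        rate = mb.guild_rate(so4_guild, gamma, ltot)
        tend = mb.biomass_tendency(so4_guild, gamma, ltot)
        gross = tend + so4_guild.q * gamma
        assert np.allclose(gross, so4_guild.z_yield / so4_guild.cell_mass * rate,
                           rtol=1e-12)


class TestBiomassTendency:
    def test_pure_decay_when_fully_limited(self, so4_guild):
        assert mb.biomass_tendency(so4_guild, 1e8, 0.0) == pytest.approx(-so4_guild.q * 1e8)

    def test_no_spontaneous_generation(self, so4_guild):
        assert mb.biomass_tendency(so4_guild, 0.0, 1.0) == 0.0

    def test_chemostat_three_way(self, so4_guild):
        """Above the equilibrium limiter product biomass grows, below it
        decays, and exactly at q c/(Z H_max) it is steady."""
        ltot_star = so4_guild.q * so4_guild.cell_mass / (
            so4_guild.z_yield * so4_guild.h_max)
        assert 0 < ltot_star < 1
        assert mb.biomass_tendency(so4_guild, 1e7, ltot_star * 1.1) > 0
        assert mb.biomass_tendency(so4_guild, 1e7, ltot_star * 0.9) < 0
        assert mb.biomass_tendency(so4_guild, 1e7, ltot_star) == pytest.approx(0.0, abs=1e-3)


class TestDoublingTime:
    def test_definition(self, so4_guild):
        # mu = ln 2 / yr -> doubling in exactly one year
        ltot = math.log(2.0) / so4_guild.mu_max
        assert mb.doubling_time(so4_guild, ltot) == pytest.approx(365.25)

    def test_fastest_is_124_days(self, so4_guild):
        assert mb.doubling_time(so4_guild) == pytest.approx(124.0, rel=1e-12)

    def test_in_situ_never_faster_than_fastest(self, so4_guild, rng):
        ltot = rng.uniform(0, 1, 100)
        td = mb.doubling_time(so4_guild, ltot)
        assert np.all(td >= mb.doubling_time(so4_guild) - 1e-9)

    def test_no_growth_is_infinite(self, so4_guild):
        assert mb.doubling_time(so4_guild, 0.0) == np.inf


class TestGuildLimiters:
    def test_product_in_unit_interval(self, toy, rng):
        from .conftest import random_state

        params, _ = toy
        state = random_state(params.grid, params.registry, rng)
        for guild in params.guilds:
            lim = mb.guild_limiters(guild, state, params.grid, params.registry,
                                    params.temperature)
            for factor in (lim.monod, lim.inhibition, lim.f_t, lim.total):
                assert np.all(factor >= 0.0) and np.all(factor <= 1.0)

    def test_stoichiometric_coupling(self, toy):
        """Each guild consumes CH4 and its acceptor in the exact ratio of its
        reaction stoichiometry (8 FeOx, 4 MnOx, 1 SO4, 2 O2 per CH4)."""
        params, _ = toy
        expected = {"aerobic_MOx": ("O2", 2.0), "SO4_ANME": ("SO4", 1.0),
                    "FeOx_ANME": ("FeOx", 8.0), "MnOx_ANME": ("MnOx", 4.0)}
        for guild in params.guilds:
            acceptor, ratio = expected[guild.name]
            stoich = guild.reaction.stoichiometry
            assert stoich["CH4"] == -1
            assert stoich[acceptor] == -ratio
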
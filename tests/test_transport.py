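import numpy as np
import pytest
from scipy.linalg import solve_banded

from aomrtm.grid_and_state import SpeciesRegistry, State, build_grid
from aomrtm.transport import (
    TransportParams,
    benthic_flux,
    build_solute_operator,
    diffusion_advection_tendency,
    effective_diffusivity,
    irrigation_tendency,
    MOL_CM2_YR_TO_UMOL_M2_D,
)
from .conftest import random_state


def make_params(registry, d0=300.0, w=0.0, alpha0=0.0, bw=None):
    bw = bw or {}
    return TransportParams(
        d0={name: d0 for name in registry.solutes},
        w=w, alpha0=alpha0, z_irr=3.0, irr_cutoff=10.0,
        bottom_water={name: bw.get(name, 0.0) for name in registry.solutes},
    )


class TestEffectiveDiffusivity:
    def test_no_tortuosity_limit(self):
        assert effective_diffusivity(300.0, 0.999999) == pytest.approx(300.0, rel=1e-5)

    def test_zero_d0(self):
        assert effective_diffusivity(0.0, 0.9) == 0.0

    def test_boudreau_value(self):
        # 300 / (1 - 2 ln 0.9)
        assert effective_diffusivity(300.0, 0.9) == pytest.approx(300.0 / (1 - 2 * np.log(0.9)), rel=1e-12)
        assert effective_diffusivity(300.0, 0.9) == pytest.approx(247.79, abs=0.01)

    def test_bounded_by_d0(self, rng):
        phi = rng.uniform(0.05, 0.99, 50)
        assert np.all(effective_diffusivity(250.0, phi) <= 250.0)

    @pytest.mark.parametrize("phi", [0.0, 1.0, -0.2, 1.3])
    def test_invalid_porosity(self, phi):
        with pytest.raises(ValueError):
            effective_diffusivity(100.0, phi)


class TestTendencies:
    def test_uniform_bottom_water_profile_is_steady(self, flat_grid, registry):
        params = make_params(registry, w=0.0, bw={n: 1e-6 for n in registry.solutes})
        st = State.zeros(flat_grid, registry)
        st.solutes[:] = 1e-6
        out = diffusion_advection_tendency(st, params, flat_grid, registry)
        assert np.allclose(out["solutes"], 0.0, atol=1e-18)

    def test_linearity(self, grid, registry, rng):
        params = make_params(registry, w=2.75, alpha0=30.0,
                             bw={n: 0.0 for n in registry.solutes})
        s1 = random_state(grid, registry, rng)
        s2 = random_state(grid, registry, rng)
        a, b = 0.7, -1.3
        combo = State.zeros(grid, registry)
        combo.solutes = a * s1.solutes + b * s2.solutes
        t1 = diffusion_advection_tendency(s1, params, grid, registry)["solutes"]
        t2 = diffusion_advection_tendency(s2, params, grid, registry)["solutes"]
        tc = diffusion_advection_tendency(combo, params, grid, registry)["solutes"]
        assert np.allclose(tc, a * t1 + b * t2, rtol=1e-10, atol=1e-22)

    def test_global_conservation_equals_boundary_flux(self, grid, registry, rng):
        """Sum of tendency x cell volume must equal the net boundary flux."""
        params = make_params(registry, d0=250.0, w=2.75, alpha0=25.0,
                             bw={n: 1e-6 for n in registry.solutes})
        st = random_state(grid, registry, rng)
        out = diffusion_advection_tendency(st, params, grid, registry)
        irr = irrigation_tendency(st, params, grid, registry)
        phi_e = grid.porosity_at_edges()
        a_pw = params.w * grid.porosity[-1]
        for k, name in enumerate(registry.solutes):
            ds0 = effective_diffusivity(params.d0[name], phi_e[0])
            c_bw = params.bottom_water[name]
            top_in = (phi_e[0] * ds0 * (c_bw - st.solutes[k, 0]) / grid.cell_centers[0]
                      + a_pw * c_bw)
            bottom_out = a_pw * st.solutes[k, -1]
            irr_in = float(np.sum(irr[k] * grid.dz))
            total = float(((out["solutes"][k] + irr[k]) * grid.dz).sum())
            assert total == pytest.approx(top_in - bottom_out + irr_in,
                                          rel=1e-10, abs=1e-18)

    def test_solid_burial_conserves_mass(self, grid, registry, rng):
        params = make_params(registry, w=2.75)
        st = random_state(grid, registry, rng)
        out = diffusion_advection_tendency(st, params, grid, registry)
        phi_e = grid.porosity_at_edges()
        for k in range(len(registry.solids)):
            bottom_out = (params.w * (1 - phi_e[-1]) * grid.solid_density
                          * st.solids[k, -1])
            total = float((out["solids"][k] * grid.dz).sum())
            assert total == pytest.approx(-bottom_out, rel=1e-10, abs=1e-20)


class TestIrrigation:
    def test_zero_when_equal_to_bottom_water(self, grid, registry):
        params = make_params(registry, alpha0=30.0,
                             bw={n: 1e-6 for n in registry.solutes})
        st = State.zeros(grid, registry)
        st.solutes[:] = 1e-6
        assert np.allclose(irrigation_tendency(st, params, grid, registry), 0.0)

    def test_zero_intensity(self, grid, registry, rng):
        params = make_params(registry, alpha0=0.0)
        st = random_state(grid, registry, rng)
        assert np.allclose(irrigation_tendency(st, params, grid, registry), 0.0)

    def test_hard_cutoff_at_10_cm(self, grid, registry):
        params = make_params(registry, alpha0=30.0,
                             bw={n: 1e-6 for n in registry.solutes})
        st = State.zeros(grid, registry)
        irr = irrigation_tendency(st, params, grid, registry)
        above = grid.cell_centers <= 10.0
        assert np.all(irr[0, above] > 0)
        assert np.allclose(irr[0, ~above], 0.0)


class TestBenthicFlux:
    def test_zero_at_equilibrium(self, grid, registry):
        params = make_params(registry, bw={n: 2e-7 for n in registry.solutes})
        st = State.zeros(grid, registry)
        st.solutes[:] = 2e-7
        assert benthic_flux(st, params, grid, registry, "CH4") == pytest.approx(0.0)

    def test_linear_profile_flux_arithmetic(self, registry):
        # two-cell column with a known linear gradient, no irrigation
        g = build_grid(2.0, 2, porosity_surface=0.9, porosity_deep=0.9)
        params = make_params(registry, d0=300.0)
        st = State.zeros(g, registry)
        slope = 1e-6  # mol cm^-3 per cm, C(z) = slope * z, C_bw = 0
        st.solutes[registry.solute_index("CH4")] = slope * g.cell_centers
        ds = effective_diffusivity(300.0, 0.9)
        expected = 0.9 * ds * slope * MOL_CM2_YR_TO_UMOL_M2_D
        got = benthic_flux(st, params, g, registry, "CH4")
        assert got == pytest.approx(expected, rel=1e-12)

    def test_irrigation_only_influx_is_negative(self, grid, registry):
        params = make_params(registry, d0=0.0, alpha0=30.0,
                             bw={"O2": 2.5e-7})
        st = State.zeros(grid, registry)  # O2 = 0 < bottom water everywhere
        assert benthic_flux(st, params, grid, registry, "O2") < 0

    def test_unknown_solute(self, grid, registry):
        params = make_params(registry)
        with pytest.raises(ValueError):
            benthic_flux(State.zeros(grid, registry), params, grid, registry, "Xe")


class TestClosedFormOracle:
    @pytest.mark.parametrize("d0,k", [(300.0, 30.0), (120.0, 10.0), (380.0, 80.0)])
    def test_steady_diffusion_with_decay(self, registry, d0, k):
        """Steady state of diffusion + first-order decay matches
        C_bw exp(-z sqrt(k / D_s)) within 1% on a 400-cell constant-phi grid."""
        phi = 0.9
        g = build_grid(40.0, 400, porosity_surface=phi, porosity_deep=phi)
        c_bw = 1e-6
        params = make_params(registry, d0=d0, bw={"O2": c_bw})
        op = build_solute_operator(d0, c_bw, params, g)
        # solve (A - k phi I) c = -b  (decay acts on porewater concentration)
        n = g.n_cells
        ab = np.zeros((3, n))
        ab[0, 1:] = op.upper[1:]
        ab[1] = op.diag - k * phi
        ab[2, :-1] = op.lower[:-1]
        c = solve_banded((1, 1), ab, -op.b)
        ds = effective_diffusivity(d0, phi)
        expected = c_bw * np.exp(-g.cell_centers * np.sqrt(k / ds))
        sel = expected > 1e-3 * c_bw  # compare over 3 decades of decay
        assert np.allclose(c[sel], expected[sel], rtol=0.01)
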
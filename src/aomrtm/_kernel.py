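"""Compiled per-cell reaction integrator.

The local reaction network is independent between cells, so each cell is
integrated over the outer step with its own adaptive sub-step sequence:
stiff cells (the oxic boundary layer, the sulfide front) take many small
sub-steps while quiescent cells take few. The kinetics evaluated here are
exactly those of :mod:`geochemistry` and :mod:`microbes`; the pure-numpy
engine path serves as the reference implementation and the test suite
asserts agreement.

All stoichiometric and kinetic tables arrive as flat arrays packed by
:class:`aomrtm.simulator.ReactionEngine`.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _rates_cell(C, gamma, inv_phi,
                lad_idx, lad, om_c_rows, om_k, om_rrows,
                sec_rows, sec_ia, sec_ib, sec_k,
                g_rows, g_nsub, g_sub_idx, g_sub_km, g_sub_solute,
                g_ninh, g_inh_idx, g_inh_kin,
                g_nquot, g_quot_idx, g_quot_coeff,
                g_hmax, g_dg0, g_dgmin, rt, act_floor, moll,
                death_rows, death_c, R, ltot):
    """Reaction rates for one cell; fills R (n_rows) and ltot (n_guilds)."""
    # --- electron-acceptor ladder; lad_idx = [O2, NO3, SO4, FeOx, MnOx]
    o2 = C[lad_idx[0]] * inv_phi
    no3 = C[lad_idx[1]] * inv_phi
    so4 = C[lad_idx[2]] * inv_phi
    feox = C[lad_idx[3]]
    mnox = C[lad_idx[4]]
    # lad: k_o2,k_no3,k_mnox,k_feox,k_so4, kin_o2,kin_no3,kin_mnox,kin_feox
    i_o2 = lad[5] / (lad[5] + o2)
    i_no3 = lad[6] / (lad[6] + no3)
    i_mn = lad[7] / (lad[7] + mnox)
    i_fe = lad[8] / (lad[8] + feox)
    f0 = o2 / (lad[0] + o2)
    f1 = no3 / (lad[1] + no3) * i_o2
    f2 = mnox / (lad[2] + mnox) * i_o2 * i_no3
    f3 = feox / (lad[3] + feox) * i_o2 * i_no3 * i_mn
    f4 = so4 / (lad[4] + so4) * i_o2 * i_no3 * i_mn * i_fe
    expl = f0 + f1 + f2 + f3 + f4
    if expl > 1.0:
        f0 /= expl
        f1 /= expl
        f2 /= expl
        f3 /= expl
        f4 /= expl
        expl = 1.0
    f5 = (1.0 - expl) * lad[9]
    for pp in range(om_c_rows.shape[0]):
        tot = om_k[pp] * C[om_c_rows[pp]]
        R[om_rrows[pp, 0]] = f0 * tot
        R[om_rrows[pp, 1]] = f1 * tot
        R[om_rrows[pp, 2]] = f2 * tot
        R[om_rrows[pp, 3]] = f3 * tot
        R[om_rrows[pp, 4]] = f4 * tot
        R[om_rrows[pp, 5]] = f5 * tot
    # --- secondary redox
    for ss in range(sec_rows.shape[0]):
        R[sec_rows[ss]] = sec_k[ss] * C[sec_ia[ss]] * C[sec_ib[ss]]
    # --- guilds
    for gg in range(g_rows.shape[0]):
        lim = 1.0
        for si in range(g_nsub[gg]):
            c = C[g_sub_idx[gg, si]]
            if g_sub_solute[gg, si] == 1:
                c = c * inv_phi
            lim *= c / (g_sub_km[gg, si] + c)
        for ii in range(g_ninh[gg]):
            c = C[g_inh_idx[gg, ii]] * inv_phi
            lim *= g_inh_kin[gg, ii] / (g_inh_kin[gg, ii] + c)
        lnq = 0.0
        for qq in range(g_nquot[gg]):
            act = C[g_quot_idx[gg, qq]] * inv_phi
            if act < act_floor:
                act = act_floor
            lnq += g_quot_coeff[gg, qq] * np.log(act * moll)
        x = (g_dg0[gg] + rt * lnq + g_dgmin[gg]) / rt
        if x > 50.0:
            x = 50.0
        f_t = 1.0 - np.exp(x)
        if f_t < 0.0:
            f_t = 0.0
        lim *= f_t
        ltot[gg] = lim
        R[g_rows[gg]] = gamma[gg] * g_hmax[gg] * lim
    for gg in range(death_rows.shape[0]):
        R[death_rows[gg]] = death_c[gg] * gamma[gg]
    return


@njit(cache=True)
def integrate_column(C, gamma, dz, inv_phi_arr, dt, safety, dt_min, floor,
                     lad_idx, lad, om_c_rows, om_k, om_rrows,
                     sec_rows, sec_ia, sec_ib, sec_k,
                     g_rows, g_nsub, g_sub_idx, g_sub_km, g_sub_solute,
                     g_ninh, g_inh_idx, g_inh_kin,
                     g_nquot, g_quot_idx, g_quot_coeff,
                     g_hmax, g_dg0, g_dgmin, rt, act_floor, moll,
                     death_rows, death_c, mu_over_h, q_death,
                     s_idx, s_coeff, s_n, cons_idx, cons_n, leak,
                     acc_aom, acc_ltot, acc_om_rows, acc_om,
                     acc_leak, counters, counters_f):
    """Integrate the reaction network over dt for every cell.

    C (n_tracked, n_cells) bulk concentrations and gamma (n_guilds, n_cells)
    are updated in place. Accumulators (time-integrated rates, limiter
    products, element leaks) are incremented; ``counters`` collects
    [total_substeps, clip_event_substeps].
    """
    n_tracked, n_cells = C.shape
    n_rows = s_idx.shape[0]
    n_guilds = g_rows.shape[0]
    R = np.empty(n_rows)
    ltot = np.empty(n_guilds)
    D = np.empty(n_tracked)
    lam = np.empty(n_tracked)
    Cl = np.empty(n_tracked)
    gl = np.empty(n_guilds)
    for cell in range(n_cells):
        for i in range(n_tracked):
            Cl[i] = C[i, cell]
        for g in range(n_guilds):
            gl[g] = gamma[g, cell]
        inv_phi = inv_phi_arr[cell]
        t = 0.0
        while t < dt * (1.0 - 1e-12):
            _rates_cell(Cl, gl, inv_phi,
                        lad_idx, lad, om_c_rows, om_k, om_rrows,
                        sec_rows, sec_ia, sec_ib, sec_k,
                        g_rows, g_nsub, g_sub_idx, g_sub_km, g_sub_solute,
                        g_ninh, g_inh_idx, g_inh_kin,
                        g_nquot, g_quot_idx, g_quot_coeff,
                        g_hmax, g_dg0, g_dgmin, rt, act_floor, moll,
                        death_rows, death_c, R, ltot)
            for i in range(n_tracked):
                D[i] = 0.0
            for j in range(n_rows):
                rj = R[j]
                if rj != 0.0:
                    for k in range(s_n[j]):
                        c = s_coeff[j, k]
                        if c < 0.0:
                            D[s_idx[j, k]] -= c * rj
            # adaptive sub-step: destruction of any species above the floor
            # limited to a fraction `safety` of its stock
            rmax = 0.0
            for i in range(n_tracked):
                if Cl[i] > floor and D[i] > 0.0:
                    r = D[i] / Cl[i]
                    if r > rmax:
                        rmax = r
            remaining = dt - t
            if rmax <= 0.0:
                dt_sub = remaining
            else:
                dt_sub = safety / rmax
                if dt_sub < dt_min:
                    dt_sub = dt_min
                if dt_sub > remaining:
                    dt_sub = remaining
            # availability scaling (stoichiometry-preserving positivity)
            clipped = False
            clip_event = False
            for i in range(n_tracked):
                den = dt_sub * D[i]
                if den > 0.0:
                    li = Cl[i] / den
                    if li < 1.0:
                        clipped = True
                        if Cl[i] > 100.0 * floor:
                            clip_event = True
                    else:
                        li = 1.0
                    lam[i] = li
                else:
                    lam[i] = 1.0
            if clipped:
                for j in range(n_rows):
                    sc = 1.0
                    i_lim = -1
                    for k in range(cons_n[j]):
                        ii = cons_idx[j, k]
                        if lam[ii] < sc:
                            sc = lam[ii]
                            i_lim = ii
                    counters_f[1] += dt_sub * R[j]
                    if sc < 1.0:
                        # suppressed turnover only counts against the run
                        # when the limiting species is outside the
                        # quasi-steady floor regime
                        if i_lim >= 0 and Cl[i_lim] > 100.0 * floor:
                            counters_f[0] += dt_sub * R[j] * (1.0 - sc)
                        R[j] *= sc
            else:
                for j in range(n_rows):
                    counters_f[1] += dt_sub * R[j]
            # state update
            for j in range(n_rows):
                rj = R[j] * dt_sub
                if rj != 0.0:
                    for k in range(s_n[j]):
                        Cl[s_idx[j, k]] += s_coeff[j, k] * rj
            for i in range(n_tracked):
                if Cl[i] < 0.0:
                    Cl[i] = 0.0
            for g in range(n_guilds):
                growth = mu_over_h[g] * R[g_rows[g]]
                gl[g] += dt_sub * (growth - q_death[g] * gl[g])
                if gl[g] < 0.0:
                    gl[g] = 0.0
            # accumulators
            for g in range(n_guilds):
                acc_aom[g, cell] += dt_sub * R[g_rows[g]]
                acc_ltot[g, cell] += dt_sub * ltot[g]
            for jj in range(acc_om_rows.shape[0]):
                acc_om[jj % 6] += dt_sub * R[acc_om_rows[jj]] * dz[cell]
            for e in range(leak.shape[0]):
                s = 0.0
                for j in range(n_rows):
                    if leak[e, j] != 0.0:
                        s += leak[e, j] * R[j]
                acc_leak[e] += dt_sub * s * dz[cell]
            counters[0] += 1
            if clip_event:
                counters[1] += 1
            t += dt_sub
        for i in range(n_tracked):
            C[i, cell] = Cl[i]
        for g in range(n_guilds):
            gamma[g, cell] = gl[g]
    return
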
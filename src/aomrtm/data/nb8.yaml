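# NB8 reference calibration for aomrtm.
# Kinetic/microbial parameters are calibrated to reproduce published
# headline model outputs; they are calibration outputs, not
# measurements. All quantities carry explicit unit strings that are
# validated at load time.
grid:
  depth_max:
    value: 80.0
    units: cm
  n_cells: 100
  porosity_surface: 0.95
  porosity_deep: 0.85
  attenuation:
    value: 10.0
    units: cm
  solid_density:
    value: 2.65
    units: g cm-3
transport:
  w:
    value: 2.75
    units: cm yr-1
  alpha0:
    value: 200.0
    units: yr-1
  z_irr:
    value: 3.2
    units: cm
  irr_cutoff:
    value: 10.0
    units: cm
  d0:
    O2:
      value: 380.0
      units: cm2 yr-1
    NO3:
      value: 340.0
      units: cm2 yr-1
    NH4:
      value: 330.0
      units: cm2 yr-1
    SO4:
      value: 190.0
      units: cm2 yr-1
    H2S:
      value: 300.0
      units: cm2 yr-1
    Fe2:
      value: 120.0
      units: cm2 yr-1
    Mn2:
      value: 110.0
      units: cm2 yr-1
    CH4:
      value: 290.0
      units: cm2 yr-1
    DIC:
      value: 190.0
      units: cm2 yr-1
bottom_water:
  O2:
    value: 2.5e-07
    units: mol cm-3
  NO3:
    value: 1.0e-08
    units: mol cm-3
  NH4:
    value: 0.0
    units: mol cm-3
  SO4:
    value: 4.8e-06
    units: mol cm-3
  H2S:
    value: 0.0
    units: mol cm-3
  Fe2:
    value: 0.0
    units: mol cm-3
  Mn2:
    value: 0.0
    units: mol cm-3
  CH4:
    value: 0.0
    units: mol cm-3
  DIC:
    value: 2.0e-06
    units: mol cm-3
kinetics:
  pools:
  - label: fast
    k:
      value: 1.0
      units: yr-1
    cn_ratio: 8.0
  - label: slow
    k:
      value: 0.055
      units: yr-1
    cn_ratio: 10.0
  - label: refractory
    k:
      value: 0.0
      units: yr-1
    cn_ratio: 12.0
  ladder:
    k_o2:
      value: 8.0e-09
      units: mol cm-3
    k_no3:
      value: 5.0e-09
      units: mol cm-3
    k_mnox:
      value: 0.0001
      units: mol cm-3
    k_feox:
      value: 0.00012
      units: mol cm-3
    k_so4:
      value: 1.0e-08
      units: mol cm-3
    kin_o2:
      value: 8.0e-09
      units: mol cm-3
    kin_no3:
      value: 5.0e-09
      units: mol cm-3
    kin_mnox:
      value: 0.0001
      units: mol cm-3
    kin_feox:
      value: 0.00012
      units: mol cm-3
    kin_so4:
      value: 2.0e-08
      units: mol cm-3
    meth_factor: 0.4
  secondary:
    nitrification:
      value: 2000000000.0
      units: cm3 mol-1 yr-1
    Fe2_oxidation_O2:
      value: 5000000000.0
      units: cm3 mol-1 yr-1
    Fe2_oxidation_MnOx:
      value: 500000.0
      units: cm3 mol-1 yr-1
    Mn2_oxidation_O2:
      value: 1000000000.0
      units: cm3 mol-1 yr-1
    H2S_oxidation_O2:
      value: 3000000000.0
      units: cm3 mol-1 yr-1
    H2S_oxidation_FeOx:
      value: 900000.0
      units: cm3 mol-1 yr-1
    H2S_oxidation_MnOx:
      value: 500000.0
      units: cm3 mol-1 yr-1
    FeS_precipitation:
      value: 500000000.0
      units: cm3 mol-1 yr-1
    pyrite_formation:
      value: 50000000.0
      units: cm3 mol-1 yr-1
thermodynamics:
  temperature:
    value: 277.15
    units: K
microbes:
  carbon_fraction: 0.5
  seed_floor:
    value: 100.0
    units: cells cm-3
  biomass_burial: false
  guilds:
  - name: aerobic_MOx
    h_max:
      value: 7.305000000000001e-12
      units: mol yr-1 cell-1
    z_yield:
      value: 2.1660849392498287
      units: g mol-1
    cell_mass:
      value: 5.0e-14
      units: g
    q:
      value: 0.12
      units: yr-1
    km:
      CH4:
        value: 2.0e-09
        units: mol cm-3
      O2:
        value: 1.5e-09
        units: mol cm-3
    inhibitors: {}
    dg0:
      value: -820.0
      units: kJ mol-1
    dg_min:
      value: 15.0
      units: kJ mol-1
  - name: SO4_ANME
    h_max:
      value: 1.3149000000000002e-12
      units: mol yr-1 cell-1
    z_yield:
      value: 0.015527490603941424
      units: g mol-1
    cell_mass:
      value: 1.0e-14
      units: g
    q:
      value: 0.24
      units: yr-1
    km:
      CH4:
        value: 3.0e-08
        units: mol cm-3
      SO4:
        value: 1.0e-07
        units: mol cm-3
    inhibitors:
      O2:
        value: 1.0e-09
        units: mol cm-3
    dg0:
      value: -30.0
      units: kJ mol-1
    dg_min:
      value: 12.0
      units: kJ mol-1
  - name: FeOx_ANME
    h_max:
      value: 7.305000000000001e-14
      units: mol yr-1 cell-1
    z_yield:
      value: 0.17072590654185843
      units: g mol-1
    cell_mass:
      value: 1.0e-14
      units: g
    q:
      value: 0.5
      units: yr-1
    km:
      CH4:
        value: 5.0e-08
        units: mol cm-3
      FeOx:
        value: 1.0e-07
        units: mol cm-3
    inhibitors:
      O2:
        value: 1.0e-09
        units: mol cm-3
      SO4:
        value: 5.0e-07
        units: mol cm-3
    dg0:
      value: -270.0
      units: kJ mol-1
    dg_min:
      value: 12.0
      units: kJ mol-1
  - name: MnOx_ANME
    h_max:
      value: 2.5567500000000004e-14
      units: mol yr-1 cell-1
    z_yield:
      value: 0.6074909557931158
      units: g mol-1
    cell_mass:
      value: 1.0e-14
      units: g
    q:
      value: 0.5
      units: yr-1
    km:
      CH4:
        value: 5.0e-08
        units: mol cm-3
      MnOx:
        value: 2.4e-07
        units: mol cm-3
    inhibitors:
      O2:
        value: 1.0e-09
        units: mol cm-3
      SO4:
        value: 5.0e-07
        units: mol cm-3
    dg0:
      value: -520.0
      units: kJ mol-1
    dg_min:
      value: 12.0
      units: kJ mol-1
scenario:
  start_year:
    value: 1969.0
    units: yr
  end_year:
    value: 2019.0
    units: yr
  baseline:
    OM_fast:
      value: 0.0001
      units: mol cm-2 yr-1
    OM_slow:
      value: 0.0005
      units: mol cm-2 yr-1
    OM_refractory:
      value: 0.0012
      units: mol cm-2 yr-1
    FeOx:
      value: 0.0002
      units: mol cm-2 yr-1
    MnOx:
      value: 3.4e-05
      units: mol cm-2 yr-1
  pulse_period:
    value: 20.0
    units: yr
  pulse_duration:
    value: 2.0
    units: yr
  pulse_offset:
    value: 4.0
    units: yr
  amplitudes:
    OM_fast: 2.8
    OM_slow: 2.8
    FeOx: 3.0
    MnOx: 4.0
  spinup_max_cycles: 12
  spinup_tol: 0.01
numerics:
  dt:
    value: 0.02
    units: yr
  substep_safety: 0.3
  max_substeps: 400
  solute_floor: 1.0e-10
  save_every:
    value: 1.0
    units: yr
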
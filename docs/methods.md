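# Methods

`aomrtm` is a one-dimensional early-diagenesis reactive-transport model of a
coastal sediment column in which the microorganisms that oxidize methane are
explicit state variables. This note documents the model equations, the
numerical scheme, the reference calibration and its intent, and the known
limitations.

## Model structure

### State

The column (default 0–80 cm, 100 uniform finite volumes) carries

* 9 dissolved species (O₂, NO₃⁻, NH₄⁺, SO₄²⁻, ΣH₂S, Fe²⁺, Mn²⁺, CH₄, DIC)
  in mol per cm³ of porewater,
* 8 particulate species (three organic-matter pools of a multi-G model,
  Fe oxides, Mn oxides, FeS, FeS₂, S⁰) in mol per g of dry sediment, and
* 4 microbial guilds (aerobic methanotrophs; sulfate-, iron-oxide- and
  manganese-oxide-driven anaerobic methanotrophs, "ANME") in cells per cm³
  of bulk sediment.

Porosity follows φ(z) = φ_∞ + (φ₀ − φ_∞)·e^(−z/λ) (defaults 0.95 → 0.85,
λ = 10 cm); dry-solid density is 2.65 g cm⁻³. All reaction rates are
assembled on the common bulk-volume basis (mol cm⁻³ bulk yr⁻¹).

### Transport

Solutes: molecular diffusion with the Boudreau tortuosity correction
D_s = D₀/(1 − 2 ln φ); porewater burial at w·φ_∞/φ (steady compaction);
nonlocal bioirrigation exchange φ·α(z)·(C_bw − C) with
α(z) = α₀·e^(−z/z_irr) above a hard 10 cm cutoff. The upper boundary is a
Dirichlet bottom-water concentration, the lower boundary has zero diffusive
gradient and advective outflow. Solids and (optionally) biomass are buried
by upwind advection at the ²¹⁰Pb-derived sedimentation velocity
w = 2.75 cm yr⁻¹; solids enter through a prescribed, time-dependent
deposition flux.

### Geochemical network

Organic-matter mineralization is first-order per pool (fast/slow/refractory)
and partitioned over the classical acceptor ladder — aerobic respiration,
denitrification, Mn- and Fe-oxide reduction, sulfate reduction — by Monod
limitation with inhibition by the acceptors above; methanogenesis
(2 CH₂O → CH₄ + CO₂) takes the residual, so pathway fractions sum to one by
construction. Nine bimolecular secondary redox reactions recycle the redox
shuttles (nitrification, Fe²⁺/Mn²⁺/H₂S oxidation by O₂ and by each other's
oxides, FeS precipitation, pyrite formation). Every stoichiometry is
element- and charge-balanced; the balance is verified numerically each time
a network is constructed, including from user-edited configuration files.
H₂O, H⁺, N₂ and H₂ are bookkept in the stoichiometries but are not
prognostic; pH is fixed implicitly by using primed (pH-absorbed) standard
Gibbs energies.

### Gene-based guilds

Each guild catalyzes one methane-oxidation reaction
(CH₄ + 2O₂ → CO₂ + 2H₂O; CH₄ + SO₄²⁻ → HCO₃⁻ + HS⁻ + H₂O;
CH₄ + 8 Fe(OH)₃ + 15 H⁺ → HCO₃⁻ + 8 Fe²⁺ + 21 H₂O;
CH₄ + 4 MnO₂ + 7 H⁺ → HCO₃⁻ + 4 Mn²⁺ + 5 H₂O) at the bulk rate

    R = Γ · H_max · M · I · F_T                      (mol CH₄ cm⁻³ yr⁻¹)

where Γ is abundance (cells cm⁻³), H_max the maximum cell-specific rate
(mol yr⁻¹ cell⁻¹), M the product of Michaelis–Menten factors C/(K_m + C)
over the substrates (CH₄ and the electron acceptor; solids enter on the
bulk-concentration basis), I the product of optional inhibition factors
K_in/(K_in + C), and F_T the thermodynamic potential factor

    F_T = max(0, 1 − exp((ΔG + ΔG_min) / RT)),  ΔG = ΔG°′ + RT ln Q.

Solute concentrations act as activities in Q (converted to mol L⁻¹ and
floored at 10⁻¹² mol cm⁻³ to keep ln Q finite); solids and water have unit
activity. F_T shuts the metabolism off once the in-situ energy yield falls
below the minimum quantum ΔG_min a cell must conserve.

Biomass evolves as

    dΓ/dt = Γ · (Z/c) · H_max · M · I · F_T − q · Γ

with Z the biomass yield (g dry mass per mol CH₄), c the dry mass per cell
(g) and q a constant first-order death rate (yr⁻¹). The same limiter product
governs catalysis and growth, so gross growth is (Z/c)·R exactly. Doubling
times are ln 2 divided by the gross per-capita growth rate: "fastest
possible" with all limiters at unity, "in-situ" with the local limiters.

Carbon and nitrogen closure: anabolism draws Z·f_C/12 mol of biomass carbon
per mol CH₄ from the DIC pool and the matching ammonium (using the fast
pool's C:N); dead biomass carbon returns to the fast organic-matter pool.
A configurable seed floor (100 cells cm⁻³) lets guilds (re)colonize zones
they had vanished from, since the growth law alone cannot create biomass.

## Numerics

The outer step (0.02 yr) is operator-split. Transport of solutes is a
backward-Euler finite-volume solve (one tridiagonal system per solute,
including irrigation), unconditionally stable and conservative by
construction; solids and biomass use explicit upwind burial (CFL ≈ 0.07).
The local reaction network is independent between cells, so each cell is
integrated over the outer step with its own adaptive explicit sub-step
sequence (a compiled per-cell kernel; a pure-numpy reference implementation
of the same kinetics is kept and the test suite asserts the two agree).
The sub-step is chosen so no species above a small availability floor loses
more than ~30% of its inventory per sub-step, with a hard cap of 400
sub-steps per outer step. Positivity is enforced stoichiometrically — when
a sub-step would exhaust a species, every reaction consuming it is scaled by
the same availability factor, which preserves stoichiometric ratios and
hence element conservation exactly; near-exhausted species (O₂ at the oxic
interface, H₂S against the iron buffer) thereby relax into the quasi-steady
regime instead of oscillating. The fraction of total dt-integrated reaction
turnover suppressed by availability scaling outside that quasi-steady floor
regime is logged per run (typically ~1%, dominated by O₂-supply competition
in the bioirrigated zone, which is the intended flux-limited closure); runs
above 5% are flagged in the run manifest.

Resolution dependence deserves an explicit statement. Integrated rates,
pathway shares and the reaction-front quantities converge under grid and
time-step refinement (halving either changes them by well under 1–2%). The
*benthic methane flux in its quiet phases*, however, is the small residual
of a strong source below and a strong microbial filter above, and under
operator splitting a fraction of the upward methane can cross the reactive
zone during the transport half-step before the reaction phase acts; this
leakage scales roughly linearly with the outer step. The shipped
calibration, including the pulse-driven benthic-release amplitudes, is
therefore defined at the reference resolution (0.8 cm, 0.02 yr), which is
stated here as a property of the model configuration rather than hidden.

A continuous audit integrates per-element (C, N, S, Fe, Mn) boundary fluxes
(bottom-water exchange, deposition, burial, N₂ loss via denitrification,
seeding) and compares them with column inventories; full transient runs
close to ~10⁻¹³ relative, and the run is declared invalid above 10⁻⁶.
The model contains no random numbers: identical configurations give
bit-identical trajectories.

Spin-up repeats the 20-year forcing cycle (capped at 12 cycles) until the
cycle-to-cycle drift of the slowest inventories — porewater methane and each
guild's biomass — falls below 1% per cycle, then the dated 1969–2019
transient is integrated with annual-mean outputs. "Final-year" diagnostics
are annual means over the last simulated year; in-situ doubling times
quoted "at the final timestep" use the last saved state.

## The NB8 reference calibration

The shipped configuration represents a brackish, iron-rich, bioirrigated
coastal site: bottom-water salinity ≈ 6 (sulfate 4.8 mmol L⁻¹ by
conservative dilution of a 28 mmol L⁻¹ seawater endmember), oxygenated
bottom water (250 µmol L⁻¹ O₂), sedimentation 2.75 cm yr⁻¹, bioirrigation
to 10 cm, and organic-matter/metal-oxide deposition pulses every 20 years
(2-year rectangular pulses; the transient ends in 2019, two years after the
last pulse). Temperature is fixed at 4 °C; diffusion coefficients are
standard cold-brackish-water values stored in the configuration.

The kinetic, thermodynamic and microbial parameters are a *reference
calibration*: they were tuned so that the simulated system reproduces the
published headline outputs of the site model this package re-implements
(pathway shares of methane oxidation, peak pulse-driven benthic CH₄ efflux,
SMTZ depth, guild abundance maxima, bulk and cell-specific sulfate-AOM
rates, and fastest/in-situ doubling times). They are calibration outputs,
not site measurements, and the configuration file says so in its header.
Three calibration constraints deserve explanation:

* **Guild growth parameters.** (Z/c)·H_max is fixed exactly by the
  fastest-possible doubling times (124/203/163 days for the SO₄-, FeOx- and
  MnOx-ANME; <1 day for aerobic methanotrophs). With c set to 10 fg dry
  mass per cell, the H_max values needed to reproduce the observed bulk and
  cell-specific rates imply yields Z of ~0.03 g mol⁻¹ for SO₄-ANME but
  several g mol⁻¹ for the metal-oxide guilds. The latter are biologically
  high; they are what the combination of printed anchors (slow doubling,
  low cell-specific rate, high abundance) forces, and they are carried
  honestly as calibration outputs with carbon closure kept sub-unity.
* **Biomass is not transported in the reference run.** With burial at
  2.75 cm yr⁻¹, a guild whose fastest doubling is 124 days cannot amplify
  from a seed population to ~10⁸ cells cm⁻³ across a ~14 cm zone against
  burial — the required net growth exceeds its gross maximum. The module
  supports burial of attached cells (config switch `biomass_burial`), but
  the reference calibration disables it; the published abundances are only
  reachable with in-place populations.
* **The system is deliberately transient.** Death rates (q ≈ 0.24–0.5 yr⁻¹
  for the ANME guilds) are low enough that populations persist between
  pulses but high enough that the guilds never settle into a static
  chemostat balance; the final model year samples the post-pulse phase of
  the limit cycle, which is what produces in-situ doubling times within a
  factor ~2 of the fastest-possible values at that time point.

## Environmental sweeps

One-at-a-time sweeps perturb the configuration: salinity rescales
bottom-water sulfate by conservative dilution (other boundary
concentrations unchanged — salinity is used as a sulfate control);
bottom-water O₂ is set directly (µmol L⁻¹); organic-matter and metal-oxide
input factors multiply the respective deposition fluxes; growth/death
multipliers scale (Z/c)·H_max (via Z) and q per guild, with the canonical
multiplier set {0.5, 0.75, 0.9, 1.1, 1.25, 1.5}. Every member is an
independent full run (own spin-up); summaries average the benthic CH₄ flux
and depth-integrated oxidation rates over the last 50 simulated years and
report final-year guild relative abundances.

## Synthetic fixtures

`fixtures.toy_column` is a 20-cell, 20-cm, 4-year miniature used by the
test suite; it keeps the full 9/8/4 species registry (a fixed model-size
invariant) and completes in seconds. `fixtures.synthetic_profiles`
generates smooth, noisy depth profiles with the qualitative structure of
the measured porewater data (O₂ gone by ~0.7 cm, sulfate crossing
0.1 mmol L⁻¹ near 20 cm, methane rising below, dissolved Fe/Mn maxima at
depth) for calibration-comparison plumbing; the files are labelled
synthetic and carry no data claims. What the tests demonstrate is therefore
internal consistency and reproduction of published model outputs under the
reference calibration — not skill against field measurements.

## Known limitations

* The salinity sweep reproduces the qualitative behaviour (methane release
  grows as sulfate is removed, falls with bottom-water oxygen, grows with
  organic loading), but the *magnitude* of the release in the sulfate-free
  end member is controlled by the balance between deep methanogenesis and
  the oxidative capacity of the bioirrigated zone, and in this calibration
  the former wins by a wide margin: with no sulfate, deep methane
  production far exceeds what oxygen and metal-oxide supply can oxidize.
  The low-oxygen response is likewise monotone but muted rather than
  sharply thresholded.

* No ebullition, no water-column processes, no pH/carbonate-system
  dynamics, no vivianite, no nitrite-driven methane oxidation, and no
  explicit ANME–SRB consortium partitioning.
* The O₂ penetration depth (<1 cm at the site) is at the resolution limit
  of the default 0.8 cm grid; oxygen consumption integrals are
  flux-controlled and robust, but the O₂ profile shape within the top cell
  is not resolved.
* Whether the in-situ doubling-time diagnostic should use gross or net
  (growth − death) rates is a convention; gross is used throughout.
* Sub-annual (seasonal) forcing is out of scope; the irrigation and
  boundary conditions are annual means.
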
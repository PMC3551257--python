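# Methods

`hepatosim` couples three scales: a kinetic hepatocyte model of
acetaminophen (APAP) metabolism and oxidative stress, a zonated
two-dimensional liver-lobule model in which six sinusoids transport blood
past those hepatocytes, and a whole-body flow-limited PBPK model whose
hepatic clearance is *emergent* — it is whatever the lobule's cells manage
to extract and metabolize. This note records the model equations, the
parameter choices and their rationale, the numerical scheme, and what the
package's tests do and do not establish.

## 1. Hepatocyte model

### Species and network

Seventeen species: twelve intracellular pools — APAP (free and
non-specifically bound), NAPQI (free and protein-bound), the glucuronide
(APAPG), sulfate (APAPS, free and bound) and glutathione (APAPGS)
conjugates, GSH, GSSG, H2O2 and a lumped superoxide pool (ROS) — plus five
extracellular bulk slots (APAP, the three conjugates and NAPQI).

Twenty-six reactions: carrier-mediated plus passive APAP uptake; UGT and
SULT conjugation; NAPQI formation by CYP3A4, CYP2E1 and a lumped minor-CYP
pool (2A6 + 1A2 + 2D6); NQO1 back-reduction; GST conjugation of NAPQI with
GSH; non-specific binding of APAP, APAPS and NAPQI; MRP2 (apical, leaves
the modeled system to bile) and MRP3/4 (basolateral, returns to the bulk)
export of the three conjugates; passive NAPQI permeation; zero-order GSH
synthesis (GSS) and saturable degradation (GGT); NAPQI-protein-driven ROS
synthesis; SOD dismutation of ROS to H2O2; GPX reduction of H2O2 at the
cost of 2 GSH; GSR recycling of GSSG; and a basal first-order H2O2
clearance. The cell ODE is `dc/dt = N v(c, p)` with integer stoichiometric
matrix `N`; the APAP-carrying moiety is in the left null space of every
transformation column (tested), so mass can leave a closed cell only
through transport columns.

Rate-law forms: irreversible Michaelis–Menten for all enzymatic steps
(multiplicative saturation for the bi-substrate GST and GPX), a saturable
carrier plus linear passive term for uptake, and first-order mass action
for binding. These are the standard minimal forms; every constant lives in
the configuration and can be refined.

### Parameter values

CYP3A4 (0.95 µmol/L_cell/min) and CYP2E1 (1.0) define the reference
individual; the variant values 1.9 and 5.0 represent inter-individual
differences (e.g. sex differences, alcohol induction). The remaining
kinetic constants are not published for this model, so they are package
defaults at literature-typical magnitudes, *calibrated once* so that three
observable outcomes emerge and then frozen:

1. an in-vitro LC50 of ≈ 4000 µM APAP for a 24-h exposure,
2. an in-vivo single-oral-dose mortality threshold of ≈ 300–330 mg/kg, and
3. zero predicted mortality at 310 mg/kg with deep mortality at ≥ 450 mg/kg.

The structural choices that make these outcomes simultaneously reachable:

- **High-Km oxidation** (Km ≈ 10 mM for all CYP reactions, the low-affinity
  regime reported for APAP oxidation). NAPQI formation then remains
  concentration-sensitive across the whole overdose range, which is what
  turns a ~30 % difference in dose into a qualitatively different outcome.
- **A finite glutathione budget.** Basal GSH 500 µmol/L_cell with synthesis
  0.1 µmol/L_cell/min and GGT degradation balanced at the basal point. At
  sub-toxic exposure the conjugation drain stays below the replenishment
  reserve and the pool finds a new steady level; above it the pool drains
  to exhaustion. The exposure–time product needed for exhaustion is what
  maps the 24-h in-vitro LC50 onto the in-vivo threshold dose.
- **A GSR recycling bottleneck** (Vmax 0.3). Under oxidative load the
  GSSG→GSH recycling saturates, so GPX activity becomes a *net* GSH drain
  and the collapse accelerates instead of stalling asymptotically.
- **Rate-saturated H2O2 escalation.** After the collapse NAPQI and its
  protein adduct accumulate, ROS production exceeds the SOD capacity
  (Vmax 6.5 µmol/L_cell/min), and H2O2 rises at an approximately constant,
  SOD-limited rate with almost no basal clearance (1e-4 /min). The H2O2
  climb is therefore nearly the same in vitro and in vivo, which makes
  death a race of GSH-collapse times rather than of peak heights — without
  this the decaying in-vivo exposure can never reproduce the printed
  in-vivo thresholds under a criterion calibrated at constant in-vitro
  exposure.

### Necrosis

A cell becomes committed to necrosis when intracellular H2O2 exceeds a
critical value **and** GSH is consumed (below 10 % of basal — the
conjunction is stated qualitatively in the source model; the 10 % cut is a
package choice, configurable). Once the criterion holds, death occurs with
per-minute hazard `hazard_scale × w(x)`, where the positional weight
`w(x) = min(1, floor / max(1 − x, 1/16))` is anchored to 1 at the central
vein and decays as the inverse distance to it (pericentral cells have the
poorest oxygen supply and are the most sensitive; `floor` = 0.1 at the
portal inlet). A committed cell executes necrosis after a uniform 0–1 min
delay; at execution all fluxes stop and the intracellular state freezes
(`dc/dt = 0`).

The critical H2O2 value is **calibrated, not assumed**: a nominal
(unperturbed) hepatocyte is exposed to the in-vitro LC50 concentration of
APAP (4000 µM) for 24 h and the threshold is set to the peak H2O2 it
reaches; the ROS gain `k_ros` is first adjusted so that this peak equals
4000 µM, making the threshold numerically coincide with the LC50 exposure.
Because the peak is superlinear in `k_ros` (a larger gain also advances
the collapse), the adjustment is a log-space bisection, converged to 0.5 %.

With lognormal (median-1) inter-cell variability of all Vmax values
(CV 0.2), exactly the above-median half of a population crosses a
threshold equal to the median cell's peak — the in-vitro LC50 of ≈ 4000 µM
is then a structural consequence of the calibration, and the package
recovers it to within a few percent by log-linear interpolation of the
simulated viability curve (binomial noise at n = 200 cells).

## 2. Sinusoid and lobule

A sinusoid is a tube of radius 5 µm lined by 16 sections of 4 hepatocytes
(hepatocyte size 23 µm, length L = 368 µm). Blood moves at the
Fahraeus-corrected suspension velocity 0.05 mm/s (the red-cell velocity,
0.1 mm/s, is recorded but not used for solute transport), with molecular
dispersion from the Stokes–Einstein relation `D = kB T/(6 π η R_g)`
(blood viscosity 3×10⁻³ Pa s, APAP radius of gyration 2.99 Å). The default
temperature is 273 K, which reproduces the commonly quoted
D = 2.22×10⁻¹⁰ m²/s for these inputs; body temperature (310 K) gives
2.53×10⁻¹⁰ and is a one-line configuration change.

Transport proceeds in discrete steps using the exact Green's function of
the advection–dispersion equation (an advecting Gaussian): per substep the
per-section bulk amounts are redistributed by a pre-computed kernel of
erf-differences, with an absorbing outlet at the central-vein end (mass
beyond L leaves; the tiny upstream-dispersed fraction is reflected into
the portal section). The substep is the time for the plume to advance one
hepatocyte (l_h/U_x ≈ 0.46 s). Because a once-per-substep lumped injection
would over-weight the portal section's residence, the inlet parcel is
split between the first two sections with weights chosen so a conservative
tracer's steady discrete profile is flat at the portal concentration.

Within each substep every section's bulk slot and its living hepatocytes
are integrated as one coupled ODE (explicit midpoint rule; all
intracellular rates are a few per minute and the bulk-exchange relaxation
stays well inside the stability region at this substep). The fraction
unbound (fu = 0.75) is applied once, at the lobule inlet. Cumulative net
transfer of parent APAP from bulk into the cells of sinusoid k is the
eliminated amount E_k — the only reading of the sinusoid elimination
quantity that is dimensionally consistent with its use as a clearance in
the liver compartment. Apical MRP2 export leaves the modeled system
(bile); basolateral exports re-enter the bulk, advect, and exit with the
venous outflow.

Zonation: the sinusoid length is split into three equal zones; CYP3A4
activity is equal in zones 1–2 and ×1.3 in the pericentral zone 3 (the
boost applies to CYP3A4 only, as only it is named; zone boundaries are
configurable). The lobule is a pure aggregator of six statistically
identical sinusoids — they share the inlet and diverge only through the
stochastic necrosis draws; the clearance term is the mean of the six
per-sinusoid elimination rates.

## 3. Whole-body model

Five compartments for a 73-kg adult (volumes scaled from body weight,
flows from cardiac output): adipose (F 0.56 L/min, V 28 L, PC 0.25),
liver (1.3, 1.82, 0.774), well-perfused tissues (3.5, 5.68, 0.774),
poorly perfused tissues (1.63, 35, 0.66) and blood (V 5.7 L); a plasma row
(V 3.4 L) shares the blood partition coefficient, so no separate plasma
state is integrated and the blood concentration is reported as plasma.
Tissues are perfusion-rate-limited: `V_i dC_i/dt = F_i (C_b − C_i/PC_i)`.
The blood closure sums the tissue exchange terms (the tissue flows add to
6.99 L/min; the nominal blood-row flow of 6.4 L/min is recorded but the
closure must use the actual tissue flows to conserve mass) and removes
urinary excretion at a fixed clearance of 0.016 L/min.

Oral dosing: each bolus adds `Fr_ing × weight × dose` (Fr_ing = 0.9) to a
gut amount that drains into the liver at k_gut = 0.025 /min. The liver
compartment receives the portal (gut) inflow as an amount rate
(`k_gut Q_gut`, the only dimensionally consistent reading) and is drained
by the lobule: the mean per-sinusoid elimination rate is scaled from one
lobule to the organ by `(0.8 × V_liver)/(384 × l_h³)` — the liver is an
average lobule replicated through the parenchyma, which occupies about
80 % of the organ — and multiplied by the coupling constant ξ = 0.75. The
arterial concentration is taken equal to mixed venous blood (no lung
compartment exists in this closure).

### Co-simulation loop

The loop macro-steps the PBPK ODEs at 0.5 min (classical RK4, 5 substeps);
within each macro step the lobule inlet is the free fraction of the liver
inflow mix `(F_liv C_b + k_gut Q_gut)/F_liv`, the lobule is sub-cycled at
the transport cadence (65 substeps), and the resulting clearance is held
constant over the macro step of the PBPK integration. All stochasticity
(necrosis commitment and delays) derives from one integer seed; identical
seeds give bit-identical outputs. A run may terminate early once drug,
reactive metabolites and oxidant load are all gone and no deaths are
pending — viability can no longer change and the recorded traces are
padded to the horizon.

The micro-scale lobule is a representative model, not a literal
sub-volume: its internal masses are not part of the body mass balance.
The body-side balance (absorbed dose = body burden + urinary + metabolized
+ gut residual) is tracked at every output time and stays at round-off in
practice (tolerance 0.1 % of dose); the sinusoid-level moiety balance is
verified separately in the transport tests (< 1e-6 relative per step).

### Inner-loop implementation

The production path of the lobule substep (transport kernel, joint
bulk+cell midpoint integration, necrosis bookkeeping) and of the in-vitro
population exposure is JIT-compiled with numba; a 2000-min whole-body
simulation runs in a few seconds. The reference implementations — the
stoichiometric `N @ v` right-hand side, scipy's LSODA for single cells and
for the per-section propagation step — remain the contract, and the test
suite asserts the fast path against them: the right-hand sides agree to
1e-12, 12-h single-cell trajectories to ~1e-3, and coupled sinusoid
propagation at the percent level expected from the integrator difference.

## 4. Experiments

- **In-vitro viability** (`simulate_in_vitro`): n cells per concentration
  (default 200), constant medium (infinite reservoir, 24 h), lognormal
  median-1 Vmax variability at CV 0.2; the positional hazard weight is 1
  (central-vein equivalent). The assay's cell density/medium volume are
  not modeled — the medium concentration is clamped.
- **LC50 estimation** (`estimate_lc50`): log-linear interpolation of the
  viability curve at 0.5; exact knots returned as-is; an unbracketed curve
  is an error, not a guess.
- **Dose scan / CYP scan**: one whole-body run per (dose, seed) or
  (CYP3A4, CYP2E1, seed); the threshold dose is the smallest scanned dose
  whose mean end-of-horizon viability is below 1. Note that recorded
  pericentral H2O2 peaks saturate just above the calibrated threshold
  whenever cells die (death freezes the state), so kinetic comparisons of
  H2O2 across variants are made with necrosis disabled.
- **Well-stirred reference** (`reference_pk`): the same PBPK with the
  lobule replaced by a spatially unresolved clearance whose extraction is
  the sinusoid's own steady extraction at the prevailing free inflow
  concentration (tabulated on a log grid, 150-min warmup so the slow
  binding pools are filled and loading is not mistaken for extraction).
  This is the regression surface standing in for external plasma-PK
  verification data, which are not bundled; at sub-toxic doses the coupled
  model matches it to better than 1 % pointwise (reduced chi-square ≈ 0.01
  at a 5 %-of-peak error scale). Agreement degrades by design at toxic
  doses, where cell death makes the coupled clearance time-dependent.

## 5. Numerical choices and degenerate inputs

- Substrate concentrations are clamped at zero inside rate laws; solver
  excursions below −(tolerance) are rejected by the non-negativity tests.
- The transport kernel is row-stochastic to round-off; with D → 0 it
  degenerates to exact plug flow (translation without spreading).
- Composing binned kernel substeps adds a bounded numerical dispersion of
  order l_h²/12 per re-binning; the Green's-function semigroup itself is
  verified at the continuous level to 1e-6, and the binned composition is
  checked at its own accuracy (few percent).
- Dead cells are frozen snapshots; a section's remaining live cells share
  one state vector (they are kinetically identical), which makes the 384-
  cell lobule cheap without changing any observable.
- Calibration failure modes (no H2O2 rise, unbracketable peak) raise with
  a diagnostic rather than returning a default.

## 6. What the synthetic conditions do and do not show

The in-vitro population, the zonated lobule and the PBPK parameters
emulate the study conditions: a 73-kg reference adult, a mean lobule with
six sinusoids, inter-cell enzyme variability as the only population
heterogeneity. Real data differ in ways the model deliberately omits:
physiological (organ volume/flow) variability, 3D lobule geometry and
inter-sinusoid structural heterogeneity, bile-side kinetics after MRP2
export, RNS/nitration chemistry (lumped into the ROS pathway), gene
induction, and regeneration after injury. Passing tests therefore show
internal consistency and that the calibrated model reproduces the reported
in-vitro and in-vivo endpoints under these idealized conditions — not that
the kinetic constants are the physiological ones; the supplementary
constants of the original cell model are not public, and ours are
reconstructed calibration targets.

## 7. Problem sizes used by the packaged studies

The dose scan runs 250–400 mg/kg in 10 mg/kg steps with 3 seeds per dose
and a 2000-min horizon (48 whole-body runs); the no-mortality comparison
runs {310, 450, 470} mg/kg with 3 seeds each; the in-vitro curve uses 200
cells at 9 concentrations for 24 h. These sizes reproduce the endpoint
statistics stably (the necrosis *timing* is stochastic; whether the
criterion is crossed at all is nearly deterministic at these sizes).
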
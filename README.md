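# hepatosim

A multi-scale simulator of acetaminophen (APAP, paracetamol)
hepatotoxicity, for toxicologists and modelers who want to connect
in-vitro cell-viability data to in-vivo dose thresholds mechanistically.
Three coupled scales:

- **Hepatocyte** — a kinetic model `dc/dt = N v(c, p)` of APAP uptake,
  Phase I oxidation to the reactive metabolite NAPQI (CYP3A4 / CYP2E1 / a
  lumped minor-CYP pool), Phase II conjugation (UGT, SULT, GST),
  glutathione (GSH) turnover, MRP export, and the superoxide → H₂O₂
  cascade that follows NAPQI–protein binding.
- **Lobule** — six sinusoids (tubes of 16 × 4 hepatocytes, radius 5 µm)
  with dispersive plug-flow transport: solutes advect at the
  Fahraeus-corrected suspension velocity U_x = 0.05 mm/s with molecular
  dispersion from the Stokes–Einstein relation D = k_B T/(6π η R_g), propagated
  in discrete steps with the exact Gaussian Green's-function kernel.
  CYP3A4 is zonated (×1.3 in the pericentral third).
- **Whole body** — a flow-limited PBPK model (adipose, liver,
  well-/poorly-perfused tissues, blood; 73-kg adult) with first-order oral
  absorption (Fr_ing = 0.9, k_gut = 0.025 /min) and fixed urinary
  clearance (0.016 L/min). Hepatic clearance is *not* a parameter: each
  macro step the lobule extracts drug from the liver inflow and the mean
  per-sinusoid eliminated amount E_k, scaled to the whole parenchyma
  (ξ = 0.75), drains the liver compartment.

Necrosis is stochastic: a hepatocyte whose H₂O₂ exceeds a critical value
while its GSH pool is depleted dies with a position-weighted exponential
hazard (pericentral cells first) after a 0–1 min random delay, and its
state freezes (`dc/dt = 0`). The critical H₂O₂ is calibrated so that the
reference cell's peak at the in-vitro LC₅₀ exposure (4000 µM APAP, 24 h)
equals 4000 µM — cell death in vivo is then an extrapolation of measured
in-vitro toxicity, not an assumption.

## Worked example

```python
from hepatosim import experiments as ex
from hepatosim.whole_body import DoseRegimen, simulate

cal = ex.calibrate_injury(target_lc50=4000.0)       # anchor the threshold
curve = ex.simulate_in_vitro(ex.InVitroSetup(seed=7), cal.profile, cal.injury)
print(ex.estimate_lc50(curve))                      # -> 3908 uM

res = simulate(DoseRegimen.single_oral(393.0, body_weight=73.0),
               profile=cal.profile, injury=cal.injury,
               duration=2000.0, seed=1)
print(res.cmax, res.final_viability)
```

prints an LC₅₀ of `3907.8` µM recovered from the simulated 200-cell
viability curve (calibration target 4000; the 2 % discrepancy is
binomial sampling plus interpolation), then `574.6 0.0` — a 393 mg/kg
overdose peaks near 575 mg/L in plasma and, in this individual
(CYP3A4 0.95, CYP2E1 1.0 µmol/L_cell/min), kills the lobule within the
2000-min horizon, starting at the central vein. Scanning doses instead:

```python
table = ex.dose_scan(range(250, 401, 10), cal.profile, cal.injury)
print(ex.threshold_dose(table))                     # -> 330.0
```

the smallest dose with any predicted mortality is `330.0` mg/kg, while
310 mg/kg leaves viability at exactly 1.0 — the model's dose threshold
for this individual. `ex.cyp_scan(...)` repeats the study across CYP3A4 /
CYP2E1 variants (0.95 vs 1.9, 1.0 vs 5.0 µmol/L_cell/min).

The `examples/` directory holds one short narrative script per
capability (single-cell overdose, in-vitro LC₅₀, sinusoid transport,
whole-body overdose, CYP variants). A thin CLI wraps the same calls:

```sh
hepatosim simulate --dose 393 --weight 73 --seed 1 --out out/
hepatosim --dump-defaults            # full YAML configuration
```

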
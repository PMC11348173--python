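# Methods

## Scope and model structure

`scpbpk` simulates a single SC bolus of an IgG-class therapeutic protein in
a population-representative human (74.8 kg, cardiac output 397.5 L/h, total
lymph flow 0.391 L/h) and predicts absolute bioavailability, plasma
pharmacokinetics and the occupancy dynamics of FcRn in the
injection-site-draining lymph nodes.  The state vector tracks three
species — dose-origin drug, systemic-origin drug and endogenous IgG — over:

- **SC site** (per-site volume from the published circular-spread
  geometry): vascular space (5 % of site), endothelial endosome (0.06 %),
  interstitial space (59.5 %).  Two-pore filtration–diffusion couples
  vascular and interstitial spaces; the filtrate equals the afferent lymph
  flow and splits over large/small pores (α_L = 0.158, σ_v,L = 0.157,
  σ_v,S = 0.998, Patlak fluxes with a diffusive-limit branch below
  Pe = 10⁻⁶).  Lymphatic drainage is hindered by σ_l = 0.2.
- **Lymphatic first pass**: the lymph capillary volume is traversed as a
  12-stage Erlang transit line (lymphatics are valved conduits; a single
  mixing tank would smear the printed 35 h arm residence time into a much
  longer tail), followed by the draining-node compartment with its APC
  endosomal pool.
- **Systemic backdrop**: plasma (2.9 L total, of which 0.4 L is tissue
  microvasculature), a central lymph-node compartment (total node volume
  minus the site-draining nodes), and one lumped permeability-limited
  tissue (5.2 L IgG-accessible interstitium, 0.015 L endothelial
  endosome).  The lumped bed is given larger permeability–surface products
  (PS_L = 0.5 × lymph flow) than the skin site because it stands in for the
  whole body including fenestrated beds.  Endogenous IgG is produced by
  zero-order synthesis into plasma.

## The FcRn salvage engine

Every endosomal pool (SC endothelium, APCs, central node, tissue) runs the
same kinetics: fluid-phase uptake delivers the surrounding medium; species
bind a shared finite receptor pool bimolecularly (k_on = 360 µM⁻¹h⁻¹,
k_off = k_on·K_D with K_D = 0.728 µM at pH 6.0 for IgG); bound material is
recycled at k_rc = 1 h⁻¹ (split FR = 0.715 to the vascular face for
endothelial pools; both branches re-enter the node fluid for APCs, which
have no vascular face); unbound material is catabolized at
k_cat = f_cat·k_int = 1 h⁻¹.  Binding is kinetic, not rapid-equilibrium,
because the transient saturation of the receptor is the phenomenon of
interest.  An optional missort branch (a fraction of bound recycling
traffic diverted to degradation) exists for APC pools; it is frozen at 0.

**APC uptake.**  The APC population of a draining-node group — macrophages,
dendritic cells and B cells lumped as one high-macropinocytosis pool —
turns the node fluid over at the fluid-phase rate K_up = 0.25 h⁻¹, so the
uptake clearance is K_up × V_node (2.17 × 10⁻³ L/h for the arm).  This is a
deliberate structural choice: lymph percolates through the APC-lined
sinuses, making the node compartment the population's sampling domain.
Scaling uptake instead by the APC volume fraction alone caps the
saturated-limit first-pass extraction at CL/(CL + L_eff) = 43 %, which
cannot produce the ~75 % losses this model predicts (and reproduces) for
APC-FcRn-knockout cohorts.  The APC volume fraction (24.5 % of the node,
derived from subcapsular-sinus macrophage counts scaled by their lineage
share) still sets the endosomal volume (25 % of APC volume), i.e. the
concentration scale at which saturation develops.

**Endogenous IgG and APCs.**  Endogenous IgG transits the lymph path
convectively but does not enter the APC endosomal pathway: the APC
compartment is a pre-systemic clearance mechanism for the dosed protein
and takes no part in endogenous-IgG homeostasis.  Baseline free FcRn in
APCs is therefore 100 %, and the baseline-normalized and absolute free
fractions coincide.  With endogenous competition included, the endogenous
complex pool buffers the receptor so strongly that a 10 mg dose depresses
free FcRn by only ~13 % and the uptake-rate sensitivity of bioavailability
largely disappears — qualitatively wrong behavior for the mechanism this
model exists to express.

## Parameters

| Parameter | Default | Units | Provenance |
|---|---|---|---|
| Site volume, flows, node/capillary volumes | per-site table | L/kg, fractions | published measurements (bundled `data/sites.yaml`) |
| Body weight | 74.8 | kg | back-solved from the site-volume geometry |
| K_up (APC fluid-phase uptake) | 0.25 | 1/h | measured macrophage pinocytosis |
| f_APC of node | 0.245 | – | mouse subcapsular-sinus counts |
| K_D (IgG–FcRn, pH 6.0) | 0.728 | µM | surface-plasmon-resonance value |
| k_on | 360 | 1/(µM·h) | fast binding, ≈10⁵ M⁻¹s⁻¹ |
| k_rc = k_cat | 1.0 | 1/h | endosomal trafficking timescale |
| FR | 0.715 | – | endothelial recycling polarity |
| FcRn, endothelial pools | 49.8 | µM | literature endosomal value |
| FcRn, APC endosomes | 5.78 | µM | **calibrated** (see below) |
| Tissue uptake clearance | 0.0226 | L/h | **calibrated** |
| Endogenous synthesis | 90.5 | mg/h | **calibrated** |
| Interstitial access | 0.48 | – | IgG steric exclusion from the matrix |
| Capillary transit stages | 12 | – | low-dispersion transit line |
| σ_l | 0.2 | – | lymphatic reflection coefficient |
| Plasma volume / baseline IgG / IgG t₁/₂ | 2.9 L / 12 g/L / 21 d | | standard human values (calibration anchors) |

## Calibration

`scpbpk.calibrate()` fits the three starred constants to three anchors —
12 g/L endogenous plasma IgG, 21-day terminal IgG half-life (computed from
the dominant eigenvalue of the drug subsystem linearized at the endogenous
steady state), and 65.1 % bioavailability for 10 mg into the arm — by
nested secant iterations (synthesis is re-anchored inside every half-life
evaluation because the tracer half-life depends on the endogenous occupancy
backdrop).  Residuals of the frozen set are all below 0.2 %
(`data/calibration_report.yaml`).  The calibration was run once
(`scripts/run_calibration.py`) and frozen; every other prediction in the
test suite and acceptance script uses the frozen file unchanged.

The structural defaults that were genuinely open — the transit-stage count,
the interstitial access fraction, the endogenous-IgG gating of APC uptake,
and the k_rc/k_cat pairing — were decided once during model construction
(the considerations are summarized above) and are configuration constants,
not per-scenario tuning knobs.

## Numerics

- Stiff integration: BDF, rtol 10⁻⁸, atol 10⁻¹⁰ mg, dense output at 0.1 h
  for the first 5 days (the FcRn transient) and 6 h thereafter; horizon
  60 days.  Halving tolerances changes bioavailability by < 10⁻⁴.
- Pre-dose steady state: coarse BDF equilibration of the endogenous
  subsystem followed by a damped Newton polish; accepted only if the
  maximum scaled residual is below 10⁻⁸ h⁻¹.  Knockout cohorts are
  equilibrated with their knockout, i.e. they are virtual individuals at
  their own homeostasis (endothelial knockout collapses baseline IgG).
- C_max/t_max are refined by a local quadratic fit around the discrete
  maximum; AUC by the trapezoid rule on the dense grid.
- Bioavailability requires the residual dose-label mass at the horizon to
  be < 0.1 % of the dose and cross-checks the arrival-based value against
  one minus the pre-systemic ledger to 0.2 % absolute.
- Virtual populations perturb K_up, site volumes and lymph flows by
  median-preserving log-normals (default CV 0.3), seeded and reproducible.

## Known limitations

- The systemic backdrop is a minimal surrogate, so absolute plasma metrics
  (C_max as % of dose, t_max) are approximate; cross-site *ratios* are the
  robust observable because the backdrop cancels.
- At very high doses (≳0.5 g) predicted bioavailability approaches the
  saturated-limit floor 1 − CL_APC/(CL_APC + L_eff) ≈ 25 % more quickly
  than reported observations suggest, because recycled drug re-enters the
  node fluid and is re-captured while saturation persists; the salvage
  capacity that would soften this floor cannot be raised without breaking
  the calibrated 10 mg behavior and the reported FcRn-transient depth.
- The free-FcRn minimum occurs at the node-concentration peak, i.e. after
  the site depot and the capillary line have both contributed their delay
  (~53 h for the arm); orderings across sites are preserved, but the
  absolute timing is later than the capillary residence time alone.
- Single bolus only; no multiple dosing, injection-volume or formulation
  effects, no charge-dependent uptake, no target-mediated disposition.
- Endogenous IgG does not interact with APCs (see above), so the model
  cannot describe APC contributions to IgG homeostasis.
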
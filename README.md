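# scpbpk — subcutaneous antibody absorption with saturable FcRn salvage

`scpbpk` is a mechanistic, physiologically based pharmacokinetic (PBPK)
simulator of subcutaneous (SC) monoclonal-antibody absorption.  Its purpose
is to predict **bioavailability from first principles** rather than fit it:
the fraction of an SC dose lost before reaching plasma emerges from
fluid-phase uptake into antigen-presenting cells (APCs) of the
injection-site-draining lymph nodes and the **transient saturation of
FcRn-mediated recycling** inside their endosomes.  It is aimed at PK
modelers and drug-discovery scientists who want to explore how dose, FcRn
affinity, APC uptake, and the injection site (arm, abdomen, back, thigh)
shape the absorption of an IgG-class therapeutic.

## Model

A bolus dose enters the interstitial space of a permeability-limited SC
site (vascular / endothelial-endosome / interstitial spaces; two-pore
filtration–diffusion across the capillary wall).  The interstitium drains
at the afferent lymph flow L_aff through lymph capillaries (a transit line
of residence time V_cap/L_aff) into the peripheral draining-node
compartment.  There the lumped APC population (24.5 % of node volume)
macropinocytoses node fluid at K_up = 0.25 h⁻¹; in the acidic endosome the
antibody competes for a finite FcRn pool,

    dC_free/dt    = uptake/V − k_on·C_free·R_free + k_off·C_bound − k_cat·C_free
    dC_bound/dt   = k_on·C_free·R_free − (k_off + k_rc)·C_bound
    R_free        = R_total − ΣC_bound ,   k_off = k_on·K_D(pH 6.0)

with bound material recycled (rescued) at k_rc and unbound material
degraded at k_cat.  Efferent lymph (93 % of afferent; the rest leaves as
solute-free water through aquaporins) carries the survivors through the
central lymphatics into plasma.  A minimal whole-body backdrop (plasma,
central lymph node, lumped two-pore tissue with endothelial FcRn,
endogenous IgG synthesis) provides the systemic disposition, the 12 g/L
endogenous IgG baseline and its 21-day half-life.

Bioavailability uses dose-origin splitting: site concentrations are
separated into a dose label and a systemic-return label, the dose label is
relabeled the instant it arrives in plasma, and

    F = (cumulative dose-label arrival in plasma) / dose ,

with a pathway-resolved elimination ledger (SC endothelium, draining-node
APCs, central lymph node, systemic tissue) that closes the mass balance
against F exactly.

Three unpublished constants (endogenous synthesis rate, tissue uptake
clearance, APC endosomal FcRn concentration) were calibrated once against
a 12 g/L IgG baseline, a 21-day IgG half-life and a 65.1 % arm
bioavailability for a 10 mg dose, then frozen
(`src/scpbpk/data/calibration.yaml`); everything else the package predicts
follows without further tuning.

## Worked example

```bash
scpbpk simulate --site arm --dose 10 --out out/
```

prints

```
bioavailability: 0.6510
```

and writes `out/run_timecourses.csv` plus `out/run_summary.json` containing

```
bioavailability          0.651
cmax                     1.035 mg/L   (30.0 % of the dose in plasma at peak)
tmax                     5.7 days
free FcRn in APCs        minimum 43.9 % of baseline at 53 h, back to
                         baseline by day 8
elimination (dose label) 34.9 % in draining-node APCs, 0.01 % in the SC
                         endothelium, ~0.01 % in the central lymph node
```

Read it as: of a 10 mg arm dose, 65.1 % reaches plasma intact; essentially
the entire pre-systemic loss happens in the draining-node APCs, whose free
FcRn transiently drops to ~44 % of baseline — the mechanistic signature of
saturable salvage.  Other commands: `scpbpk sweep --param apc.k_up
--values 0.125,0.25,0.5`, `scpbpk cohorts` (FcRn knockout cohorts),
`scpbpk sites` (cross-site Cmax/tmax/AUC ratios), `scpbpk removal-curve`,
all accepting a YAML config (`src/scpbpk/data/example_arm_10mg.yaml`).

The same functionality is available as a library:

```python
import scpbpk as s
res = s.simulate(s.ScenarioSpec(drug=s.DrugProperties(dose=10, injection_site="arm")))
res.bioavailability      # 0.651
res.free_fcrn.minimum_percent
res.ledger               # pathway-resolved elimination table
```

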
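# Example run configuration: 10 mg IgG bolus into the arm, default
# physiology, 60-day horizon.
scenario:
  drug:
    name: IgG
    molecular_weight: 150000.0
    kd_ph6: 0.728        # uM, FcRn affinity at endosomal pH 6.0
    dose: 10.0           # mg
    injection_site: arm
  knockouts:
    apc_fcrn: false
    endothelial_fcrn: false
  overrides: {}
execution:
  horizon_days: 60
  rtol: 1.0e-8
  atol: 1.0e-10
  seed: 0
output:
  formats: [csv, json]
  plots: false
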
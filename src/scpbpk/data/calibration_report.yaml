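# Residuals of the frozen calibration (relative to each anchor).
targets:
  terminal_half_life: 21.0
  baseline_igg: 12.0
  base_bioavailability: 0.651
fitted:
  synthesis_rate: 90.207426
  cl_up_tissue: 0.02260389
  fcrn_total_apc: 5.777442
relative_residuals:
  terminal_half_life: 0.001103026139857688
  baseline_igg: -7.251253830720117e-08
  base_bioavailability: -6.793571013963273e-06
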
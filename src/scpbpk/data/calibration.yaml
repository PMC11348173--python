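# Frozen calibration of the unpublished model constants.
# Produced by scripts/run_calibration.py; do not edit by hand.
# Anchors: plasma IgG baseline 12 g/L, terminal IgG half-life 21 d,
# arm bioavailability 0.651 for a 10 mg IgG dose.
synthesis_rate: 90.207426
cl_up_tissue: 0.02260389
fcrn_total_apc: 5.777442
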
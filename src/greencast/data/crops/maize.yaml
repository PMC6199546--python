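description: >
  Synthetic grain-maize parameter set typical of a long-cycle Pannonian
  hybrid. Illustrative values for the surrogate crop model, not a
  calibrated parameterisation of any published study.
name: maize
planting_doy: 115          # ~25 April
gdd_requirement: 1900.0    # deg C day above tbase
tbase: 10.0
kcb_stages: [0.30, 0.70, 1.15, 0.50]
stage_fractions: [0.20, 0.45, 0.80]
ke_soil: 1.00
wp_star: 30.0              # g/m2 per unit sum(Tr/ET0)
hi: 0.48
root_depth: 1.00           # m
depletion_fraction: 0.55
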
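description: >
  Synthetic spring-barley parameter set: early planting, low base
  temperature, short cycle finishing before high summer. Illustrative
  values for the surrogate crop model, not a calibrated
  parameterisation of any published study.
name: spring_barley
planting_doy: 80           # ~21 March
gdd_requirement: 1750.0
tbase: 0.0
kcb_stages: [0.25, 0.60, 1.05, 0.35]
stage_fractions: [0.20, 0.50, 0.85]
ke_soil: 1.00
wp_star: 14.0
hi: 0.45
root_depth: 0.80
depletion_fraction: 0.55
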
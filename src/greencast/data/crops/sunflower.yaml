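description: >
  Synthetic sunflower parameter set: oil crop with low harvest index
  and modest normalized water productivity, hence lower mass yield and
  higher footprint than the grain crops. Illustrative values for the
  surrogate crop model, not a calibrated parameterisation of any
  published study.
name: sunflower
planting_doy: 105          # ~15 April
gdd_requirement: 1600.0
tbase: 8.0
kcb_stages: [0.30, 0.65, 1.05, 0.40]
stage_fractions: [0.20, 0.45, 0.80]
ke_soil: 1.00
wp_star: 16.0
hi: 0.35
root_depth: 1.20
depletion_fraction: 0.50
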
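# Example experiment: two synthetic Pannonian sites, three summer crops,
# nine forecast seasons with the ensemble growing from 10 to 50 members.
seed: 7
years: {start: 2006, end: 2014}
output_dir: scratch/example_out
sites:
  - site_id: pannonia_south
    soil: pannonia_south
    climate:
      latitude: 45.3
      temp_level: 16.5
      temp_amplitude: 10.5
  - site_id: pannonia_north
    soil: pannonia_north
    climate:
      latitude: 48.2
      temp_level: 15.5
      temp_amplitude: 10.0
      p01: 0.23
      p11: 0.48
crops: [maize, spring_barley, sunflower]
scenario:
  temp_bias: 0.3
  precip_bias: 1.1
  member_inflation: 1.0
options:
  alpha: 0.05
  closeness_band: 2.0
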
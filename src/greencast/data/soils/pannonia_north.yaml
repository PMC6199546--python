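description: >
  Synthetic chernozem-like soil for the northern Pannonian example
  site: loess top horizon over sand/gravel, somewhat lower water
  retention. Illustrative values, not measured soil data.
fc: 0.30
wp: 0.13
sat: 0.44
initial_fill: 0.60
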
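description: >
  Synthetic chernozem-like soil for the southern Pannonian example
  site: deep clayey top horizon with high water retention.
  Illustrative values, not measured soil data.
fc: 0.33
wp: 0.16
sat: 0.46
initial_fill: 0.70
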
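# Empty-blister example: no tablet, no drug -- the cavity humidity simply
# relaxes exponentially toward the ambient humidity.
schema_version: 1
environment:
  temperature: 313 K
  ambient_rh: 70 %
  initial_cavity_rh: 40 %
  horizon: 30 day
blister:
  cavity_volume: 0.41 mL
  cavity_area: 3.9 cm^2
  k_perm: 1e-5 1/s
solver:
  output_interval: 0.5 day
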
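# Cilazapril case study, reinterpreted degradation pre-exponential factor.
#
# Identical to case_study.yaml except that the pre-exponential factor is
# read as 5.43e+18 1/s: with the standard negative activation-energy
# exponent this yields a degradation rate constant of ~1.7e-9 1/s at
# 40 degC / 70 % RH (half-life ~13 years), i.e. shelf-life-scale kinetics.
schema_version: 1
environment:
  temperature: 313 K
  ambient_rh: 70 %
  initial_cavity_rh: 40 %
  saturation_pressure: 7.39 kPa
  horizon: 3 year
blister:
  cavity_volume: 0.41 mL
  cavity_area: 3.9 cm^2
  wvtr:
    value: 0.3 g/m^2/day
    donor_rh: 90 %
    test_temperature: 313 K
tablet:
  dry_mass: 364 mg
  monolayer_load: 0.0296 g/g
  c_gab: 8.93
  k_gab: 0.847
  sorption_rate: 4.41 1/s
  initial_load: equilibrium-at-initial-rh
drug:
  molar_mass: 417.5 g/mol
  mass: 10 mg
  stoichiometric_factor: 1
  pre_exponential: 5.43e18 1/s
  activation_energy: 1.71e5 J/mol
  humidity_factor: 3.4
  arrhenius_sign: -1
solver:
  step_criterion: 1e-2
  convergence_limit: 1e-8
  output_interval: 1 day
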
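# Reference operating point of the separator: 2.5/5 um polystyrene mixture,
# both electrode sets driven, frequency at the big particle's DEP crossover.
geometry:
  W_ch_um: 100
  H_ch_um: 100
  l_um: 120
  d_um: 30
  n: 30
  Vpp1_V: 20
  Vpp2_V: 12.5
medium:
  rel_permittivity: 78.5
  conductivity_S_per_m: 1.0e-4
  viscosity_Pa_s: 1.0e-3
  density_kg_per_m3: 1000.0
particles:
  small: {radius_um: 2.5, material: polystyrene, density_kg_per_m3: 1050}
  big:   {radius_um: 5.0, material: polystyrene, density_kg_per_m3: 1050}
flow:
  Q_uL_per_h: 200
operation:
  frequency: crossover_big
field:
  spacing_um: 1.0
  tol: 1.0e-6
  max_iter: 200000
  relaxation: 1.0
  axial_bc: insulated
dynamics:
  time_step_s: 1.0e-5
  max_time_s: 60.0
  integrator: central_difference
seeding:
  rows: 9
  cols: 9
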
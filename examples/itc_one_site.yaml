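# One-site ITC design: asparagine binding to the tandem SBD1 site
# (K_a = 2.5e6 /M, i.e. K_D = 400 nM), 20 x 2 µl injections at 25 °C.
sites:
  - {n: 1.0, ka: 2.5e6, dh: -40.0}   # dh in kJ/mol
cell_volume_ul: 200.0
cell_conc_uM: 50.0
syringe_conc_uM: 500.0
injection_volumes_ul: [2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0,
                       2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0]
temperature: 298.15
noise_sd_uJ: 0.0
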
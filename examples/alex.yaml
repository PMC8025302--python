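# µs-ALEX timetrace simulation: 50/50 mixture of the open (E* 0.58) and
# closed (E* 0.74) SBD2 states, conditions near the half-saturation point.
mode: populations
n_populations: 2
states:
  - {label: open, e_app: 0.58, s_app: 0.5}
  - {label: closed, e_app: 0.74, s_app: 0.5}
weights: [0.5, 0.5]
simulation:
  duration: 30.0            # seconds of trace
  mean_dexc_photons: 200.0  # mean donor-excitation photons per burst
  burst_rate: 20.0          # bursts per second (~50 pM sample)
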
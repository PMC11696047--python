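# Dentate-lesion phenotype: onset phase broadly distributed over the cycle
# (kappa ~ 0.42), shallower slope, extra spikes in the early third.
precession_slope: -80.0
onset_phase_mean: 228.4
onset_phase_kappa: 0.42
within_cycle_sd: 55.0
early_phase_excess: 0.25
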
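# Control-like phenotype: steep precession, late and tightly concentrated
# onset phase. Values approximate the control CA3 population statistics
# (median slope ~ -150 deg/traversal, onset mean ~228 deg, kappa ~ 1.9).
precession_slope: -150.0
onset_phase_mean: 228.4
onset_phase_kappa: 1.91
within_cycle_sd: 40.0
early_phase_excess: 0.0
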
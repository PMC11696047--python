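# Entorhinal-lesion phenotype: onset phase preserved, within-cycle phase
# variability inflated (precession noisier throughout the train).
precession_slope: -150.0
onset_phase_mean: 228.4
onset_phase_kappa: 1.3
within_cycle_sd: 70.0
early_phase_excess: 0.0
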
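# GRPP: no resetting effect on the liver slice clock (null PRC).
[response]
peptide_name = "GRPP"
prc_coefficients = [0.0, 0.0, 0.0, 0.0, 0.0]
ec50_nM = 20.0
hill_n = 1.0
amplitude_damping_factor = 1.0
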
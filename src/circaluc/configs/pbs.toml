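# Vehicle control: no phase response, no amplitude effect.
[response]
peptide_name = "PBS"
prc_coefficients = [0.0, 0.0, 0.0, 0.0, 0.0]
ec50_nM = 1.0
hill_n = 1.0
amplitude_damping_factor = 1.0
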
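# Glucagon: same PRC shape as OXM scaled to a -3 h maximum delay at 180 deg;
# higher EC50 so resetting appears only at relatively high concentrations.
[response]
peptide_name = "GCG"
prc_coefficients = [-0.9375, 0.0, 1.5, 0.0, -0.5625]
ec50_nM = 60.0
hill_n = 1.5
amplitude_damping_factor = 0.95
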
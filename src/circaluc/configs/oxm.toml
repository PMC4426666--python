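# Oxyntomodulin: strong liver-slice resetting; PRC minimum -8 h at 180 deg,
# no shift at the ascending crossing, modest delay (~1 h) around 270 deg.
# Low EC50: effective already at sub-nanomolar doses.
[response]
peptide_name = "OXM"
prc_coefficients = [-2.5, 0.0, 4.0, 0.0, -1.5]
ec50_nM = 5.0
hill_n = 1.5
amplitude_damping_factor = 0.85
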
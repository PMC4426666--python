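# Dexamethasone: biphasic PRC (pure second harmonic) - delays for treatments
# in 0-90 deg, advances in 100-180 deg, no marked effect around 270 deg.
# Used experimentally at 100 uM, far above EC50.
[response]
peptide_name = "DEX"
prc_coefficients = [0.0, 0.0, 0.0, -2.5, 0.0]
ec50_nM = 1000.0
hill_n = 1.0
amplitude_damping_factor = 1.0
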
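# GCG-only dose-response cohort.
[generator]
peptides = ["GCG"]
doses_nM = [0.5, 1.5, 4.5, 15.0, 45.0, 150.0, 450.0]
replicates = 5
phase_window_deg = [180.0, 200.0]
noise_frac = 0.05

[generator.oscillator]
duration_h = 192.0
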
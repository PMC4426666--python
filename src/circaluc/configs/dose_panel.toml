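# Five-peptide slice dose-response design: 0.5-450 nM ladder, n = 5 per dose,
# treatments in the 180-200 degree window, 5% amplitude noise, 8-day traces.
[generator]
peptides = ["GLP-1", "GLP-2", "GRPP", "GCG", "OXM"]
doses_nM = [0.5, 1.5, 4.5, 15.0, 45.0, 150.0, 450.0]
replicates = 5
phase_window_deg = [180.0, 200.0]
noise_frac = 0.05

[generator.oscillator]
duration_h = 192.0

[analysis]
detrend_window_h = 24.0
smooth_window_h = 2.0
min_separation_h = 12.0
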
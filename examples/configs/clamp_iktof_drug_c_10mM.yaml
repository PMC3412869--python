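# Clamp-level block signature of the closed-state blocker at 10 mM:
# hold -70 mV, 500 ms test pulse to +50 mV (peak suppressed, area spared).
protocol: clamp
channel: iktof
variant: epicardial
drug: C
dose_mM: 10.0
segments: [[20.0, -70.0], [500.0, 50.0]]
outdir: results/clamp_drug_c
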
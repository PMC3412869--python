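# AP-level dose-response of the open-state blocker in the endocardial cell:
# relative APD50 prolongation at 1 Hz, normalized to complete I_Ktof block.
# Run with:  python -c "from mouseap.config import RunConfig, run; run(RunConfig.from_yaml('examples/configs/dose_response_endo_drug_o.yaml'))"
protocol: dose_response
variant: endocardial
drug: O
metric: apd50_prolongation
doses: [0.01, 0.03, 0.1, 0.3, 1.0]
fast: true
n_beats: 60
outdir: results/dose_response_endo_drug_o
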
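# Ultra-rapidly activating delayed rectifier K+ current (Kv1.5), scheme:
#   C1 = C2 = C3 = C4 = O <-> I.
# Activation expands the Bondarenko et al. (2004) a_ur gate. The O<->I rates
# are determined algebraically from the HH steady state/time constant of
# i_ur, plus a residual recovery rate rec0 that leaves inactivation
# incomplete at depolarized potentials (cloned Kv1.5 phenotype).
channel: ikur
states: [C1, C2, C3, C4, O, I]
conducting: [O]
conductance:   # mS/uF
  epicardial: {value: 0.160, provenance: bondarenko2004-apex}
  endocardial: {value: 0.1200, provenance: calibrated-apd-anchor}
  septal: {value: 0.0975, provenance: bondarenko2004-septum}
rates:
  act_vh: {value: -22.5, units: mV, provenance: bondarenko2004}
  act_k: {value: 7.7, units: mV, provenance: bondarenko2004}
  tau_a: {value: 0.493, units: ms, provenance: bondarenko2004}
  tau_b: {value: 0.0629, units: 1/mV, provenance: bondarenko2004}
  tau_c: {value: 2.058, units: ms, provenance: bondarenko2004}
  inact_vh: {value: 45.2, units: mV, provenance: bondarenko2004, note: "i_ss = 1/(1+exp((V+inact_vh)/inact_k))"}
  inact_k: {value: 5.7, units: mV, provenance: bondarenko2004}
  tau_i0: {value: 1200.0, units: ms, provenance: bondarenko2004, note: "tau_i = tau_i0 - tau_i_amp/(1+exp((V+inact_vh)/inact_k))"}
  tau_i_amp: {value: 170.0, units: ms, provenance: bondarenko2004}
  rec0: {value: 0.00017, provenance: calibrated-phenotype, note: "residual I->O rate; incomplete inactivation"}
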
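# Slow transient outward K+ current (Kv1.4), Markov scheme:
#   C1 = C2 = C3 = C4 = O, O <-> IN (N-type), IN <-> INC (coupled C-type),
#   O <-> IC1 <-> IC2 (C-type chain).
# Activation ladder expands the Bondarenko et al. (2004) a_tos gate; the
# per-subunit midpoint is shifted so the 4-subunit open-probability midpoint
# matches the single-gate curve. All inactivation rates are voltage-
# insensitive (coupled N/C-type mechanism of Kv1.4).
channel: iktos
states: [C1, C2, C3, C4, O, IN, INC, IC1, IC2]
conducting: [O]
conductance:   # mS/uF
  epicardial: {value: 0.0, provenance: stated-zero}
  endocardial: {value: 0.0, provenance: stated-zero}
  septal: {value: 0.0629, provenance: bondarenko2004-septum}
rates:
  act_vh: {value: -34.5, units: mV, provenance: bondarenko2004-shifted, note: "per-subunit a_ss midpoint; -22.5 shifted by -12 for the 4th-power ladder"}
  act_k: {value: 7.7, units: mV, provenance: bondarenko2004}
  tau_a: {value: 0.493, units: ms, provenance: bondarenko2004, note: "tau = tau_a*exp(-tau_b*V)+tau_c"}
  tau_b: {value: 0.0629, units: 1/mV, provenance: bondarenko2004}
  tau_c: {value: 2.058, units: ms, provenance: bondarenko2004}
  kni: {value: 0.0030, provenance: calibrated-phenotype, note: "O->IN"}
  knr: {value: 0.0004, provenance: calibrated-phenotype, note: "IN->O; sets seconds-scale recovery"}
  kcf: {value: 0.0008, provenance: calibrated-phenotype, note: "O->IC1"}
  kcb: {value: 0.0003, provenance: calibrated-phenotype}
  k2f: {value: 0.0003, provenance: calibrated-phenotype, note: "IC1->IC2"}
  k2b: {value: 0.00012, provenance: calibrated-phenotype}
  kncf: {value: 0.0005, provenance: calibrated-phenotype, note: "IN->INC"}
  kncb: {value: 0.0002, provenance: calibrated-phenotype}
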
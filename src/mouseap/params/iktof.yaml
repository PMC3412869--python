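# Fast transient outward K+ current (Kv4.x), Markov scheme:
#   C1 = C2 = C3 = O = I1 = I2, with closed-state inactivation C3 <-> I1.
# Activation ladder is the HH expansion of the Bondarenko et al. (2004)
# a_tof gate (a^3), so three closed states. Inactivation rates are
# calibrated to the Kv4.x phenotype targets listed in PROVENANCE.md.
channel: iktof
states: [C1, C2, C3, O, I1, I2, B1, B2, B3, BO]
conducting: [O]
conductance:   # mS/uF
  epicardial: {value: 0.4067, provenance: bondarenko2004-apex}
  endocardial: {value: 0.2000, provenance: calibrated-apd-anchor}
  septal: {value: 0.0798, provenance: bondarenko2004-septum}
rates:   # per-ms unless noted
  act_a1: {value: 0.18064, provenance: bondarenko2004, note: "alpha_a = act_a1*exp(act_a2*(V+30))"}
  act_a2: {value: 0.03577, units: 1/mV, provenance: bondarenko2004}
  act_b1: {value: 0.3956, provenance: bondarenko2004, note: "beta_a = act_b1*exp(-act_b2*(V+30))"}
  act_b2: {value: 0.06237, units: 1/mV, provenance: bondarenko2004}
  oi_base: {value: 0.002, provenance: calibrated-phenotype, note: "O->I1 = oi_base + oi_amp/(1+exp(-(V-oi_vh)/oi_k))"}
  oi_amp: {value: 0.030, provenance: calibrated-phenotype}
  oi_vh: {value: -15.0, units: mV, provenance: calibrated-phenotype}
  oi_k: {value: 8.0, units: mV, provenance: calibrated-phenotype}
  io_a: {value: 0.030, provenance: calibrated-phenotype, note: "I1->O = io_a*exp(-(V-io_vref)/io_k)"}
  io_vref: {value: -70.0, units: mV, provenance: calibrated-phenotype}
  io_k: {value: 25.0, units: mV, provenance: calibrated-phenotype}
  ci_f: {value: 0.30, provenance: calibrated-phenotype, note: "C3->I1; preferential closed-state inactivation"}
  ci_b: {value: 0.002, provenance: calibrated-phenotype, note: "I1->C3"}
  k12: {value: 0.006, provenance: calibrated-phenotype, note: "I1->I2 deep inactivation"}
  k21: {value: 0.012, provenance: calibrated-phenotype, note: "I2->I1"}
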
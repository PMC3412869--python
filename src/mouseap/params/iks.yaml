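# Slow delayed rectifier K+ current (KCNQ1/KCNE1). Structure and rates from
# the Silva & Rudy (2005) Markov model: four subunits each crossing two
# voltage-sensor steps (rates alpha/beta then gamma/delta), 15 closed zipper
# states, opening C15 -> O1 (theta/eta) and O1 <-> O2 (psi/omega). Rates are
# written k = k1 * exp(+/- k2 * V*F/RT).
channel: iks
states: 17 zipper states, O1, O2
conducting: [O1, O2]
conductance:   # mS/uF
  epicardial: {value: 0.00575, provenance: bondarenko2004}
  endocardial: {value: 0.00575, provenance: bondarenko2004}
  septal: {value: 0.00575, provenance: bondarenko2004}
rates:
  a1: {value: 3.98e-4, provenance: silva-rudy2005}
  a2: {value: 0.361, provenance: silva-rudy2005}
  b1: {value: 5.74e-5, provenance: silva-rudy2005}
  b2: {value: 0.0923, provenance: silva-rudy2005}
  g1: {value: 3.41e-3, provenance: silva-rudy2005}
  g2: {value: 0.868, provenance: silva-rudy2005}
  d1: {value: 1.20e-3, provenance: silva-rudy2005}
  d2: {value: 0.330, provenance: silva-rudy2005}
  theta: {value: 6.47e-3, provenance: silva-rudy2005}
  e1: {value: 1.25e-2, provenance: silva-rudy2005}
  e2: {value: 0.481, provenance: silva-rudy2005}
  p1: {value: 6.33e-3, provenance: silva-rudy2005}
  p2: {value: 1.27, provenance: silva-rudy2005}
  w1: {value: 4.91e-3, provenance: silva-rudy2005}
  w2: {value: 0.679, provenance: silva-rudy2005}
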
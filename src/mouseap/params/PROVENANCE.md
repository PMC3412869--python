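# Parameter provenance

Every rate constant and conductance in the YAML files in this directory
carries a `provenance` tag. The tags mean:

- **bondarenko2004** — transcribed from the published Bondarenko, Szigeti,
  Bett, Kim & Rasmusson (2004) mouse ventricular myocyte model (the
  substrate cell model; `-apex` / `-septum` mark its two regional variants).
  No machine-readable source (e.g. CellML) was used; the transcription is
  from the published description and should be treated as approximate where
  the original print is ambiguous.
- **bondarenko2004-shifted** — a Bondarenko gate parameter with a documented
  shift applied when a single HH gate is expanded into a multi-subunit
  Markov ladder (the ladder's open-probability midpoint is a shifted version
  of the per-subunit midpoint).
- **silva-rudy2005** — transcribed from the Silva & Rudy (2005) IKs Markov
  model.
- **calibrated-phenotype** — not available in a printed table; fixed once by
  calibrating the isolated channel against its target phenotype, then
  frozen. Targets used:
  - I_Ktof: fast activation (tau < 2 ms at +50 mV); inactivation
    time-to-half-decay ~20-40 ms at +50 mV; near-complete inactivation
    within a 500 ms step; recovery tau ~25-40 ms at -80 mV; steady-state
    inactivation midpoint near -45 mV (negative-shifted, reflecting
    closed-state inactivation of Kv4 channels).
  - I_Ktos: slow, voltage-insensitive inactivation at positive potentials
    (time-to-half-decay at +30 vs +50 mV within 10%); seconds-scale recovery.
  - I_Kur: very slow inactivation (~1.2 s) that remains incomplete at
    depolarized potentials.
- **calibrated-clamp-anchor** — drug binding constants fixed once from the
  clamp-level anchor behaviors of the two idealized blockers: the
  closed-state blocker produces ~80% peak but <20% area reduction at 10 mM
  and no detectable effect at 1 uM (hold -70 mV, 500 ms test to +50 mV);
  the open-state blocker has an area-reduction IC50 of 10 uM and at 1 mM
  blocks the peak ~80% with near-total area reduction.
- **calibrated-apd-anchor** — regional conductance scalings not available in
  a printed table; the endocardial I_Ktof/I_Kur/I_Kss conductances are the
  epicardial (apex) values scaled by a single factor fixed so that the
  endocardial control action potential at 1 Hz has APD90 near 30 ms, then
  frozen.
- **stated-zero** — explicitly zero in the endocardial and epicardial cell
  variants (I_Ktos is confined to the septal variant).

Because the full printed rate-constant table for the four Markov K+ schemes
was not available for transcription, the channel-level and AP-level
acceptance checks in `tests/test_acceptance.py` are property-based
(mechanism signatures, orderings, monotonicity, and calibrated anchors)
rather than digit-exact comparisons. This file is the record of that
degradation and of which constants are transcription vs. calibration.
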
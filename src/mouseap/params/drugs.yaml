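# Idealized I_Ktof-specific blockers.
#
# drug_c: closed-state blocker (4-AP-like). Binds competitively to the three
#   closed states (C1,C2,C3 -> B1,B2,B3); bound states interconvert with the
#   same activation-ladder rates as the closed states; bound states are
#   non-conducting and cannot inactivate.
# drug_o: open-state blocker (quinidine-like). Binds competitively to the
#   open state (O -> BO); BO is non-conducting.
#
# Association rates scale linearly with dose (kon * [D]); dissociation is
# dose-independent. Values are calibrated once to the clamp-level anchors
# in PROVENANCE.md (resting-block Kd for drug C, area-IC50 for drug O).
drug_c:
  mechanism: closed_state
  kon: {value: 0.00008, units: 1/(mM*ms), provenance: calibrated-clamp-anchor}
  koff: {value: 0.0002, units: 1/ms, provenance: calibrated-clamp-anchor, note: "resting bound states B1/B2; Kd = 2.5 mM at rest, multi-second equilibration gives reverse use dependence"}
  koff_depol: {value: 0.010, units: 1/ms, provenance: calibrated-clamp-anchor, note: "B3, relief of block on depolarization (4-AP-like); spares the current area during long steps"}
drug_o:
  mechanism: open_state
  kon: {value: 4.0, units: 1/(mM*ms), provenance: calibrated-clamp-anchor}
  koff: {value: 0.002, units: 1/ms, provenance: calibrated-clamp-anchor, note: "slow dissociation; the 10 uM area-IC50 is kinetic (kon*[D] vs. inactivation), not the equilibrium Kd"}
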
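"""S1-S2 restitution of the endocardial model.

After a steady 1 Hz conditioning train (S1), a single premature stimulus
(S2) is delivered at coupling intervals from 40 to 300 ms. The table lists
the S2 beat's APDs and peak potential: amplitude recovers toward the
steady-state value as the interval lengthens, and the early restitution
slope is negative (premature beats are broader, not shorter - the mouse
signature of slow I_Ktof recovery from inactivation).
"""

from mouseap import s1s2_restitution

df = s1s2_restitution(
    "endocardial", s1_bcl=1000.0,
    s2_intervals=(40.0, 60.0, 100.0, 200.0, 300.0), n_beats=40,
)
cols = ["beat", "S1S2_ms", "apd30", "apd75", "apd90", "peak_V", "captured"]
print(df[cols].round(2).to_string(index=False))
print(
    "\nThe S2 peak climbs back to the S1 amplitude by ~300 ms; at 40 ms the "
    "stimulus no longer elicits a full action potential (captured=False, "
    "APDs flagged absent)."
)
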
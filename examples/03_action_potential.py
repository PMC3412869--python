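"""Steady 1 Hz pacing of the endocardial and epicardial myocyte models.

Paces each variant with the standard stimulus (0.5 ms, 60 pA/pF), measures
the action potential durations of the final beat, and writes the traces to
CSV. Pre-pacing is shortened from the production 1000 beats to keep the
example quick; the convergence flag reports whether the 0.01% beat-to-beat
criterion was reached.
"""

from mouseap import apd_set, run_to_steady_pacing

for variant in ("endocardial", "epicardial"):
    res = run_to_steady_pacing(variant, bcl=1000.0, n_beats=40)
    a = apd_set(res.trace)
    res.trace.to_csv(f"{variant}_1hz_beat.csv")
    print(
        f"{variant:12s}: peak {a.peak_V:6.1f} mV, (dV/dt)max {a.dvdt_max:5.0f} mV/ms, "
        f"APD30 {a.apd30:5.2f}  APD50 {a.apd50:5.2f}  APD75 {a.apd75:5.2f}  "
        f"APD90 {a.apd90:5.2f} ms (converged={res.converged})"
    )

print(
    "\nThe epicardial cell repolarizes faster than the endocardial cell at "
    "every level - the transmural gradient carried by its larger I_Ktof, "
    "I_Kur and I_Kss conductances."
)
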
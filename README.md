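# mouseap

Markov-model simulator of the mouse ventricular action potential, built to
ask a pharmacology question: **how does the conformational state a drug
binds to — not just its potency — shape its effect on repolarization at
different heart rates?**

The mouse ventricle repolarizes through a fast transient outward K⁺
current (I_Ktof, Kv4.x) working alongside I_Ktos (Kv1.4), I_Kur (Kv1.5),
I_Ks (KCNQ1/KCNE1), I_Kss, I_Kr and I_K1. `mouseap` represents the four
named currents as continuous-time Markov chains

    dp/dt = Q(V, [D]) p,        I = G · p_open · (V − E_K),

embedded in a whole-cell ODE model (Na⁺, L-type Ca²⁺ and rapid delayed
rectifier Markov chains, Ca²⁺ handling, pumps and exchangers after
Bondarenko et al. 2004), with the membrane equation
dV/dt = −(ΣI_ion + I_stim) in pA/pF. Two idealized I_Ktof-specific
blockers are built in as extra Markov states:

* **drug C** (closed-state, 4-AP-like): binds C1–C3 → B1–B3; block
  accumulates at rest and is relieved on depolarization, so it blunts the
  current peak while sparing total current flow, and prolongs the action
  potential *more* at slow rates (reverse use dependence);
* **drug O** (open-state, quinidine-like): binds O → BO during each action
  potential, suppressing total current flow at doses that barely touch the
  peak, and prolongs the action potential *more* at fast rates (use
  dependence).

The library covers the full characterization workflow: ideal-clamp channel
protocols (double-pulse availability, dose–response with peak/area block
metrics and Boltzmann fits), steady pacing with APD30/50/75/90 measured
from (dV/dt)max, APD–cycle-length scans, S1–S2 restitution, AP-level
dose–response normalized to complete I_Ktof block, and a use-dependence
classifier. Audience: cardiac electrophysiologists and safety
pharmacologists doing in-silico mechanism studies.

## Worked example

```python
from mouseap import DrugSpec, apd_set, run_to_steady_pacing

for variant in ("endocardial", "epicardial"):
    res = run_to_steady_pacing(variant, bcl=1000.0, n_beats=40)
    a = apd_set(res.trace)
    print(variant, f"APD30 {a.apd30:.2f}  APD75 {a.apd75:.2f}  APD90 {a.apd90:.2f} ms")
```

prints (endocardial first):

```
endocardial APD30 3.56  APD75 19.41  APD90 29.70 ms
epicardial APD30 2.50  APD75 15.74  APD90 25.82 ms
```

— a short, spike-like murine action potential, with the epicardial cell
repolarizing faster at every level (its larger I_Ktof/I_Kur/I_Kss). Adding
`drug=DrugSpec.drug_o(0.1)` (0.1 mM open-state blocker) to the same call
prolongs the endocardial APD30 by ~40–60% depending on rate; scanning
`bcl` and normalizing to control reproduces the use-dependent /
reverse-use-dependent fingerprints of the two mechanisms (see
`examples/04_rate_dependence.py`).

The `examples/` scripts each run one capability end to end and print what
the numbers mean: channel clamp characterization, clamp-level
dose–response (drug C at 10 mM: ~78% peak but only ~7% area block; drug O
area-block half-max ≈ 10 µM), steady pacing, rate-dependence
classification, and S1–S2 restitution.

A thin CLI mirrors the library for shell use:

```bash
mouseap pace --variant endocardial --fast
mouseap dose-response --drug O --metric area
mouseap bcl-scan --drug C --dose 1.0 --fast
mouseap restitution --s1-bcl 1000 --fast
mouseap validate
```

Every run writes a summary CSV plus a provenance JSON (parameter-file
hashes, solver tolerances, beat counts). All parameters live in annotated
YAML files under `src/mouseap/params/`, one per channel, each constant
tagged with its provenance; `docs/methods.md` describes the model,
calibration targets and numerics.

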
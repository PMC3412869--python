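"""Use dependence vs reverse use dependence of I_Ktof block.

Scans steady-state pacing rate (BCL 100 ms - 3 s) in control and under the
two blockers, normalizes each drugged APD to its control at the same BCL,
and classifies the rank trend: relative prolongation growing with BCL is
reverse use dependence (the drug works best at slow rates, 4-AP-like);
shrinking with BCL is use dependence (quinidine-like).
"""

import numpy as np

from mouseap import DrugSpec, apd_set, run_to_steady_pacing, use_dependence_index

BCLS = (100.0, 200.0, 500.0, 1000.0, 2000.0)


def scan(variant, drug=None):
    out = {}
    for bcl in BCLS:
        n = int(max(30, min(120, 60000 / bcl)))
        res = run_to_steady_pacing(variant, bcl=bcl, n_beats=n, drug=drug)
        out[bcl] = apd_set(res.trace)
    return out


for variant, drug, level, tag in (
    ("endocardial", DrugSpec.drug_c(1.0), "apd75", "drug C 1 mM, APD75"),
    ("epicardial", DrugSpec.drug_o(0.1), "apd30", "drug O 0.1 mM, APD30"),
):
    ctrl = scan(variant)
    drugged = scan(variant, drug)
    rel = np.array([getattr(drugged[b], level) / getattr(ctrl[b], level)
                    for b in BCLS])
    label, _ = use_dependence_index(BCLS, rel)
    print(f"{tag} ({variant}):")
    for b, r in zip(BCLS, rel):
        print(f"  BCL {b:6.0f} ms  relative {level.upper()} {r:.3f}")
    print(f"  -> {label}\n")
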
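"""Physical constants, cell geometry and fixed ionic milieu.

Units used throughout the package:

* time            ms
* voltage         mV
* concentration   uM (micromolar) unless a drug dose, which is mM
* current density pA/pF
* conductance     mS/uF

Geometry and milieu are those of the Bondarenko et al. (2004) mouse
ventricular myocyte model, the substrate into which the Markov K+ channel
schemes are inserted.
"""

# Thermodynamics
FARADAY = 96.5          # C/mmol
RGAS = 8.314            # J/(mol*K)
TEMP = 298.0            # K
RT_OVER_F = RGAS * TEMP / FARADAY   # ~25.67 mV

# Cell geometry
ACAP = 1.534e-4         # capacitive membrane area, cm^2
CM = 1.0                # specific capacitance, uF/cm^2
V_MYO = 25.84e-6        # myoplasmic volume, uL
V_JSR = 0.12e-6         # junctional SR volume, uL
V_NSR = 2.098e-6        # network SR volume, uL
V_SS = 1.485e-9         # subspace volume, uL

# Fixed extracellular concentrations (uM)
KO = 5400.0
NAO = 140000.0
CAO = 1800.0

# Default intracellular K+ used for channel-level (clamp) work, uM.
# Whole-cell simulations track K_i dynamically; the clamp protocols use the
# diastolic value so that E_K matches the intact cell.
KI_DEFAULT = 143720.0


def nernst_k(ko: float = KO, ki: float = KI_DEFAULT) -> float:
    """Nernst potential for K+ in mV."""
    import math

    if ko <= 0 or ki <= 0:
        raise ValueError("concentrations must be positive")
    return RT_OVER_F * math.log(ko / ki)
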
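"""Whole-cell mouse ventricular myocyte model.

The membrane equation is

    dV/dt = -(I_CaL + I_pCa + I_NaCa + I_Cab + I_Na + I_Nab + I_NaK
              + I_Ktof + I_Ktos + I_K1 + I_Ks + I_Kur + I_Kss + I_Kr
              + I_ClCa + I_stim)

with all currents in pA/pF, so no explicit capacitance appears. The
substrate (I_Na, I_CaL, I_Kr Markov chains, Ca2+ handling, pumps and
exchangers, I_K1, I_Kss, I_ClCa) follows the Bondarenko et al. (2004)
mouse model; the four K+ currents I_Ktof, I_Ktos, I_Kur and I_Ks are the
Markov schemes of :mod:`mouseap.rates`, including the I_Ktof drug-bound
states, which are integrated whether or not a drug is present (at zero
concentration their dynamics reduce exactly to the unblocked scheme).

All channel-state blocks integrate every occupancy; conservation is never
imposed by elimination for the four Markov K+ schemes, only checked.
Integration uses an adaptive embedded Runge-Kutta (Dormand-Prince 4(5))
with mixed absolute/relative error control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import rates
from .channels import load_conductance, load_rate_vector
from .drugs import DrugSpec
from .trace import CellTrace

# ---------------------------------------------------------------------------
# State vector layout
# ---------------------------------------------------------------------------

IV = 0
INAI, IKI, ICAI, ICASS, ICAJSR, ICANSR = 1, 2, 3, 4, 5, 6
ILTRPN, IHTRPN = 7, 8
IRYR_PO1, IRYR_PO2, IRYR_PC2, IPRYR = 9, 10, 11, 12
ICAL0 = 13      # 7 states: O, C2, C3, C4, I1, I2, I3 (C1 = 1 - sum)
INA0 = 20       # 8 states: CNa2, CNa1, ONa, IFNa, I1Na, I2Na, ICNa2, ICNa3 (CNa3 = 1 - sum)
IKR0 = 28       # 4 states: CK1, CK2, OK, IK (CK0 = 1 - sum)
IAKSS = 32
ITOF0 = 33      # 10 states, order per rates.py
ITOS0 = 43      # 9 states
IKUR0 = 52      # 6 states
IKS0 = 58       # 17 states
NSTATES = 75

CURRENT_NAMES = (
    "ICaL", "IpCa", "INaCa", "ICab", "INa", "INab", "INaK",
    "IKtof", "IKtos", "IK1", "IKs", "IKur", "IKss", "IKr", "IClCa",
)

# Parameter vector layout
P_GKTOF, P_GKTOS, P_GKS, P_GKUR, P_GKSS = 0, 1, 2, 3, 4
P_GKR, P_GNA, P_GCAL = 5, 6, 7
P_CONC, P_KONC, P_KOFFC, P_KONO, P_KOFFO, P_KOFFC3 = 8, 9, 10, 11, 12, 13
_OFF_TOF = 14
_OFF_TOS = _OFF_TOF + len(rates.IKTOF_PARAM_NAMES)
_OFF_KUR = _OFF_TOS + len(rates.IKTOS_PARAM_NAMES)
_OFF_KS = _OFF_KUR + len(rates.IKUR_PARAM_NAMES)
NPARAMS = _OFF_KS + len(rates.IKS_PARAM_NAMES)

# Physical constants and geometry (duplicated as plain floats for numba)
_F = 96.5
_RTF = 8.314 * 298.0 / 96.5
_ACAP_CM = 1.534e-4          # uF
_VMYO = 25.84e-6
_VJSR = 0.12e-6
_VNSR = 2.098e-6
_VSS = 1.485e-9
_KO, _NAO, _CAO = 5400.0, 140000.0, 1800.0

# Variant-specific conductances not owned by a Markov channel file
_GKSS = {"epicardial": 0.050, "endocardial": 0.045, "septal": 0.0324}

VARIANTS = ("endocardial", "epicardial", "septal")


def pack_params(
    variant: str = "endocardial",
    drug: DrugSpec | None = None,
    conductance_overrides: dict | None = None,
) -> np.ndarray:
    """Assemble the flat parameter vector for the jitted right-hand side."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    g = {
        "GKtof": load_conductance("iktof", variant),
        "GKtos": load_conductance("iktos", variant),
        "GKs": load_conductance("iks", variant),
        "GKur": load_conductance("ikur", variant),
        "GKss": _GKSS[variant],
        "GKr": 0.078,
        "GNa": 13.0,
        "GCaL": 0.1729,
    }
    if conductance_overrides:
        unknown = set(conductance_overrides) - set(g)
        if unknown:
            raise ValueError(f"unknown conductance overrides: {sorted(unknown)}")
        g.update(conductance_overrides)
    p = np.zeros(NPARAMS)
    p[P_GKTOF], p[P_GKTOS], p[P_GKS], p[P_GKUR], p[P_GKSS] = (
        g["GKtof"], g["GKtos"], g["GKs"], g["GKur"], g["GKss"],
    )
    p[P_GKR], p[P_GNA], p[P_GCAL] = g["GKr"], g["GNa"], g["GCaL"]
    p[P_KOFFC3] = -1.0
    if drug is not None:
        p[P_CONC] = drug.concentration
        if drug.mechanism == "closed_state":
            p[P_KONC], p[P_KOFFC] = drug.kon, drug.koff
            p[P_KOFFC3] = drug.koff_b3
        else:
            p[P_KONO], p[P_KOFFO] = drug.kon, drug.koff
    p[_OFF_TOF:_OFF_TOS] = load_rate_vector("iktof")
    p[_OFF_TOS:_OFF_KUR] = load_rate_vector("iktos")
    p[_OFF_KUR:_OFF_KS] = load_rate_vector("ikur")
    p[_OFF_KS:] = load_rate_vector("iks")
    return p


def initial_state() -> np.ndarray:
    """A generic diastolic starting point; run to rest before production use."""
    y = np.zeros(NSTATES)
    y[IV] = -82.4
    y[INAI] = 14237.0
    y[IKI] = 143720.0
    y[ICAI] = 0.115
    y[ICASS] = 0.115
    y[ICAJSR] = 1299.5
    y[ICANSR] = 1299.5
    y[ILTRPN] = 11.27
    y[IHTRPN] = 125.3
    # channel blocks start in their first (fully closed/available) state
    y[ITOF0] = 1.0
    y[ITOS0] = 1.0
    y[IKUR0] = 1.0
    y[IKS0] = 1.0
    return y


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

@njit(cache=True)
def _currents_into(y, p, out):
    """All membrane current densities (pA/pF), in CURRENT_NAMES order."""
    V = y[IV]
    nai = y[INAI]
    ki = y[IKI]
    cai = y[ICAI]
    vf = V / _RTF

    e_k = _RTF * np.log(_KO / ki)
    e_na = _RTF * np.log((0.9 * _NAO + 0.1 * _KO) / (0.9 * nai + 0.1 * ki))

    i_cal = p[P_GCAL] * y[ICAL0] * (V - 63.0)
    i_pca = 1.0 * cai * cai / (0.25 + cai * cai)          # Km = 0.5 uM
    i_naca = (
        292.8
        / (87500.0 ** 3 + _NAO ** 3)
        / (1380.0 + _CAO)
        / (1.0 + 0.1 * np.exp((0.35 - 1.0) * vf))
        * (np.exp(0.35 * vf) * nai ** 3 * _CAO - np.exp((0.35 - 1.0) * vf) * _NAO ** 3 * cai)
    )
    e_can = 0.5 * _RTF * np.log(_CAO / cai)
    i_cab = 0.000367 * (V - e_can)
    i_na = p[P_GNA] * y[INA0 + 2] * (V - e_na)
    i_nab = 0.0026 * (V - e_na)
    sigma = (np.exp(_NAO / 67300.0) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * vf) + 0.0365 * sigma * np.exp(-vf))
    i_nak = (
        0.88 * f_nak / (1.0 + (21000.0 / nai) ** 1.5) * _KO / (_KO + 1500.0)
    )
    i_ktof = p[P_GKTOF] * y[ITOF0 + 3] * (V - e_k)
    i_ktos = p[P_GKTOS] * y[ITOS0 + 4] * (V - e_k)
    i_k1 = 0.2938 * _KO / (_KO + 210.0) * (V - e_k) / (1.0 + np.exp(0.0896 * (V - e_k)))
    i_ks = p[P_GKS] * (y[IKS0 + 15] + y[IKS0 + 16]) * (V - e_k)
    i_kur = p[P_GKUR] * y[IKUR0 + 4] * (V - e_k)
    i_kss = p[P_GKSS] * y[IAKSS] * (V - e_k)
    e_kr = _RTF * np.log((0.98 * _KO + 0.02 * _NAO) / (0.98 * ki + 0.02 * nai))
    i_kr = p[P_GKR] * y[IKR0 + 2] * (V - e_kr)
    o_clca = 0.2 / (1.0 + np.exp(-(V - 46.7) / 7.8))
    i_clca = 10.0 * o_clca * cai / (cai + 10.0) * (V - (-40.0))

    out[0] = i_cal
    out[1] = i_pca
    out[2] = i_naca
    out[3] = i_cab
    out[4] = i_na
    out[5] = i_nab
    out[6] = i_nak
    out[7] = i_ktof
    out[8] = i_ktos
    out[9] = i_k1
    out[10] = i_ks
    out[11] = i_kur
    out[12] = i_kss
    out[13] = i_kr
    out[14] = i_clca


@njit(cache=True)
def _currents(y, p):
    out = np.empty(15)
    _currents_into(y, p, out)
    return out


@njit(cache=True)
def _rhs_into(y, p, stim, dy, cur):
    """Time derivative of the full state, written into ``dy`` in place.

    ``stim`` in pA/pF, depolarizing > 0; ``cur`` is a length-15 scratch
    buffer that afterwards holds the current densities.
    """
    V = y[IV]
    cai = y[ICAI]
    cass = y[ICASS]
    cajsr = y[ICAJSR]
    cansr = y[ICANSR]

    _currents_into(y, p, cur)
    i_ion = cur.sum()
    # stimulus is depolarizing; internally an inward current -stim
    dy[IV] = -(i_ion - stim)

    # --- Ca2+ subsystem -----------------------------------------------------
    po1, po2, pc2 = y[IRYR_PO1], y[IRYR_PO2], y[IRYR_PC2]
    pc1 = 1.0 - po1 - po2 - pc2
    pryr = y[IPRYR]
    j_rel = 4.5 * (po1 + po2) * (cajsr - cass) * pryr
    j_tr = (cansr - cajsr) / 20.0
    j_xfer = (cass - cai) / 8.0
    j_leak = 1.74e-5 * (cansr - cai)
    j_up = 0.45 * cai * cai / (0.25 + cai * cai)
    d_ltrpn = 0.0327 * cai * (70.0 - y[ILTRPN]) - 0.0196 * y[ILTRPN]
    d_htrpn = 0.00237 * cai * (140.0 - y[IHTRPN]) - 3.2e-5 * y[IHTRPN]
    j_trpn = d_ltrpn + d_htrpn
    b_i = 1.0 / (1.0 + 50.0 * 0.238 / ((0.238 + cai) * (0.238 + cai)))
    b_ss = 1.0 / (1.0 + 50.0 * 0.238 / ((0.238 + cass) * (0.238 + cass)))
    b_jsr = 1.0 / (1.0 + 15000.0 * 800.0 / ((800.0 + cajsr) * (800.0 + cajsr)))
    conv = _ACAP_CM / (2.0 * _VMYO * _F)
    dy[ICAI] = b_i * (
        j_leak + j_xfer - j_up - j_trpn - (cur[3] - 2.0 * cur[2] + cur[1]) * conv
    )
    dy[ICASS] = b_ss * (
        j_rel * _VJSR / _VSS - j_xfer * _VMYO / _VSS - cur[0] * _ACAP_CM / (2.0 * _VSS * _F)
    )
    dy[ICAJSR] = b_jsr * (j_tr - j_rel)
    dy[ICANSR] = (j_up - j_leak) * _VMYO / _VNSR - j_tr * _VJSR / _VNSR
    dy[ILTRPN] = d_ltrpn
    dy[IHTRPN] = d_htrpn

    # RyR gating
    dy[IRYR_PO1] = (
        0.006075 * cass ** 4 * pc1 - 0.07125 * po1
        - 0.00405 * cass ** 3 * po1 + 0.965 * po2
        - 0.009 * po1 + 0.0008 * pc2
    )
    dy[IRYR_PO2] = 0.00405 * cass ** 3 * po1 - 0.965 * po2
    dy[IRYR_PC2] = 0.009 * po1 - 0.0008 * pc2
    dy[IPRYR] = -0.04 * pryr - 0.1 * (cur[0] / 7.0) * np.exp(-(V - 5.0) ** 2 / 648.0)

    # --- intracellular ion concentrations ----------------------------------
    convm = _ACAP_CM / (_VMYO * _F)
    dy[INAI] = -(cur[4] + cur[5] + 3.0 * cur[2] + 3.0 * cur[6]) * convm
    # stimulus charge is carried by K+ so long runs conserve charge
    dy[IKI] = -(
        cur[7] + cur[8] + cur[9] + cur[10] + cur[11] + cur[12] + cur[13]
        - 2.0 * cur[6] - stim
    ) * convm

    # --- L-type Ca2+ channel (7 integrated states, C1 by conservation) ------
    o_l = y[ICAL0 + 0]
    c2 = y[ICAL0 + 1]
    c3 = y[ICAL0 + 2]
    c4 = y[ICAL0 + 3]
    i1 = y[ICAL0 + 4]
    i2 = y[ICAL0 + 5]
    i3 = y[ICAL0 + 6]
    c1 = 1.0 - o_l - c2 - c3 - c4 - i1 - i2 - i3
    alpha = (
        0.4 * np.exp((V + 12.0) / 10.0)
        * (1.0 + 0.7 * np.exp(-(V + 40.0) ** 2 / 10.0) - 0.75 * np.exp(-(V + 20.0) ** 2 / 400.0))
        / (1.0 + 0.12 * np.exp((V + 12.0) / 10.0))
    )
    beta = 0.05 * np.exp(-(V + 12.0) / 13.0)
    gamma = 0.23324 * cass / (20.0 + cass)
    kpcf = 13.0 * (1.0 - np.exp(-(V + 14.5) ** 2 / 100.0))
    kpcb = 0.0005
    j12 = 4.0 * alpha * c1 - beta * c2
    j23 = 3.0 * alpha * c2 - 2.0 * beta * c3
    j34 = 2.0 * alpha * c3 - 3.0 * beta * c4
    j4o = alpha * c4 - 4.0 * beta * o_l
    j_oi1 = gamma * o_l - kpcb * i1
    j_oi2 = 0.001 * (kpcf * o_l - alpha * i2)
    j_c4i1 = 0.01 * (alpha * gamma * c4 - 4.0 * beta * kpcb * i1)
    j_c4i2 = 0.002 * (gamma * c4 - 4.0 * beta * i2)
    j_i1i3 = 0.001 * (kpcf * i1 - alpha * i3)
    j_i2i3 = gamma * i2 - kpcb * i3
    dy[ICAL0 + 0] = j4o - j_oi1 - j_oi2
    dy[ICAL0 + 1] = j12 - j23
    dy[ICAL0 + 2] = j23 - j34
    dy[ICAL0 + 3] = j34 - j4o - j_c4i1 - j_c4i2
    dy[ICAL0 + 4] = j_oi1 + j_c4i1 - j_i1i3
    dy[ICAL0 + 5] = j_oi2 + j_c4i2 - j_i2i3
    dy[ICAL0 + 6] = j_i1i3 + j_i2i3

    # --- fast Na+ channel ----------------------------------------------------
    cna2 = y[INA0 + 0]
    cna1 = y[INA0 + 1]
    ona = y[INA0 + 2]
    ifna = y[INA0 + 3]
    i1na = y[INA0 + 4]
    i2na = y[INA0 + 5]
    icna2 = y[INA0 + 6]
    icna3 = y[INA0 + 7]
    cna3 = 1.0 - cna2 - cna1 - ona - ifna - i1na - i2na - icna2 - icna3
    a11 = 3.802 / (0.1027 * np.exp(-(V + 2.5) / 17.0) + 0.20 * np.exp(-(V + 2.5) / 150.0))
    a12 = 3.802 / (0.1027 * np.exp(-(V + 2.5) / 15.0) + 0.23 * np.exp(-(V + 2.5) / 150.0))
    a13 = 3.802 / (0.1027 * np.exp(-(V + 2.5) / 12.0) + 0.25 * np.exp(-(V + 2.5) / 150.0))
    b11 = 0.1917 * np.exp(-(V + 2.5) / 20.3)
    b12 = 0.20 * np.exp(-(V - 2.5) / 20.3)
    b13 = 0.22 * np.exp(-(V - 7.5) / 20.3)
    a3 = 7.0e-7 * np.exp(-(V + 7.0) / 7.7)
    b3 = 0.0084 + 0.00002 * (V + 7.0)
    a2 = 1.0 / (0.188495 * np.exp(-(V + 7.0) / 16.6) + 0.393956)
    # The 0.1 factor bounds the Na+ window current in the -40..-10 mV range,
    # where the mouse plateau sits; without it repolarization stalls.
    b2 = 0.1 * a13 * a2 * a3 / (b13 * b3)
    a4 = a2 / 1000.0
    b4 = a3
    a5 = a2 / 95000.0
    b5 = a3 / 50.0
    j_c3c2 = a11 * cna3 - b11 * cna2
    j_c2c1 = a12 * cna2 - b12 * cna1
    j_c1o = a13 * cna1 - b13 * ona
    j_oif = a2 * ona - b2 * ifna
    j_ifi1 = a4 * ifna - b4 * i1na
    j_i1i2 = a5 * i1na - b5 * i2na
    j_ifc1 = a3 * ifna - b3 * cna1
    j_ic2c2 = a3 * icna2 - b3 * cna2
    j_ic3c3 = a3 * icna3 - b3 * cna3
    j_ic3ic2 = a11 * icna3 - b11 * icna2
    j_ic2if = a12 * icna2 - b12 * ifna
    dy[INA0 + 0] = j_c3c2 - j_c2c1 + j_ic2c2
    dy[INA0 + 1] = j_c2c1 - j_c1o + j_ifc1
    dy[INA0 + 2] = j_c1o - j_oif
    dy[INA0 + 3] = j_oif - j_ifi1 - j_ifc1 + j_ic2if
    dy[INA0 + 4] = j_ifi1 - j_i1i2
    dy[INA0 + 5] = j_i1i2
    dy[INA0 + 6] = j_ic3ic2 - j_ic2if - j_ic2c2
    dy[INA0 + 7] = -j_ic3ic2 - j_ic3c3

    # --- rapid delayed rectifier (mERG) --------------------------------------
    ck1 = y[IKR0 + 0]
    ck2 = y[IKR0 + 1]
    ok = y[IKR0 + 2]
    ik = y[IKR0 + 3]
    ck0 = 1.0 - ck1 - ck2 - ok - ik
    aa0 = 0.022348 * np.exp(0.01176 * V)
    ba0 = 0.047002 * np.exp(-0.0631 * V)
    aa1 = 0.013733 * np.exp(0.038198 * V)
    ba1 = 0.0000689 * np.exp(-0.04178 * V)
    ai = 0.090821 * np.exp(0.023391 * (V + 5.0))
    bi = 0.006497 * np.exp(-0.03268 * (V + 5.0))
    j01 = aa0 * ck0 - ba0 * ck1
    j12k = 0.023761 * ck1 - 0.036778 * ck2
    j2o = aa1 * ck2 - ba1 * ok
    j_oi = ai * ok - bi * ik
    dy[IKR0 + 0] = j01 - j12k
    dy[IKR0 + 1] = j12k - j2o
    dy[IKR0 + 2] = j2o - j_oi
    dy[IKR0 + 3] = j_oi

    # --- non-inactivating steady-state K+ current gate -----------------------
    ass = 1.0 / (1.0 + np.exp(-(V + 22.5) / 7.7))
    tau_kss = 39.3 * np.exp(-0.0862 * V) + 13.17
    dy[IAKSS] = (ass - y[IAKSS]) / tau_kss

    # --- Markov K+ channels ---------------------------------------------------
    rates.iktof_apply(
        V, p[P_CONC], p[_OFF_TOF:_OFF_TOS],
        p[P_KONC], p[P_KOFFC], p[P_KONO], p[P_KOFFO], p[P_KOFFC3], y, dy, ITOF0,
    )
    rates.iktos_apply(V, p[_OFF_TOS:_OFF_KUR], y, dy, ITOS0)
    rates.ikur_apply(V, p[_OFF_KUR:_OFF_KS], y, dy, IKUR0)
    rates.iks_apply(V, p[_OFF_KS:], y, dy, IKS0)


# ---------------------------------------------------------------------------
# Adaptive Dormand-Prince 4(5) integrator
# ---------------------------------------------------------------------------

@njit(cache=True)
def _advance(y, duration, stim, p, h0, rtol, atol, hmax):
    """Integrate ``y`` in place over ``duration`` ms at constant stimulus.

    Returns (next step size, status); status 0 = ok, 1 = step underflow,
    2 = non-finite state.
    """
    k1 = np.empty(NSTATES)
    k2 = np.empty(NSTATES)
    k3 = np.empty(NSTATES)
    k4 = np.empty(NSTATES)
    k5 = np.empty(NSTATES)
    k6 = np.empty(NSTATES)
    k7 = np.empty(NSTATES)
    yt = np.empty(NSTATES)
    ynew = np.empty(NSTATES)
    cur = np.empty(15)
    t = 0.0
    h = min(h0, duration)
    _rhs_into(y, p, stim, k1, cur)
    fresh_k1 = True
    while t < duration - 1e-12:
        if h < 1e-10:
            return h, 1
        if t + h > duration:
            h = duration - t
        if not fresh_k1:
            _rhs_into(y, p, stim, k1, cur)
            fresh_k1 = True
        for i in range(NSTATES):
            yt[i] = y[i] + h * 0.2 * k1[i]
        _rhs_into(yt, p, stim, k2, cur)
        for i in range(NSTATES):
            yt[i] = y[i] + h * (0.075 * k1[i] + 0.225 * k2[i])
        _rhs_into(yt, p, stim, k3, cur)
        for i in range(NSTATES):
            yt[i] = y[i] + h * ((44.0 / 45.0) * k1[i] - (56.0 / 15.0) * k2[i]
                                + (32.0 / 9.0) * k3[i])
        _rhs_into(yt, p, stim, k4, cur)
        for i in range(NSTATES):
            yt[i] = y[i] + h * ((19372.0 / 6561.0) * k1[i] - (25360.0 / 2187.0) * k2[i]
                                + (64448.0 / 6561.0) * k3[i] - (212.0 / 729.0) * k4[i])
        _rhs_into(yt, p, stim, k5, cur)
        for i in range(NSTATES):
            yt[i] = y[i] + h * ((9017.0 / 3168.0) * k1[i] - (355.0 / 33.0) * k2[i]
                                + (46732.0 / 5247.0) * k3[i] + (49.0 / 176.0) * k4[i]
                                - (5103.0 / 18656.0) * k5[i])
        _rhs_into(yt, p, stim, k6, cur)
        for i in range(NSTATES):
            ynew[i] = y[i] + h * ((35.0 / 384.0) * k1[i] + (500.0 / 1113.0) * k3[i]
                                  + (125.0 / 192.0) * k4[i] - (2187.0 / 6784.0) * k5[i]
                                  + (11.0 / 84.0) * k6[i])
        _rhs_into(ynew, p, stim, k7, cur)
        # weighted RMS of the embedded 4th/5th-order difference
        acc = 0.0
        ok = True
        for i in range(NSTATES):
            if not np.isfinite(ynew[i]):
                ok = False
                break
            e = h * ((71.0 / 57600.0) * k1[i] - (71.0 / 16695.0) * k3[i]
                     + (71.0 / 1920.0) * k4[i] - (17253.0 / 339200.0) * k5[i]
                     + (22.0 / 525.0) * k6[i] - (1.0 / 40.0) * k7[i])
            sc = atol + rtol * abs(ynew[i])
            acc += (e / sc) * (e / sc)
        if not ok:
            h *= 0.5
            fresh_k1 = True
            if h < 1e-10:
                return h, 2
            continue
        err = np.sqrt(acc / NSTATES)
        if err <= 1.0:
            t += h
            for i in range(NSTATES):
                y[i] = ynew[i]
                k1[i] = k7[i]    # FSAL: derivative at the accepted state
            fac = 5.0 if err == 0.0 else min(5.0, max(0.2, 0.9 * err ** -0.2))
            h = min(h * fac, hmax)
        else:
            h = max(h * max(0.2, 0.9 * err ** -0.2), 1e-10)
    return h, 0


class IntegrationError(RuntimeError):
    pass


@dataclass
class Solver:
    """Error-control settings for the whole-cell integrator."""

    rtol: float = 1e-6
    atol: float = 1e-8
    hmax: float = 1.0      # ms

    def advance(self, y: np.ndarray, duration: float, stim: float, p: np.ndarray,
                h0: float = 1e-3) -> float:
        h, status = _advance(y, duration, stim, p, h0, self.rtol, self.atol, self.hmax)
        if status != 0:
            self._diagnose(y, p, status)
        return h

    @staticmethod
    def _diagnose(y, p, status):
        names = []
        cur = np.asarray(_currents(y, p))
        for name, value in zip(CURRENT_NAMES, cur):
            if not np.isfinite(value):
                names.append(name)
        detail = f" non-finite currents: {names}" if names else ""
        kind = "step-size underflow" if status == 1 else "non-finite state"
        raise IntegrationError(f"integration aborted ({kind}).{detail}")


DEFAULT_SOLVER = Solver()

STIM_AMP = 60.0    # pA/pF, depolarizing
STIM_DUR = 0.5     # ms


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

def state_derivative(state: np.ndarray, t: float = 0.0, stimulus: float = 0.0,
                     params: np.ndarray | None = None) -> np.ndarray:
    """dy/dt of the assembled cell; ``stimulus`` is depolarizing in pA/pF."""
    if params is None:
        params = pack_params()
    state = np.asarray(state, dtype=float)
    if state.shape != (NSTATES,):
        raise ValueError(f"state must have shape ({NSTATES},)")
    dy = np.empty(NSTATES)
    _rhs_into(state, params, stimulus, dy, np.empty(15))
    if not np.all(np.isfinite(dy)):
        Solver._diagnose(state, params, 2)
    return dy


def occupancy_blocks(state: np.ndarray) -> dict[str, np.ndarray]:
    """The four Markov K+ occupancy blocks (each should sum to 1)."""
    return {
        "iktof": state[ITOF0:ITOF0 + 10],
        "iktos": state[ITOS0:ITOS0 + 9],
        "ikur": state[IKUR0:IKUR0 + 6],
        "iks": state[IKS0:IKS0 + 17],
    }


def check_state(state: np.ndarray, tol: float = 1e-6) -> None:
    """Assert occupancy conservation; never silently renormalizes."""
    for name, block in occupancy_blocks(state).items():
        s = float(block.sum())
        if abs(s - 1.0) > tol:
            raise AssertionError(f"{name} occupancy sums to {s!r} (|delta| > {tol})")


_REST_CACHE: dict = {}


def rest_state(variant: str = "endocardial", duration: float = 20000.0,
               solver: Solver = DEFAULT_SOLVER) -> np.ndarray:
    """Quiescent steady state, computed once per variant and cached."""
    key = (variant, round(duration))
    if key not in _REST_CACHE:
        p = pack_params(variant)
        y = initial_state()
        solver.advance(y, duration, 0.0, p, h0=1e-3)
        _REST_CACHE[key] = y
    return _REST_CACHE[key].copy()


def _beat_sample_times(bcl: float, fine_window: float = 60.0,
                       dt_fine: float = 0.05, dt_coarse: float = 0.5) -> np.ndarray:
    fine_end = min(fine_window, bcl)
    t_fine = np.arange(0.0, fine_end, dt_fine)
    t_coarse = np.arange(fine_end, bcl + 1e-9, dt_coarse)
    return np.concatenate([t_fine, t_coarse])


def record_interval(y: np.ndarray, params: np.ndarray, sample_times: np.ndarray,
                    stim_amp: float, stim_dur: float,
                    solver: Solver = DEFAULT_SOLVER) -> CellTrace:
    """Integrate one stimulus interval, sampling V and currents.

    The stimulus starts at t=0 of the interval. ``y`` is advanced in place.
    """
    n = len(sample_times)
    V = np.empty(n)
    cur = np.empty((n, len(CURRENT_NAMES)))
    h = 1e-3
    t_prev = 0.0
    for k, t_s in enumerate(sample_times):
        if t_s > t_prev:
            # split the advance at the stimulus edge
            if t_prev < stim_dur:
                t_mid = min(t_s, stim_dur)
                h = solver.advance(y, t_mid - t_prev, stim_amp, params, h)
                if t_s > t_mid:
                    h = solver.advance(y, t_s - t_mid, 0.0, params, h)
            else:
                h = solver.advance(y, t_s - t_prev, 0.0, params, h)
            t_prev = t_s
        V[k] = y[IV]
        cur[k] = _currents(y, params)
    currents = {name: cur[:, i].copy() for i, name in enumerate(CURRENT_NAMES)}
    return CellTrace(time_ms=sample_times.copy(), V_mV=V, currents=currents)


@dataclass
class PacingResult:
    """End state and final-beat trace of a steady pacing run."""

    state: np.ndarray
    trace: CellTrace
    converged: bool
    beats_run: int
    variant: str = ""
    bcl: float = 0.0
    drug: DrugSpec | None = None


def run_to_steady_pacing(
    variant: str = "endocardial",
    bcl: float = 1000.0,
    n_beats: int = 1000,
    drug: DrugSpec | None = None,
    converge_tol: float = 1e-4,
    min_beats: int = 5,
    stim_amp: float = STIM_AMP,
    stim_dur: float = STIM_DUR,
    solver: Solver = DEFAULT_SOLVER,
    y0: np.ndarray | None = None,
    conductance_overrides: dict | None = None,
) -> PacingResult:
    """Pace to steady state and record the final beat.

    Pacing stops early once the state vector at successive beat onsets
    changes by less than ``converge_tol`` in relative terms (the steady-state
    criterion), else after ``n_beats`` beats. The returned trace covers the
    last beat with fine sampling around the upstroke.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    p = pack_params(variant, drug, conductance_overrides)
    y = rest_state(variant, solver=solver) if y0 is None else y0.copy()
    h = 1e-3
    converged = False
    prev = y.copy()
    beats = 0
    # beat-to-beat change is judged on V, gating and Ca states; the very slow
    # Na+/K+ bulk drift would otherwise mask electrical steady state
    mask = np.ones(NSTATES, dtype=bool)
    mask[[INAI, IKI]] = False
    # floor the per-state scale at 1e-2 so vanishing occupancies do not
    # dominate the relative criterion
    scale = np.maximum(np.abs(prev), 1e-2)
    for beat in range(n_beats - 1):
        h = solver.advance(y, stim_dur, stim_amp, p, h)
        h = solver.advance(y, bcl - stim_dur, 0.0, p, h)
        beats += 1
        rel = np.max((np.abs(y - prev) / scale)[mask])
        if beat >= min_beats and rel < converge_tol:
            converged = True
            break
        prev[:] = y
        scale = np.maximum(np.abs(y), 1e-2)
    trace = record_interval(y, p, _beat_sample_times(bcl), stim_amp, stim_dur, solver)
    beats += 1
    check_state(y, tol=1e-5)
    return PacingResult(
        state=y, trace=trace, converged=converged, beats_run=beats,
        variant=variant, bcl=bcl, drug=drug,
    )
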
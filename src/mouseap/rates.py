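"""Voltage-dependent transition rates and generator matrices for the four
Markov K+ channel schemes.

Everything here is numba-compiled and shared between the introspectable
:class:`~mouseap.markov.MarkovScheme` layer and the whole-cell ODE
right-hand side, so channel kinetics have a single definition.

State orderings (fixed, used everywhere):

* I_Ktof  : C1, C2, C3, O, I1, I2, B1, B2, B3, BO      (10; B* are drug-bound)
* I_Ktos  : C1, C2, C3, C4, O, IN, INC, IC1, IC2       (9)
* I_Kur   : C1, C2, C3, C4, O, I                       (6)
* I_Ks    : C(n1,n2) zipper states (15), O1, O2        (17)

Activation ladders are Hodgkin-Huxley expansions of the corresponding
Bondarenko et al. (2004) gate rates; inactivation and drug rates are
calibrated to the channel phenotypes documented in
``params/PROVENANCE.md``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Parameter vector layouts (index -> name). YAML parameter files are loaded
# into flat float64 vectors in exactly this order.
# ---------------------------------------------------------------------------

IKTOF_PARAM_NAMES = (
    "act_a1", "act_a2",      # alpha_a = act_a1 * exp(act_a2 * (V + 30))
    "act_b1", "act_b2",      # beta_a  = act_b1 * exp(-act_b2 * (V + 30))
    "oi_base", "oi_amp", "oi_vh", "oi_k",   # O -> I1 sigmoid rate
    "io_a", "io_vref", "io_k",              # I1 -> O exponential recovery rate
    "ci_f", "ci_b",          # C3 <-> I1 (closed-state inactivation)
    "k12", "k21",            # I1 <-> I2 (deep inactivation)
)

IKTOS_PARAM_NAMES = (
    "act_vh", "act_k",       # per-subunit steady state midpoint/slope (mV)
    "tau_a", "tau_b", "tau_c",  # tau = tau_a * exp(-tau_b * V) + tau_c (ms)
    "kni", "knr",            # O <-> IN  (N-type, voltage-insensitive)
    "kcf", "kcb",            # O <-> IC1 (C-type)
    "k2f", "k2b",            # IC1 <-> IC2
    "kncf", "kncb",          # IN <-> INC (coupled C-type from N-type)
)

IKUR_PARAM_NAMES = (
    "act_vh", "act_k",
    "tau_a", "tau_b", "tau_c",
    "inact_vh", "inact_k",   # i_ss = 1 / (1 + exp((V + inact_vh) / inact_k))
    "tau_i0", "tau_i_amp",   # tau_i = tau_i0 - tau_i_amp / (1 + exp((V+inact_vh)/inact_k))
    "rec0",                  # residual I -> O rate giving incomplete inactivation
)

IKS_PARAM_NAMES = (
    "a1", "a2",   # alpha = a1 * exp(a2 * vf)     (vf = V*F/RT, dimensionless)
    "b1", "b2",   # beta  = b1 * exp(-b2 * vf)
    "g1", "g2",   # gamma = g1 * exp(g2 * vf)
    "d1", "d2",   # delta = d1 * exp(-d2 * vf)
    "theta",      # C15 -> O1 (voltage-independent)
    "e1", "e2",   # eta   = e1 * exp(-e2 * vf)    (O1 -> C15)
    "p1", "p2",   # psi   = p1 * exp(p2 * vf)     (O1 -> O2)
    "w1", "w2",   # omega = w1 * exp(-w2 * vf)    (O2 -> O1)
)

RT_OVER_F = 8.314 * 298.0 / 96.5

# I_Ks zipper bookkeeping: state k <-> (n1, n2), n1 subunits through the
# first sensor step only, n2 through both; n1 + n2 <= 4.
_IKS_N1 = []
_IKS_N2 = []
_IKS_LOOKUP = -np.ones((5, 5), dtype=np.int64)
for _n1 in range(5):
    for _n2 in range(5 - _n1):
        _IKS_LOOKUP[_n1, _n2] = len(_IKS_N1)
        _IKS_N1.append(_n1)
        _IKS_N2.append(_n2)
IKS_N1 = np.array(_IKS_N1, dtype=np.int64)
IKS_N2 = np.array(_IKS_N2, dtype=np.int64)
IKS_LOOKUP = _IKS_LOOKUP
IKS_N_CLOSED = 15
IKS_N_STATES = 17  # 15 closed + O1 + O2


# ---------------------------------------------------------------------------
# I_Ktof (Kv4.x) -- 3 closed, open, 2 inactivated, 4 drug-bound states
# ---------------------------------------------------------------------------

@njit(cache=True)
def iktof_alpha_a(V, p):
    return p[0] * np.exp(p[1] * (V + 30.0))


@njit(cache=True)
def iktof_beta_a(V, p):
    return p[2] * np.exp(-p[3] * (V + 30.0))


@njit(cache=True)
def iktof_k_oi(V, p):
    """Open-state inactivation rate, sigmoid in V."""
    return p[4] + p[5] / (1.0 + np.exp(-(V - p[6]) / p[7]))


@njit(cache=True)
def iktof_k_io(V, p):
    """Recovery rate I1 -> O, grows at hyperpolarized potentials."""
    return p[8] * np.exp(-(V - p[9]) / p[10])


@njit(cache=True)
def iktof_generator(V, conc_mM, p, kon_c, koff_c, kon_o, koff_o, koff_c3=-1.0):
    """10x10 generator for I_Ktof including both drug-bound extensions.

    ``kon_c``/``kon_o`` are association rate constants (per mM per ms); a
    mechanism is inert when its on-rate or the concentration is zero, in
    which case the dynamics on the 6 gating states reduce exactly to the
    unblocked scheme (bound states start empty and stay empty).
    ``koff_c3`` is the dissociation rate from the activated bound state B3
    (4-AP-like relief of block on depolarization); negative means equal to
    ``koff_c``.
    """
    if koff_c3 < 0.0:
        koff_c3 = koff_c
    aa = iktof_alpha_a(V, p)
    ba = iktof_beta_a(V, p)
    koi = iktof_k_oi(V, p)
    kio = iktof_k_io(V, p)
    cif = p[11]
    cib = p[12]
    k12 = p[13]
    k21 = p[14]
    Q = np.zeros((10, 10))
    # gating ladder C1-C2-C3-O (indices 0,1,2,3), multiplicities 3,2,1
    _add(Q, 0, 1, 3.0 * aa)
    _add(Q, 1, 0, ba)
    _add(Q, 1, 2, 2.0 * aa)
    _add(Q, 2, 1, 2.0 * ba)
    _add(Q, 2, 3, aa)
    _add(Q, 3, 2, 3.0 * ba)
    # inactivation O-I1-I2 (indices 3,4,5) and closed-state path C3-I1
    _add(Q, 3, 4, koi)
    _add(Q, 4, 3, kio)
    _add(Q, 4, 5, k12)
    _add(Q, 5, 4, k21)
    _add(Q, 2, 4, cif)
    _add(Q, 4, 2, cib)
    # closed-state block: C1,C2,C3 <-> B1,B2,B3 (indices 6,7,8)
    kc = kon_c * conc_mM
    for i in range(3):
        _add(Q, i, 6 + i, kc)
        _add(Q, 6 + i, i, koff_c3 if i == 2 else koff_c)
    # bound-ladder transitions mirror C1-C2-C3
    _add(Q, 6, 7, 3.0 * aa)
    _add(Q, 7, 6, ba)
    _add(Q, 7, 8, 2.0 * aa)
    _add(Q, 8, 7, 2.0 * ba)
    # open-state block: O <-> BO (index 9)
    _add(Q, 3, 9, kon_o * conc_mM)
    _add(Q, 9, 3, koff_o)
    return Q


@njit(cache=True)
def _add(Q, i, j, rate):
    """Transition i -> j at ``rate``; keeps columns summing to zero."""
    Q[j, i] += rate
    Q[i, i] -= rate


@njit(cache=True)
def iktof_apply(V, conc_mM, p, kon_c, koff_c, kon_o, koff_o, koff_c3, y, dy, off):
    """In-place derivative of the 10 I_Ktof states at y[off:off+10].

    Flux-conservative hand expansion of :func:`iktof_generator` (kept in
    lockstep by a unit test) used on the hot path of the whole-cell ODE.
    """
    if koff_c3 < 0.0:
        koff_c3 = koff_c
    aa = iktof_alpha_a(V, p)
    ba = iktof_beta_a(V, p)
    koi = iktof_k_oi(V, p)
    kio = iktof_k_io(V, p)
    c1, c2, c3 = y[off], y[off + 1], y[off + 2]
    o, i1, i2 = y[off + 3], y[off + 4], y[off + 5]
    b1, b2, b3, bo = y[off + 6], y[off + 7], y[off + 8], y[off + 9]
    kc = kon_c * conc_mM
    f12 = 3.0 * aa * c1 - ba * c2
    f23 = 2.0 * aa * c2 - 2.0 * ba * c3
    f3o = aa * c3 - 3.0 * ba * o
    foi1 = koi * o - kio * i1
    fi12 = p[13] * i1 - p[14] * i2
    fci = p[11] * c3 - p[12] * i1
    fb1 = kc * c1 - koff_c * b1
    fb2 = kc * c2 - koff_c * b2
    fb3 = kc * c3 - koff_c3 * b3
    g12 = 3.0 * aa * b1 - ba * b2
    g23 = 2.0 * aa * b2 - 2.0 * ba * b3
    fbo = kon_o * conc_mM * o - koff_o * bo
    dy[off] = -f12 - fb1
    dy[off + 1] = f12 - f23 - fb2
    dy[off + 2] = f23 - f3o - fci - fb3
    dy[off + 3] = f3o - foi1 - fbo
    dy[off + 4] = foi1 + fci - fi12
    dy[off + 5] = fi12
    dy[off + 6] = fb1 - g12
    dy[off + 7] = fb2 + g12 - g23
    dy[off + 8] = fb3 + g23
    dy[off + 9] = fbo


# ---------------------------------------------------------------------------
# I_Ktos (Kv1.4) -- 4 closed, open, N-type, coupled and C-type inactivation
# ---------------------------------------------------------------------------

@njit(cache=True)
def iktos_alpha_beta(V, p):
    ass = 1.0 / (1.0 + np.exp(-(V - p[0]) / p[1]))
    tau = p[2] * np.exp(-p[3] * V) + p[4]
    return ass / tau, (1.0 - ass) / tau


@njit(cache=True)
def iktos_generator(V, p):
    a, b = iktos_alpha_beta(V, p)
    kni, knr = p[5], p[6]
    kcf, kcb = p[7], p[8]
    k2f, k2b = p[9], p[10]
    kncf, kncb = p[11], p[12]
    Q = np.zeros((9, 9))
    # C1..C4 = 0..3, O = 4, IN = 5, INC = 6, IC1 = 7, IC2 = 8
    _add(Q, 0, 1, 4.0 * a)
    _add(Q, 1, 0, b)
    _add(Q, 1, 2, 3.0 * a)
    _add(Q, 2, 1, 2.0 * b)
    _add(Q, 2, 3, 2.0 * a)
    _add(Q, 3, 2, 3.0 * b)
    _add(Q, 3, 4, a)
    _add(Q, 4, 3, 4.0 * b)
    _add(Q, 4, 5, kni)   # N-type inactivation, voltage-insensitive
    _add(Q, 5, 4, knr)
    _add(Q, 5, 6, kncf)  # C-type inactivation of the N-inactivated channel
    _add(Q, 6, 5, kncb)
    _add(Q, 4, 7, kcf)   # C-type inactivation from the open state
    _add(Q, 7, 4, kcb)
    _add(Q, 7, 8, k2f)
    _add(Q, 8, 7, k2b)
    return Q


@njit(cache=True)
def iktos_apply(V, p, y, dy, off):
    """In-place derivative of the 9 I_Ktos states (mirrors iktos_generator)."""
    a, b = iktos_alpha_beta(V, p)
    c1, c2, c3, c4 = y[off], y[off + 1], y[off + 2], y[off + 3]
    o, i_n, i_nc, ic1, ic2 = y[off + 4], y[off + 5], y[off + 6], y[off + 7], y[off + 8]
    f12 = 4.0 * a * c1 - b * c2
    f23 = 3.0 * a * c2 - 2.0 * b * c3
    f34 = 2.0 * a * c3 - 3.0 * b * c4
    f4o = a * c4 - 4.0 * b * o
    fn = p[5] * o - p[6] * i_n
    fnc = p[11] * i_n - p[12] * i_nc
    fc = p[7] * o - p[8] * ic1
    fc2 = p[9] * ic1 - p[10] * ic2
    dy[off] = -f12
    dy[off + 1] = f12 - f23
    dy[off + 2] = f23 - f34
    dy[off + 3] = f34 - f4o
    dy[off + 4] = f4o - fn - fc
    dy[off + 5] = fn - fnc
    dy[off + 6] = fnc
    dy[off + 7] = fc - fc2
    dy[off + 8] = fc2


# ---------------------------------------------------------------------------
# I_Kur (Kv1.5) -- 4 closed, open, one inactivated state
# ---------------------------------------------------------------------------

@njit(cache=True)
def ikur_alpha_beta(V, p):
    ass = 1.0 / (1.0 + np.exp(-(V - p[0]) / p[1]))
    tau = p[2] * np.exp(-p[3] * V) + p[4]
    return ass / tau, (1.0 - ass) / tau


@njit(cache=True)
def ikur_k_oi(V, p):
    iss = 1.0 / (1.0 + np.exp((V + p[5]) / p[6]))
    tau = p[7] - p[8] / (1.0 + np.exp((V + p[5]) / p[6]))
    return (1.0 - iss) / tau


@njit(cache=True)
def ikur_k_io(V, p):
    iss = 1.0 / (1.0 + np.exp((V + p[5]) / p[6]))
    tau = p[7] - p[8] / (1.0 + np.exp((V + p[5]) / p[6]))
    # The residual recovery rate rec0 keeps steady-state inactivation
    # incomplete at depolarized potentials (Kv1.5 phenotype).
    return iss / tau + p[9]


@njit(cache=True)
def ikur_generator(V, p):
    a, b = ikur_alpha_beta(V, p)
    koi = ikur_k_oi(V, p)
    kio = ikur_k_io(V, p)
    Q = np.zeros((6, 6))
    # C1..C4 = 0..3, O = 4, I = 5
    _add(Q, 0, 1, 4.0 * a)
    _add(Q, 1, 0, b)
    _add(Q, 1, 2, 3.0 * a)
    _add(Q, 2, 1, 2.0 * b)
    _add(Q, 2, 3, 2.0 * a)
    _add(Q, 3, 2, 3.0 * b)
    _add(Q, 3, 4, a)
    _add(Q, 4, 3, 4.0 * b)
    _add(Q, 4, 5, koi)
    _add(Q, 5, 4, kio)
    return Q


@njit(cache=True)
def ikur_apply(V, p, y, dy, off):
    """In-place derivative of the 6 I_Kur states (mirrors ikur_generator)."""
    a, b = ikur_alpha_beta(V, p)
    koi = ikur_k_oi(V, p)
    kio = ikur_k_io(V, p)
    c1, c2, c3, c4, o, i = (y[off], y[off + 1], y[off + 2], y[off + 3],
                            y[off + 4], y[off + 5])
    f12 = 4.0 * a * c1 - b * c2
    f23 = 3.0 * a * c2 - 2.0 * b * c3
    f34 = 2.0 * a * c3 - 3.0 * b * c4
    f4o = a * c4 - 4.0 * b * o
    foi = koi * o - kio * i
    dy[off] = -f12
    dy[off + 1] = f12 - f23
    dy[off + 2] = f23 - f34
    dy[off + 3] = f34 - f4o
    dy[off + 4] = f4o - foi
    dy[off + 5] = foi


# ---------------------------------------------------------------------------
# I_Ks (KCNQ1/KCNE1) -- Silva-Rudy two-step sensor zipper, two open states
# ---------------------------------------------------------------------------

@njit(cache=True)
def iks_rates(V, p):
    vf = V / RT_OVER_F
    alpha = p[0] * np.exp(p[1] * vf)
    beta = p[2] * np.exp(-p[3] * vf)
    gamma = p[4] * np.exp(p[5] * vf)
    delta = p[6] * np.exp(-p[7] * vf)
    theta = p[8]
    eta = p[9] * np.exp(-p[10] * vf)
    psi = p[11] * np.exp(p[12] * vf)
    omega = p[13] * np.exp(-p[14] * vf)
    return alpha, beta, gamma, delta, theta, eta, psi, omega


@njit(cache=True)
def iks_generator(V, p):
    alpha, beta, gamma, delta, theta, eta, psi, omega = iks_rates(V, p)
    Q = np.zeros((IKS_N_STATES, IKS_N_STATES))
    for k in range(IKS_N_CLOSED):
        n1 = IKS_N1[k]
        n2 = IKS_N2[k]
        rest = 4 - n1 - n2
        if rest > 0:
            _add(Q, k, IKS_LOOKUP[n1 + 1, n2], rest * alpha)
        if n1 > 0:
            _add(Q, k, IKS_LOOKUP[n1 - 1, n2], n1 * beta)
            _add(Q, k, IKS_LOOKUP[n1 - 1, n2 + 1], n1 * gamma)
        if n2 > 0:
            _add(Q, k, IKS_LOOKUP[n1 + 1, n2 - 1], n2 * delta)
    c_last = IKS_LOOKUP[0, 4]
    o1 = IKS_N_CLOSED
    o2 = IKS_N_CLOSED + 1
    _add(Q, c_last, o1, theta)
    _add(Q, o1, c_last, eta)
    _add(Q, o1, o2, psi)
    _add(Q, o2, o1, omega)
    return Q


@njit(cache=True)
def iks_apply(V, p, y, dy, off):
    """In-place derivative of the 17 I_Ks states (mirrors iks_generator)."""
    alpha, beta, gamma, delta, theta, eta, psi, omega = iks_rates(V, p)
    for k in range(IKS_N_STATES):
        dy[off + k] = 0.0
    for k in range(IKS_N_CLOSED):
        n1 = IKS_N1[k]
        n2 = IKS_N2[k]
        rest = 4 - n1 - n2
        pk = y[off + k]
        if rest > 0:
            j = IKS_LOOKUP[n1 + 1, n2]
            r = rest * alpha * pk
            dy[off + k] -= r
            dy[off + j] += r
        if n1 > 0:
            j = IKS_LOOKUP[n1 - 1, n2]
            r = n1 * beta * pk
            dy[off + k] -= r
            dy[off + j] += r
            j = IKS_LOOKUP[n1 - 1, n2 + 1]
            r = n1 * gamma * pk
            dy[off + k] -= r
            dy[off + j] += r
        if n2 > 0:
            j = IKS_LOOKUP[n1 + 1, n2 - 1]
            r = n2 * delta * pk
            dy[off + k] -= r
            dy[off + j] += r
    c_last = off + IKS_LOOKUP[0, 4]
    o1 = off + IKS_N_CLOSED
    o2 = o1 + 1
    f_open = theta * y[c_last] - eta * y[o1]
    f_oo = psi * y[o1] - omega * y[o2]
    dy[c_last] -= f_open
    dy[o1] += f_open - f_oo
    dy[o2] += f_oo
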
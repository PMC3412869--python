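"""The four Markov K+ channel models and their current equations.

Each channel is exposed two ways, backed by the same compiled rate
functions in :mod:`mouseap.rates`:

* as a :class:`~mouseap.markov.MarkovScheme` for clamp protocols,
  stationary analysis and drug augmentation, and
* inside the whole-cell ODE right-hand side (:mod:`mouseap.cell`).

Current for every channel is ohmic: I = G * p_open * (V - E_K), where
p_open sums the occupancy of all conducting states (I_Ks has two).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from . import rates
from .constants import KI_DEFAULT, KO, nernst_k
from .markov import MarkovScheme, Transition

VARIANTS = ("endocardial", "epicardial", "septal")

IKTOF_STATES = ("C1", "C2", "C3", "O", "I1", "I2", "B1", "B2", "B3", "BO")
IKTOS_STATES = ("C1", "C2", "C3", "C4", "O", "IN", "INC", "IC1", "IC2")
IKUR_STATES = ("C1", "C2", "C3", "C4", "O", "I")
IKS_STATES = tuple(
    f"C{k + 1}" for k in range(rates.IKS_N_CLOSED)
) + ("O1", "O2")

_PARAM_NAMES = {
    "iktof": rates.IKTOF_PARAM_NAMES,
    "iktos": rates.IKTOS_PARAM_NAMES,
    "ikur": rates.IKUR_PARAM_NAMES,
    "iks": rates.IKS_PARAM_NAMES,
}


@functools.lru_cache(maxsize=None)
def _load_yaml(name: str) -> dict:
    with resources.files("mouseap.params").joinpath(f"{name}.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_rate_vector(channel: str) -> np.ndarray:
    """Flat rate-constant vector in the order defined in :mod:`mouseap.rates`."""
    doc = _load_yaml(channel)
    names = _PARAM_NAMES[channel]
    return np.array([float(doc["rates"][n]["value"]) for n in names])


def load_conductance(channel: str, variant: str) -> float:
    if variant not in VARIANTS:
        raise ValueError(f"unknown cell variant {variant!r}; expected one of {VARIANTS}")
    doc = _load_yaml(channel)
    return float(doc["conductance"][variant]["value"])


@dataclass(frozen=True)
class ChannelParams:
    """Whole-cell conductance, rate constants and Nernst inputs for one channel."""

    name: str
    conductance: float          # mS/uF
    rate_constants: tuple      # flat vector, order per rates.<CHANNEL>_PARAM_NAMES
    ko: float = KO              # uM
    ki: float = KI_DEFAULT      # uM

    def __post_init__(self):
        if self.conductance < 0:
            raise ValueError("conductance must be >= 0")

    @property
    def e_k(self) -> float:
        return nernst_k(self.ko, self.ki)

    @property
    def rate_vector(self) -> np.ndarray:
        return np.asarray(self.rate_constants, dtype=float)


def channel_params(channel: str, variant: str = "epicardial") -> ChannelParams:
    return ChannelParams(
        name=channel,
        conductance=load_conductance(channel, variant),
        rate_constants=tuple(load_rate_vector(channel)),
    )


def channel_current(params: ChannelParams, open_prob, V):
    """I = G * p_open * (V - E_K) in pA/pF.

    ``open_prob`` is the summed occupancy of the conducting states; for
    schemes with more than one open state pass the sum.
    """
    open_prob = np.asarray(open_prob, dtype=float)
    if np.any(open_prob < -1e-9) or np.any(open_prob > 1 + 1e-9):
        raise ValueError("open_prob must lie in [0, 1]")
    return params.conductance * open_prob * (np.asarray(V, dtype=float) - params.e_k)


# ---------------------------------------------------------------------------
# Scheme construction. Transitions are discovered from the compiled
# generator matrices (probed at several voltages/doses), so the declarative
# layer cannot drift from the simulated kinetics.
# ---------------------------------------------------------------------------

_PROBES = (-100.0, -40.0, 0.0, 40.0)


def _scheme_from_generator(name, states, conducting, genfn, transition_labels=None):
    n = len(states)
    edges: set[tuple[int, int]] = set()
    for V in _PROBES:
        Q = genfn(V, 1.0)
        for i in range(n):
            for j in range(n):
                if i != j and Q[j, i] > 0:
                    edges.add((i, j))
    transitions = []
    for i, j in sorted(edges):
        def rate(Vm, conc, _i=i, _j=j):
            return genfn(Vm, conc)[_j, _i]

        transitions.append(Transition(states[i], states[j], rate))
    return MarkovScheme(
        name=name,
        states=tuple(states),
        transitions=tuple(transitions),
        conducting_states=frozenset(conducting),
    )


def build_iktof_scheme(
    rate_vector: np.ndarray | None = None,
    kon_c: float = 0.0,
    koff_c: float = 0.0,
    kon_o: float = 0.0,
    koff_o: float = 0.0,
    koff_c3: float = -1.0,
    name: str = "iktof",
) -> MarkovScheme:
    """The I_Ktof gating scheme (3 closed, open, 2 inactivated states).

    With all drug rates zero this returns the 6-state unblocked scheme.
    Drug-augmented variants are normally built through
    :func:`mouseap.drugs.augment_scheme`.
    """
    p = load_rate_vector("iktof") if rate_vector is None else np.asarray(rate_vector)
    include_c = kon_c > 0 or koff_c > 0
    include_o = kon_o > 0 or koff_o > 0
    n = 6 + (3 if include_c else 0) + (1 if include_o else 0)
    if include_o and not include_c:
        states = IKTOF_STATES[:6] + ("BO",)
    else:
        states = IKTOF_STATES[:n]

    def genfn(V, conc):
        Q = rates.iktof_generator(V, conc, p, kon_c, koff_c, kon_o, koff_o, koff_c3)
        if n == 10:
            return Q
        if include_o and not include_c:
            keep = [0, 1, 2, 3, 4, 5, 9]
            return Q[np.ix_(keep, keep)]
        return Q[:n, :n]

    return _scheme_from_generator(name, states, {"O"}, genfn)


def build_iktos_scheme(rate_vector: np.ndarray | None = None) -> MarkovScheme:
    p = load_rate_vector("iktos") if rate_vector is None else np.asarray(rate_vector)
    return _scheme_from_generator(
        "iktos", IKTOS_STATES, {"O"}, lambda V, c: rates.iktos_generator(V, p)
    )


def build_ikur_scheme(rate_vector: np.ndarray | None = None) -> MarkovScheme:
    p = load_rate_vector("ikur") if rate_vector is None else np.asarray(rate_vector)
    return _scheme_from_generator(
        "ikur", IKUR_STATES, {"O"}, lambda V, c: rates.ikur_generator(V, p)
    )


def build_iks_scheme(rate_vector: np.ndarray | None = None) -> MarkovScheme:
    p = load_rate_vector("iks") if rate_vector is None else np.asarray(rate_vector)
    return _scheme_from_generator(
        "iks", IKS_STATES, {"O1", "O2"}, lambda V, c: rates.iks_generator(V, p)
    )


_BUILDERS = {
    "iktof": build_iktof_scheme,
    "iktos": build_iktos_scheme,
    "ikur": build_ikur_scheme,
    "iks": build_iks_scheme,
}


def build_scheme(channel: str) -> MarkovScheme:
    try:
        return _BUILDERS[channel]()
    except KeyError:
        raise ValueError(f"unknown channel {channel!r}") from None
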
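"""Generic continuous-time Markov chain machinery for ion-channel gating.

A channel is a :class:`MarkovScheme`: a set of named conformational states,
a list of transitions with voltage- (and possibly ligand-) dependent rate
laws, and a subset of conducting states. The scheme is realized numerically
as a generator matrix Q acting on column occupancy vectors, dp/dt = Q p,
with columns summing to zero so that total occupancy is conserved.

Rate laws are callables ``rate(V_mV, conc_mM) -> per-ms`` and must be
non-negative and finite over the physiological voltage range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm

RateLaw = Callable[[float, float], float]


class SchemeError(ValueError):
    """Raised for ill-formed Markov schemes (unknown states, disconnected graphs...)."""


@dataclass(frozen=True)
class Transition:
    src: str
    dst: str
    rate: RateLaw
    label: str = ""

    def __repr__(self) -> str:  # rate callables are noise in reprs
        tag = f" [{self.label}]" if self.label else ""
        return f"Transition({self.src}->{self.dst}{tag})"


@dataclass(frozen=True)
class MarkovScheme:
    """One channel's gating scheme.

    Parameters
    ----------
    name
        Channel identifier, e.g. ``"iktof"``.
    states
        Ordered state labels. Closed states conventionally ``C1..``, open
        ``O``, inactivated ``I..``, drug-bound ``B..``.
    transitions
        Directed transitions with per-ms rate laws. Reverse transitions are
        listed explicitly; nothing is inferred.
    conducting_states
        Non-empty subset of ``states`` that carry current. For schemes with
        several open states the open probability is their occupancy sum.
    """

    name: str
    states: tuple[str, ...]
    transitions: tuple[Transition, ...]
    conducting_states: frozenset[str]

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise SchemeError(f"{self.name}: duplicate state labels")
        known = set(self.states)
        for tr in self.transitions:
            if tr.src not in known or tr.dst not in known:
                raise SchemeError(
                    f"{self.name}: transition {tr.src}->{tr.dst} references unknown state"
                )
            if tr.src == tr.dst:
                raise SchemeError(f"{self.name}: self-transition on {tr.src}")
        if not self.conducting_states:
            raise SchemeError(f"{self.name}: conducting_states is empty")
        if not self.conducting_states <= known:
            raise SchemeError(f"{self.name}: conducting_states not a subset of states")
        if not self._connected():
            raise SchemeError(f"{self.name}: transition graph is not connected")

    def _connected(self) -> bool:
        adj: dict[str, set[str]] = {s: set() for s in self.states}
        for tr in self.transitions:
            adj[tr.src].add(tr.dst)
            adj[tr.dst].add(tr.src)
        seen = {self.states[0]}
        stack = [self.states[0]]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return len(seen) == len(self.states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)

    @property
    def conducting_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.states) if s in self.conducting_states])


def transition_matrix(scheme: MarkovScheme, V: float, drug_conc: float = 0.0) -> np.ndarray:
    """Generator matrix Q (per-ms) at membrane potential ``V`` mV.

    Convention: Q acts on column occupancy vectors, dp/dt = Q @ p; entry
    Q[j, i] (i != j) is the rate from state i to state j, and each column
    sums to zero, so d(sum p)/dt = 0 identically.
    """
    if not np.isfinite(V):
        raise ValueError("V must be finite")
    if drug_conc < 0:
        raise ValueError("drug_conc must be >= 0")
    n = scheme.n_states
    Q = np.zeros((n, n))
    idx = {s: i for i, s in enumerate(scheme.states)}
    for tr in scheme.transitions:
        r = float(tr.rate(V, drug_conc))
        if not np.isfinite(r) or r < 0:
            raise ValueError(
                f"{scheme.name}: rate {tr.src}->{tr.dst} = {r!r} at V={V} mV is invalid"
            )
        i, j = idx[tr.src], idx[tr.dst]
        Q[j, i] += r
        Q[i, i] -= r
    return Q


def steady_state_occupancy(
    scheme: MarkovScheme, V: float, drug_conc: float = 0.0
) -> np.ndarray:
    """Stationary occupancy at fixed voltage: the normalized nullspace of Q.

    The transition graph must be connected (checked at scheme construction),
    which makes the stationary distribution unique.
    """
    Q = transition_matrix(scheme, V, drug_conc)
    n = scheme.n_states
    # Solve Q p = 0 subject to sum(p) = 1 as an augmented least-squares system.
    A = np.vstack([Q, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = np.linalg.norm(Q @ p)
    if resid > 1e-8:
        raise RuntimeError(f"{scheme.name}: stationary solve residual {resid:.2e}")
    if p.min() < -1e-9:
        raise RuntimeError(f"{scheme.name}: negative stationary occupancy {p.min():.2e}")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def occupancy_derivative(
    scheme: MarkovScheme, occupancy: np.ndarray, V: float, drug_conc: float = 0.0
) -> np.ndarray:
    """dp/dt = Q p for one channel at instantaneous voltage ``V``."""
    occupancy = np.asarray(occupancy, dtype=float)
    if occupancy.shape != (scheme.n_states,):
        raise ValueError(
            f"occupancy has shape {occupancy.shape}, scheme has {scheme.n_states} states"
        )
    return transition_matrix(scheme, V, drug_conc) @ occupancy


def propagate_fixed_voltage(
    scheme: MarkovScheme,
    p0: np.ndarray,
    V: float,
    duration: float,
    dt_out: float,
    drug_conc: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy trajectory under an ideal voltage clamp at fixed ``V``.

    Uses the matrix exponential of the (constant) generator between output
    samples, which is exact for a time-homogeneous chain. Returns
    ``(times, occupancies)`` with occupancies of shape (n_t, n_states);
    times start at ``dt_out`` (the caller holds the t=0 sample).
    """
    Q = transition_matrix(scheme, V, drug_conc)
    n_out = max(1, int(round(duration / dt_out)))
    prop = expm(Q * dt_out)
    out = np.empty((n_out, scheme.n_states))
    p = np.asarray(p0, dtype=float).copy()
    for k in range(n_out):
        p = prop @ p
        out[k] = p
    times = dt_out * np.arange(1, n_out + 1)
    return times, out


def simulate_piecewise_clamp(
    scheme: MarkovScheme,
    segments: Sequence[tuple[float, float]],
    dt_out: float = 0.5,
    drug_conc: float = 0.0,
    p0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ideal-clamp simulation over piecewise-constant command voltage.

    ``segments`` is a list of ``(duration_ms, V_mV)``. The initial occupancy
    defaults to the stationary distribution at the first segment's voltage
    (i.e. the holding potential). Returns ``(time, V, occupancy)`` arrays
    including the t=0 sample.
    """
    if p0 is None:
        p0 = steady_state_occupancy(scheme, segments[0][1], drug_conc)
    times = [np.array([0.0])]
    volts = [np.array([segments[0][1]])]
    occs = [np.asarray(p0, dtype=float)[None, :]]
    t0 = 0.0
    p = np.asarray(p0, dtype=float)
    for dur, V in segments:
        t, occ = propagate_fixed_voltage(scheme, p, V, dur, dt_out, drug_conc)
        times.append(t0 + t)
        volts.append(np.full_like(t, V))
        occs.append(occ)
        p = occ[-1]
        t0 += t[-1]
    return np.concatenate(times), np.concatenate(volts), np.vstack(occs)
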
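"""State-dependent block of I_Ktof by idealized drugs.

Two mechanisms are modeled, both strictly non-conducting when bound and
competitive (a bound channel cannot gate into the states the drug occupies):

* ``closed_state`` ("drug C", 4-AP-like): binds the three closed states,
  adding bound states B1, B2, B3 that interconvert with the same
  activation-ladder rates as C1-C3. Block accumulates at rest and must
  unbind before the channel can open, so the peak current is suppressed
  while late current is spared: apparent activation and decay slow down.
* ``open_state`` ("drug O", quinidine-like): binds the open state, adding a
  single bound state BO. Block develops during depolarization, so current
  decay accelerates and the time-integral of the current is suppressed more
  than the peak.

Association rates scale linearly with concentration (kon * [D]);
dissociation is concentration-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .channels import _load_yaml
from .markov import MarkovScheme, SchemeError, Transition
from .trace import ChannelTrace

MECHANISMS = ("closed_state", "open_state")


@dataclass(frozen=True)
class DrugSpec:
    """An idealized I_Ktof blocker: mechanism, dose and binding rates."""

    mechanism: str
    concentration: float        # mM
    kon: float                  # 1/(mM*ms), per target state
    koff: float                 # 1/ms
    koff_depol: float | None = None
    """Dissociation rate from the activated bound state B3 (closed-state
    mechanism only). 4-AP-like block is relieved on depolarization: slow
    unbinding from the resting bound states, fast from B3. ``None`` means
    equal to ``koff``."""

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"unknown drug mechanism {self.mechanism!r}; expected one of {MECHANISMS}"
            )
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0 mM")
        if self.kon < 0 or self.koff < 0:
            raise ValueError("binding rates must be >= 0")
        if self.koff_depol is not None and self.koff_depol < 0:
            raise ValueError("binding rates must be >= 0")

    @property
    def koff_b3(self) -> float:
        return self.koff if self.koff_depol is None else self.koff_depol

    @classmethod
    def drug_c(cls, concentration: float, **overrides) -> "DrugSpec":
        """The closed-state blocker at ``concentration`` mM."""
        doc = _load_yaml("drugs")["drug_c"]
        spec = cls(
            mechanism="closed_state",
            concentration=concentration,
            kon=float(doc["kon"]["value"]),
            koff=float(doc["koff"]["value"]),
            koff_depol=float(doc["koff_depol"]["value"]),
        )
        return replace(spec, **overrides) if overrides else spec

    @classmethod
    def drug_o(cls, concentration: float, **overrides) -> "DrugSpec":
        """The open-state blocker at ``concentration`` mM."""
        doc = _load_yaml("drugs")["drug_o"]
        spec = cls(
            mechanism="open_state",
            concentration=concentration,
            kon=float(doc["kon"]["value"]),
            koff=float(doc["koff"]["value"]),
        )
        return replace(spec, **overrides) if overrides else spec

    @classmethod
    def from_name(cls, name: str, concentration: float, **overrides) -> "DrugSpec":
        key = name.strip().lower()
        if key in ("c", "drug_c", "closed_state"):
            return cls.drug_c(concentration, **overrides)
        if key in ("o", "drug_o", "open_state"):
            return cls.drug_o(concentration, **overrides)
        raise ValueError(f"unknown drug {name!r}")

    def at(self, concentration: float) -> "DrugSpec":
        return replace(self, concentration=concentration)


def augment_scheme(base: MarkovScheme, drug: DrugSpec) -> MarkovScheme:
    """Extend a gating scheme with the drug-bound states of ``drug``.

    All base states and transitions are preserved unchanged; bound states
    are non-conducting. Association rate laws are ``kon * [D]`` into each
    bound state; for the closed-state mechanism the bound states mirror the
    transitions among their partner closed states.
    """
    if drug.mechanism == "closed_state":
        targets = [s for s in base.states if s.startswith("C")]
        if len(targets) != 3:
            raise SchemeError(
                f"closed-state block needs exactly three closed states; "
                f"{base.name} has {len(targets)}"
            )
        bound = {c: f"B{i + 1}" for i, c in enumerate(targets)}
    else:
        targets = sorted(base.conducting_states)
        if len(targets) != 1:
            raise SchemeError(
                f"open-state block needs exactly one open state; "
                f"{base.name} has {len(targets)} conducting states"
            )
        bound = {targets[0]: "BO"}

    transitions = list(base.transitions)
    last_closed = targets[-1]
    for target, bname in bound.items():
        transitions.append(
            Transition(target, bname, lambda V, c, k=drug.kon: k * c, label="bind")
        )
        koff = (
            drug.koff_b3
            if drug.mechanism == "closed_state" and target == last_closed
            else drug.koff
        )
        transitions.append(
            Transition(bname, target, lambda V, c, k=koff: k, label="unbind")
        )
    if drug.mechanism == "closed_state":
        # bound ladder mirrors the closed-state ladder, same rate laws
        tset = set(bound)
        for tr in base.transitions:
            if tr.src in tset and tr.dst in tset:
                transitions.append(
                    Transition(bound[tr.src], bound[tr.dst], tr.rate, label="bound-ladder")
                )

    return MarkovScheme(
        name=f"{base.name}+{drug.mechanism}",
        states=base.states + tuple(bound[t] for t in targets),
        transitions=tuple(transitions),
        conducting_states=base.conducting_states,
    )


def _metric(trace: ChannelTrace, mode: str) -> float:
    if mode == "peak":
        return float(np.max(trace.current))
    if mode == "area":
        return float(np.trapezoid(trace.current, trace.time_ms))
    raise ValueError(f"unknown mode {mode!r}; expected 'peak' or 'area'")


def fraction_blocked(control: ChannelTrace, drugged: ChannelTrace, mode: str) -> float:
    """Normalized reduction 1 - metric_drug / metric_control.

    ``mode`` is ``"peak"`` (max current) or ``"area"`` (time-integral of the
    current over the pulse). Both traces must come from the identical
    protocol; the control metric must be positive.
    """
    m_control = _metric(control, mode)
    if m_control <= 0:
        raise ValueError(f"control {mode} metric is {m_control}; block undefined")
    return 1.0 - _metric(drugged, mode) / m_control
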
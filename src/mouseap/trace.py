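"""Time-series containers for channel-level and cell-level simulations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ChannelTrace:
    """A voltage-clamp simulation of one channel in isolation.

    ``occupancy`` has shape (n_t, n_states); ``current`` is the current
    density in pA/pF carried by the conducting states.
    """

    time_ms: np.ndarray
    V_mV: np.ndarray
    occupancy: np.ndarray
    current: np.ndarray
    states: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ms": self.time_ms, "V_mV": self.V_mV}
        for i, s in enumerate(self.states):
            data[f"p_{s}"] = self.occupancy[:, i]
        data["current_pA_per_pF"] = self.current
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CellTrace:
    """A whole-cell simulation: membrane potential plus per-current densities."""

    time_ms: np.ndarray
    V_mV: np.ndarray
    currents: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ms": self.time_ms, "V_mV": self.V_mV}
        for name, arr in self.currents.items():
            data[name] = arr
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
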
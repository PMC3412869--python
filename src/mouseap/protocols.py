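"""Stimulation and clamp protocols as declarative, reusable specifications.

Voltage-clamp protocols run a single channel in isolation under an ideal
clamp (the membrane ODE is disabled and V follows the command exactly);
pacing protocols run the whole cell. Defaults reproduce the standard
characterization set: double-pulse availability, steady-state BCL scans
over {80..3000} ms, S1-S2 restitution with S2 intervals 40-300 ms, and
log-spaced dose-response grids from 1 uM to 10 mM.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import cell, markov, metrics
from .channels import build_iktof_scheme, build_scheme, channel_params
from .drugs import DrugSpec, augment_scheme, fraction_blocked
from .trace import ChannelTrace

BCL_SET = (80.0, 100.0, 200.0, 300.0, 400.0, 500.0, 800.0, 1000.0, 2000.0, 3000.0)
S2_SET = tuple(float(x) for x in range(40, 301, 10))
DOSE_GRID = tuple(float(x) for x in np.logspace(-3, 1, 13))   # mM; 1 uM..10 mM, 3/decade
S2_MIN, S2_MAX = 40.0, 300.0


@dataclass
class ProtocolSpec:
    """A clamp or pacing schedule with its stimulus definition.

    ``segments`` is a list of ``(duration_ms, command_mV)`` for clamp kinds
    or ignored for pacing kinds, which use ``bcl``/``n_beats`` (and
    ``s1_bcl``/``s2_intervals`` for restitution).
    """

    kind: str
    segments: tuple = ()
    stim_amp: float = cell.STIM_AMP
    stim_dur: float = cell.STIM_DUR
    bcl: float = 1000.0
    n_beats: int = 1000
    bcls: tuple = BCL_SET
    s1_bcl: float = 1000.0
    s2_intervals: tuple = S2_SET
    doses: tuple = DOSE_GRID

    _KINDS = ("voltage_clamp", "paced_train", "s1s2", "bcl_scan", "dose_scan")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        self.segments = tuple((float(d), float(v)) for d, v in self.segments)
        for d, _ in self.segments:
            if d <= 0:
                raise ValueError("segment durations must be > 0")
        self.s2_intervals = tuple(float(x) for x in self.s2_intervals)
        if self.kind == "s1s2":
            for s2 in self.s2_intervals:
                if not S2_MIN <= s2 <= S2_MAX:
                    raise ValueError(f"S1-S2 interval {s2} outside [{S2_MIN}, {S2_MAX}] ms")
        self.bcls = tuple(float(x) for x in self.bcls)
        self.doses = tuple(float(x) for x in self.doses)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        return cls(**d)


# ---------------------------------------------------------------------------
# Channel-level clamp
# ---------------------------------------------------------------------------

def clamp_channel(
    channel: str,
    segments,
    variant: str = "epicardial",
    drug: DrugSpec | None = None,
    dt_out: float = 0.25,
) -> ChannelTrace:
    """Simulate one channel under an ideal piecewise-constant clamp.

    The initial occupancy is the stationary distribution at the first
    segment's (holding) potential, including drug binding when present.
    """
    if channel == "iktof" and drug is not None:
        scheme = augment_scheme(build_iktof_scheme(), drug)
        conc = drug.concentration
    else:
        scheme = build_scheme(channel)
        conc = 0.0
    par = channel_params(channel, variant)
    t, V, occ = markov.simulate_piecewise_clamp(scheme, segments, dt_out=dt_out, drug_conc=conc)
    popen = occ[:, scheme.conducting_indices].sum(axis=1)
    current = np.asarray(par.conductance * popen * (V - par.e_k))
    return ChannelTrace(time_ms=t, V_mV=V, occupancy=occ, current=current, states=scheme.states)


BLOCK_CLAMP = ((20.0, -70.0), (500.0, 50.0))   # hold -70 mV, 500 ms test to +50 mV


def double_pulse_iv(
    channel: str = "iktof",
    variant: str = "epicardial",
    hold: float = -80.0,
    p1_voltages=tuple(range(-100, 51, 20)),
    p1_dur: float = 500.0,
    p2_voltage: float = 50.0,
    p2_dur: float = 500.0,
    drug: DrugSpec | None = None,
    dt_out: float = 0.25,
):
    """Double-pulse protocol: P1 activation I-V and P2 availability.

    Returns ``(table, traces)`` where the table has one row per P1 voltage
    with the P1 peak current (activation) and the P2 peak current
    (availability after P1); traces maps P1 voltage to the full
    ChannelTrace. Single-pulse activation protocols are the special case
    ``p2_dur=0``.
    """
    rows = []
    traces = {}
    for v1 in p1_voltages:
        segments = [(20.0, hold), (p1_dur, float(v1))]
        if p2_dur > 0:
            segments.append((p2_dur, p2_voltage))
        tr = clamp_channel(channel, segments, variant=variant, drug=drug, dt_out=dt_out)
        p1_win = (tr.time_ms > 20.0) & (tr.time_ms <= 20.0 + p1_dur)
        p1_peak = float(np.max(np.abs(tr.current[p1_win])) * np.sign(
            tr.current[p1_win][np.argmax(np.abs(tr.current[p1_win]))]))
        p2_peak = float(np.max(tr.current[tr.time_ms > 20.0 + p1_dur])) if p2_dur > 0 else np.nan
        rows.append({"P1_mV": float(v1), "P1_peak": p1_peak, "P2_peak": p2_peak})
        traces[float(v1)] = tr
    return pd.DataFrame(rows), traces


# ---------------------------------------------------------------------------
# Whole-cell pacing scans
# ---------------------------------------------------------------------------

_APD_COLS = ("apd30", "apd50", "apd75", "apd90")


def _apd_row(trace) -> dict:
    aset = metrics.apd_set(trace)
    # a genuine AP overshoots; graded responses stay well below this
    captured = (aset.peak_V - aset.resting_V_reference) > 40.0
    row = {c: getattr(aset, c) if captured else np.nan for c in _APD_COLS}
    row.update(
        peak_V=aset.peak_V, dvdt_max=aset.dvdt_max, captured=captured,
    )
    return row


def bcl_scan(
    variant: str = "endocardial",
    drug: DrugSpec | None = None,
    bcls=BCL_SET,
    n_beats: int = 1000,
    solver: cell.Solver = cell.DEFAULT_SOLVER,
) -> pd.DataFrame:
    """Steady-state APD versus basic cycle length.

    One row per BCL with APD30/50/75/90 of the final beat, capture and
    convergence flags. Failed captures are flagged, not dropped.
    """
    rows = []
    for bcl in bcls:
        res = cell.run_to_steady_pacing(
            variant, bcl=bcl, n_beats=n_beats, drug=drug, solver=solver
        )
        row = {"variant": variant, "BCL_ms": bcl,
               "dose_mM": 0.0 if drug is None else drug.concentration,
               "mechanism": "" if drug is None else drug.mechanism}
        row.update(_apd_row(res.trace))
        row.update(converged=res.converged, beats_run=res.beats_run)
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_to_control(scan: pd.DataFrame, control: pd.DataFrame) -> pd.DataFrame:
    """Per-BCL APD ratios drug/control (the relative APD-BCL relationship)."""
    merged = scan.merge(control[["BCL_ms", *_APD_COLS]], on="BCL_ms",
                        suffixes=("", "_control"))
    for c in _APD_COLS:
        merged[f"rel_{c}"] = merged[c] / merged[f"{c}_control"]
    return merged


def s1s2_restitution(
    variant: str = "endocardial",
    drug: DrugSpec | None = None,
    s1_bcl: float = 1000.0,
    s2_intervals=S2_SET,
    n_beats: int = 1000,
    record_ms: float = 150.0,
    solver: cell.Solver = cell.DEFAULT_SOLVER,
) -> pd.DataFrame:
    """S1-S2 restitution: APDs and amplitude of a premature S2 beat.

    A conditioning S1 train is paced to steady state once; each S2 interval
    restarts from the cached end-of-train state, delivers one more S1 beat
    and then the S2 stimulus at the given coupling interval. When S2 fails
    to elicit an action potential the amplitude is still recorded and the
    APDs are flagged absent (NaN).
    """
    for s2 in s2_intervals:
        if not S2_MIN <= s2 <= S2_MAX:
            raise ValueError(f"S1-S2 interval {s2} outside [{S2_MIN}, {S2_MAX}] ms")
    train = cell.run_to_steady_pacing(
        variant, bcl=s1_bcl, n_beats=n_beats, drug=drug, solver=solver
    )
    p = cell.pack_params(variant, drug)
    s1_row = {"variant": variant, "S1S2_ms": np.nan, "beat": "S1",
              "dose_mM": 0.0 if drug is None else drug.concentration,
              "mechanism": "" if drug is None else drug.mechanism}
    s1_row.update(_apd_row(train.trace))
    rows = [s1_row]
    for s2 in s2_intervals:
        y = train.state.copy()
        # one more S1 beat, truncated at the S2 coupling interval
        solver.advance(y, cell.STIM_DUR, train.trace.meta.get("stim_amp", cell.STIM_AMP), p)
        solver.advance(y, s2 - cell.STIM_DUR, 0.0, p)
        sample = cell._beat_sample_times(record_ms)
        tr = cell.record_interval(y, p, sample, cell.STIM_AMP, cell.STIM_DUR, solver)
        row = {"variant": variant, "S1S2_ms": s2, "beat": "S2",
               "dose_mM": 0.0 if drug is None else drug.concentration,
               "mechanism": "" if drug is None else drug.mechanism}
        row.update(_apd_row(tr))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dose-response scans
# ---------------------------------------------------------------------------

def clamp_block_response(
    mechanism: str,
    doses=DOSE_GRID,
    mode: str = "area",
    variant: str = "epicardial",
    refine: bool = True,
) -> metrics.DoseResponse:
    """Clamp-level dose-response of I_Ktof block (hold -70, test +50 mV).

    ``mode`` selects the peak-current or current-area metric. The half-max
    dose is found by monotone interpolation on the grid plus bisection
    refinement in log dose.
    """
    control = clamp_channel("iktof", BLOCK_CLAMP, variant=variant)

    def response(dose: float) -> float:
        drug = DrugSpec.from_name(mechanism, dose)
        tr = clamp_channel("iktof", BLOCK_CLAMP, variant=variant, drug=drug)
        return fraction_blocked(control, tr, mode)

    resp = np.array([response(d) for d in doses])
    d_half, monotone = metrics.half_max_dose(
        doses, resp, refine=response if refine else None
    )
    if not monotone:
        import warnings

        warnings.warn(f"{mechanism} {mode} block is not monotone on the dose grid")
    fit = metrics.fit_boltzmann(doses, np.clip(resp, 0, 1))
    return metrics.DoseResponse(
        doses=np.asarray(doses, dtype=float), responses=resp,
        metric=f"{mode}_block", half_max_dose=d_half, fit=fit, monotone=monotone,
    )


def apd_prolongation_response(
    mechanism: str,
    variant: str = "endocardial",
    doses=DOSE_GRID,
    bcl: float = 1000.0,
    n_beats: int = 1000,
    level: int = 50,
    refine: bool = True,
    solver: cell.Solver = cell.DEFAULT_SOLVER,
) -> metrics.DoseResponse:
    """Relative APD prolongation vs dose, normalized to full I_Ktof block.

    The reference states are the drug-free cell and the cell with I_Ktof
    conductance set to zero (the maximum-prolongation limit); the response
    at each dose is (APD_drug - APD_control)/(APD_block - APD_control) at
    the chosen repolarization level, paced at the given BCL.
    """
    control = cell.run_to_steady_pacing(variant, bcl=bcl, n_beats=n_beats, solver=solver)
    full = cell.run_to_steady_pacing(
        variant, bcl=bcl, n_beats=n_beats, solver=solver,
        conductance_overrides={"GKtof": 0.0},
    )
    apd_c = metrics.apd(control.trace, level)
    apd_f = metrics.apd(full.trace, level)

    def response(dose: float) -> float:
        drug = DrugSpec.from_name(mechanism, dose)
        res = cell.run_to_steady_pacing(
            variant, bcl=bcl, n_beats=n_beats, drug=drug, solver=solver
        )
        return metrics.relative_prolongation(metrics.apd(res.trace, level), apd_c, apd_f)

    resp = np.array([response(d) for d in doses])
    d_half, monotone = metrics.half_max_dose(
        doses, resp, refine=response if refine else None
    )
    if not monotone:
        import warnings

        warnings.warn(f"{mechanism} APD{level} prolongation not monotone on the dose grid")
    return metrics.DoseResponse(
        doses=np.asarray(doses, dtype=float), responses=resp,
        metric=f"apd{level}_prolongation", half_max_dose=d_half, monotone=monotone,
    )


def dose_scan(variant, mechanism, doses=DOSE_GRID, metric: str = "area",
              **kwargs) -> metrics.DoseResponse:
    """Dispatch to the clamp-level (peak/area) or AP-level dose-response."""
    if metric in ("peak", "area"):
        return clamp_block_response(mechanism, doses=doses, mode=metric,
                                    variant=variant, **kwargs)
    if metric == "apd50_prolongation":
        return apd_prolongation_response(mechanism, variant=variant, doses=doses,
                                         **kwargs)
    raise ValueError(f"unknown dose-scan metric {metric!r}")
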
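"""Scalar summaries: APD at arbitrary repolarization levels, block
fractions, Boltzmann dose-response fits, and use-dependence classification.

APD conventions: the action potential duration at level x (APDx) is the
interval from the time of maximal upstroke velocity, (dV/dt)max, to the
time at which V has repolarized by x% of the excursion from the
pre-stimulus (per-beat diastolic) potential to the peak. Crossing times are
linearly interpolated between samples; if the threshold is crossed more
than once the first crossing after the peak counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

from .trace import CellTrace


@dataclass
class APDSet:
    """APDs and upstroke descriptors of one action potential (ms, mV)."""

    apd30: float
    apd50: float
    apd75: float
    apd90: float
    dvdt_max: float
    upstroke_time: float
    peak_V: float
    resting_V_reference: float

    def level(self, lev: int) -> float:
        return {30: self.apd30, 50: self.apd50, 75: self.apd75, 90: self.apd90}[lev]


def apd(trace: CellTrace, level: float, stim_window: float = 10.0) -> float:
    """APD at ``level`` percent repolarization for a single-AP trace.

    The trace must start at the stimulus onset of the beat to be measured.
    Returns NaN when the repolarization threshold is never crossed within
    the trace (e.g. failed capture), mirroring the flagged-absent
    convention of the summary tables.
    """
    if not 0 < level < 100:
        raise ValueError("level must be in (0, 100)")
    t = np.asarray(trace.time_ms, dtype=float)
    V = np.asarray(trace.V_mV, dtype=float)
    v_ref = V[0]  # pre-stimulus diastolic potential of this beat
    # (dV/dt)max restricted to a window after the stimulus to avoid artifacts
    dvdt = np.gradient(V, t)
    win = t <= t[0] + stim_window
    iu = int(np.argmax(np.where(win, dvdt, -np.inf)))
    t_up = t[iu]
    ipk = int(np.argmax(V))
    v_pk = V[ipk]
    thr = v_pk - (level / 100.0) * (v_pk - v_ref)
    below = np.nonzero(V[ipk:] <= thr)[0]
    if len(below) == 0:
        return math.nan
    j = ipk + below[0]
    if j == 0 or V[j] == V[j - 1]:
        t_cross = t[j]
    else:
        t_cross = t[j - 1] + (thr - V[j - 1]) * (t[j] - t[j - 1]) / (V[j] - V[j - 1])
    return t_cross - t_up


def apd_set(trace: CellTrace, stim_window: float = 10.0) -> APDSet:
    """APD30/50/75/90 plus upstroke descriptors for one beat."""
    t = np.asarray(trace.time_ms, dtype=float)
    V = np.asarray(trace.V_mV, dtype=float)
    dvdt = np.gradient(V, t)
    win = t <= t[0] + stim_window
    iu = int(np.argmax(np.where(win, dvdt, -np.inf)))
    return APDSet(
        apd30=apd(trace, 30, stim_window),
        apd50=apd(trace, 50, stim_window),
        apd75=apd(trace, 75, stim_window),
        apd90=apd(trace, 90, stim_window),
        dvdt_max=float(dvdt[iu]),
        upstroke_time=float(t[iu]),
        peak_V=float(V.max()),
        resting_V_reference=float(V[0]),
    )


def relative_prolongation(apd_drug: float, apd_control: float, apd_full_block: float) -> float:
    """APD prolongation normalized to that of complete I_Ktof block."""
    denom = apd_full_block - apd_control
    if denom <= 0:
        raise ValueError(
            "full-block APD must exceed control APD for normalized prolongation"
        )
    return (apd_drug - apd_control) / denom


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------

def _boltzmann(logd, rmax, logd_half, slope):
    return rmax / (1.0 + np.exp((logd_half - logd) / slope))


@dataclass
class BoltzmannFit:
    r_max: float
    d_half: float      # mM
    slope: float       # decades
    residual_norm: float

    def __call__(self, dose):
        return _boltzmann(np.log10(np.asarray(dose, dtype=float)),
                          self.r_max, np.log10(self.d_half), self.slope)


@dataclass
class DoseResponse:
    """A dose grid with measured responses and the derived potency numbers."""

    doses: np.ndarray           # mM
    responses: np.ndarray       # fraction of maximal effect
    metric: str = ""
    half_max_dose: float = float("nan")
    fit: BoltzmannFit | None = None
    monotone: bool = True


def fit_boltzmann(doses, responses) -> BoltzmannFit:
    """Least-squares Boltzmann (log-logistic) fit on log10 dose.

    r(d) = r_max / (1 + exp((log d_half - log d)/s)). Requires at least four
    points with responses in [0, 1]. Raises if the optimizer fails.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(doses) < 4:
        raise ValueError("need at least 4 dose points")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if np.any((responses < -1e-9) | (responses > 1 + 1e-9)):
        raise ValueError("responses must lie in [0, 1]")
    logd = np.log10(doses)
    rmax0 = max(responses.max(), 1e-3)
    half0 = logd[int(np.argmin(np.abs(responses - rmax0 / 2)))]
    try:
        popt, _ = curve_fit(
            _boltzmann, logd, responses, p0=(rmax0, half0, 0.5),
            bounds=([1e-6, logd.min() - 3, 0.01], [1.5, logd.max() + 3, 5.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Boltzmann fit did not converge: {exc}") from exc
    resid = float(np.linalg.norm(_boltzmann(logd, *popt) - responses))
    return BoltzmannFit(r_max=float(popt[0]), d_half=float(10 ** popt[1]),
                        slope=float(popt[2]), residual_norm=resid)


def half_max_dose(doses, responses, refine=None, tol_log=0.004):
    """Dose at half-maximal response by monotone log-interpolation.

    ``refine``, if given, is a callable dose -> response used for bisection
    refinement of the interpolated crossing to ``tol_log`` in log10 dose
    (about +/-1%). Returns (dose, monotone_flag); the flag is False when the
    response grid is not non-decreasing (the crossing of half-max is still
    reported, taken at the first attainment).
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    order = np.argsort(doses)
    doses, responses = doses[order], responses[order]
    monotone = bool(np.all(np.diff(responses) >= -1e-9))
    target = responses.max() / 2.0
    above = np.nonzero(responses >= target)[0]
    i = int(above[0])
    if i == 0:
        return float(doses[0]), monotone
    lo, hi = doses[i - 1], doses[i]
    rlo, rhi = responses[i - 1], responses[i]
    logd = np.log10(lo) + (target - rlo) * (np.log10(hi) - np.log10(lo)) / (rhi - rlo)
    if refine is not None:
        llo, lhi = np.log10(lo), np.log10(hi)
        while lhi - llo > tol_log:
            mid = 0.5 * (llo + lhi)
            if refine(10 ** mid) >= target:
                lhi = mid
            else:
                llo = mid
        logd = 0.5 * (llo + lhi)
    return float(10 ** logd), monotone


# ---------------------------------------------------------------------------
# Use-dependence classification
# ---------------------------------------------------------------------------

def use_dependence_index(bcl_ms, relative_apd, flat_tol: float = 0.005):
    """Classify the BCL trend of drug-induced relative APD change.

    Relative APD here is APD(drug)/APD(control) at matched BCL. A positive
    monotone trend with BCL (drug more effective at slow rates) is reverse
    use dependence; a negative trend is use dependence. Non-monotone curves
    are ``mixed`` and the BCL at the extremum is reported as change point.

    Returns (label, change_point_bcl_or_None).
    """
    bcl = np.asarray(bcl_ms, dtype=float)
    rel = np.asarray(relative_apd, dtype=float)
    if len(bcl) < 3:
        raise ValueError("need at least 3 BCLs")
    order = np.argsort(bcl)
    bcl, rel = bcl[order], rel[order]
    if rel.max() - rel.min() < flat_tol:
        return "neutral", None
    rho = spearmanr(bcl, rel).statistic
    if rho >= 0.8:
        return "reverse_use_dependent", None
    if rho <= -0.8:
        return "use_dependent", None
    # no dominant rank trend: report the location of the extremum
    iext = int(np.argmax(rel)) if rho < 0 else int(np.argmin(rel))
    return "mixed", float(bcl[iext])
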
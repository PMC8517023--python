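"""Voltage-clamp analysis: leak estimation and subtraction, current density,
G-V construction, Boltzmann and activation-tau fitting, and VSP decay ratios.

The conductance-voltage relation is built from steady-state leak-subtracted
step currents, G(V) = I_ss / (V - E_K), normalised to its maximum, and fit
with the Boltzmann form

    G/G_max = 1 / (1 + exp((V1/2 - V) / k)),

with k > 0 for a conductance that rises with depolarization.  All fits are
deterministic: fixed initialisation (V1/2 at the voltage nearest half
activation, k = 8 mV) and a gradient-norm convergence flag instead of any
stochastic restart.  PIP2-depletion sensitivity is summarised as the ratio
of the current at the end of a 10-s depolarizing step (mean of the final
100 ms) over the peak current after step onset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .ephys_synth import E_K_DEFAULT, Sweep, SweepSet, boltzmann


@dataclass(frozen=True)
class LeakParams:
    g_leak: float       # nS
    e_leak: float       # mV


@dataclass
class GVCurve:
    voltages: np.ndarray        # mV
    current: np.ndarray         # steady-state leak-subtracted pA
    conductance: np.ndarray     # nS
    g_norm: np.ndarray          # G / G_max


@dataclass
class BoltzmannFit:
    v_half: float
    k: float
    rss: float
    converged: bool

    def predict(self, v: np.ndarray) -> np.ndarray:
        return boltzmann(v, self.v_half, self.k)


@dataclass
class TauFit:
    tau: float                  # ms; nan when flagged
    amplitude: float
    baseline: float
    rising: bool
    converged: bool


@dataclass
class DecayResult:
    table: pd.DataFrame         # columns: voltage_mV, ratio, peak_pA, flagged

    def ratio_at(self, v: float) -> float:
        row = self.table[np.isclose(self.table["voltage_mV"], v)]
        if row.empty:
            raise KeyError(v)
        return float(row["ratio"].iloc[0])


def estimate_leak(sweeps: SweepSet, method: str = "reference_step",
                  reference: Optional[SweepSet] = None,
                  channel_free_segments: Sequence[int] = (0, 1)) -> LeakParams:
    """Linear (ohmic) leak parameters.

    ``reference_step``: fits I = g*(V - E) through the mean currents of the
    channel-free segments of each sweep (e.g. the holding segment and the
    brief -60 mV step of a VSP protocol, where the channel is shut).
    ``reference_cellline``: same linear fit on the main-step currents of a
    channel-free reference sweep set (untransfected / GFP-only cells).
    """
    if method == "reference_step":
        pts_v, pts_i = [], []
        for sw in sweeps.sweeps:
            for seg in channel_free_segments:
                level, _, _ = sw.segments[seg]
                sl = sw.segment_slice(seg)
                pts_v.append(level)
                pts_i.append(float(sw.current[sl].mean()))
    elif method == "reference_cellline":
        if reference is None:
            raise ValueError("reference_cellline requires a reference sweep set")
        pts_v, pts_i = [], []
        for sw in reference.sweeps:
            seg = sw.main_segment()
            sl = sw.segment_slice(seg)
            pts_v.append(sw.segments[seg][0])
            pts_i.append(float(sw.current[sl].mean()))
    else:
        raise ValueError(f"unknown leak method {method!r}")
    v = np.asarray(pts_v)
    i = np.asarray(pts_i)
    if np.unique(v).size < 2:
        raise ValueError("need currents at >= 2 distinct voltages for a leak fit")
    g, b = np.polyfit(v, i, 1)      # I = g V + b
    e = -b / g if abs(g) > 1e-12 else 0.0
    return LeakParams(g_leak=float(g), e_leak=float(e))


def leak_subtract(sweeps: SweepSet, leak: LeakParams) -> SweepSet:
    """Subtract g_leak * (V(t) - E_leak) pointwise from every sweep."""
    out = []
    for sw in sweeps.sweeps:
        corrected = sw.current - leak.g_leak * (sw.voltage - leak.e_leak)
        out.append(Sweep(times=sw.times.copy(), current=corrected,
                         voltage=sw.voltage.copy(),
                         segments=list(sw.segments)))
    return SweepSet(protocol=sweeps.protocol, sweeps=out,
                    capacitance=sweeps.capacitance,
                    metadata=dict(sweeps.metadata, leak_subtracted=True))


def leak_subtract_and_density(sweeps: SweepSet, leak: LeakParams,
                              c_m: Optional[float] = None
                              ) -> tuple[SweepSet, pd.DataFrame]:
    """Leak-subtracted traces plus peak current density (pA/pF) per step."""
    c_m = sweeps.capacitance if c_m is None else c_m
    if c_m <= 0:
        raise ValueError("capacitance must be positive")
    subtracted = leak_subtract(sweeps, leak)
    rows = []
    for sw in subtracted.sweeps:
        seg = sw.main_segment()
        sl = sw.segment_slice(seg)
        peak = float(sw.current[sl].max())
        rows.append({"voltage_mV": sw.segments[seg][0], "peak_pA": peak,
                     "density_pA_per_pF": peak / c_m})
    return subtracted, pd.DataFrame(rows)


def gv_curve(subtracted: SweepSet, e_k: float = E_K_DEFAULT,
             ss_frac: float = 0.1) -> GVCurve:
    """Steady-state G-V relation from leak-subtracted sweeps.

    G(V) = mean current over the final ``ss_frac`` of the main step divided
    by the driving force (V - E_K), normalised by the maximum over voltages.
    """
    voltages, currents = [], []
    for sw in subtracted.sweeps:
        seg = sw.main_segment()
        level, t0, t1 = sw.segments[seg]
        if np.isclose(level, e_k):
            raise ZeroDivisionError(
                f"step voltage {level} mV equals E_K; driving force vanishes")
        sl = sw.segment_slice(seg)
        n = sl.stop - sl.start
        tail = slice(sl.stop - max(int(round(ss_frac * n)), 1), sl.stop)
        voltages.append(level)
        currents.append(float(sw.current[tail].mean()))
    v = np.asarray(voltages)
    i = np.asarray(currents)
    g = i / (v - e_k)
    g_max = g.max()
    if g_max <= 0:
        raise ValueError("non-positive maximal conductance")
    return GVCurve(voltages=v, current=i, conductance=g, g_norm=g / g_max)


def fit_boltzmann(gv: GVCurve | tuple[np.ndarray, np.ndarray]) -> BoltzmannFit:
    """Least-squares Boltzmann fit of normalised conductance.

    Initialisation: V1/2 at the voltage whose G/G_max is nearest 0.5,
    k = 8 mV.  The convergence flag requires a gradient norm < 1e-8;
    non-convergence is flagged, never raised.
    """
    if isinstance(gv, GVCurve):
        v, y = gv.voltages, gv.g_norm
    else:
        v, y = np.asarray(gv[0], dtype=float), np.asarray(gv[1], dtype=float)
    if v.size < 4:
        raise ValueError("need >= 4 voltage points to fit a Boltzmann")
    x0 = np.array([v[np.argmin(np.abs(y - 0.5))], 8.0])

    def resid(x):
        return boltzmann(v, x[0], x[1]) - y

    res = least_squares(resid, x0, gtol=1e-14, xtol=1e-14, ftol=1e-14)
    grad_norm = float(np.linalg.norm(res.grad, ord=np.inf))
    return BoltzmannFit(v_half=float(res.x[0]), k=float(res.x[1]),
                        rss=float(2.0 * res.cost),
                        converged=bool(res.success and grad_norm < 1e-8))


def fit_activation_tau(times: np.ndarray, current: np.ndarray,
                       fit_window: tuple[float, float] = (0.1, 1.0)
                       ) -> TauFit:
    """Single-exponential activation fit A*(1 - exp(-t/tau)) + B.

    ``fit_window`` is fractional within the provided step trace (default
    10%-100%, skipping any residual fast component).  A trace that does not
    rise over the window is flagged, not raised.
    """
    times = np.asarray(times, dtype=float)
    current = np.asarray(current, dtype=float)
    n = times.size
    i0, i1 = int(fit_window[0] * n), int(fit_window[1] * n)
    t = times[i0:i1] - times[i0]
    y = current[i0:i1]
    m = max(len(y) // 10, 1)
    rising = y[-m:].mean() > y[:m].mean() + 1e-12
    if not rising:
        return TauFit(tau=float("nan"), amplitude=0.0,
                      baseline=float(y.mean()), rising=False, converged=False)
    span = y[-m:].mean() - y[:m].mean()
    x0 = np.array([span, (t[-1] - t[0]) / 5.0, y[:m].mean()])

    def resid(x):
        return x[0] * (1.0 - np.exp(-t / x[1])) + x[2] - y

    res = least_squares(resid, x0, gtol=1e-14, xtol=1e-14, ftol=1e-14)
    return TauFit(tau=float(res.x[1]), amplitude=float(res.x[0]),
                  baseline=float(res.x[2]), rising=True,
                  converged=bool(res.success))


def decay_ratio(vsp_sweeps: SweepSet, end_window_ms: float = 100.0
                ) -> DecayResult:
    """Per-voltage I(end)/I(peak) over the long depolarizing segment.

    I(end) is the mean of the final ``end_window_ms``; the peak is the
    maximum after step onset.  Sweeps with a non-positive peak are flagged.
    """
    rows = []
    for sw in vsp_sweeps.sweeps:
        seg = sw.main_segment()
        level, t0, t1 = sw.segments[seg]
        sl = sw.segment_slice(seg)
        cur = sw.current[sl]
        t = sw.times[sl]
        peak = float(cur.max())
        end = float(cur[t >= t1 - end_window_ms].mean())
        flagged = peak <= 0
        rows.append({"voltage_mV": level,
                     "ratio": end / peak if not flagged else float("nan"),
                     "peak_pA": peak, "flagged": flagged})
    return DecayResult(table=pd.DataFrame(rows))
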
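"""Synthetic whole-cell voltage-clamp sweeps for a Kv7-like channel.

The channel is a single, non-inactivating first-order gate:

    dp/dt = (p_inf(V) - p) / tau_act(V),
    p_inf(V) = 1 / (1 + exp((V1/2 - V) / k)),

solved exactly (exponential relaxation) on each constant-voltage segment,
with the gate state carried across segments.  The recorded current is

    I(t) = g_max * p(t) * s(t) * (V - E_K) + g_leak * (V - E_leak) + noise,

in pA with conductances in nS and voltages in mV.  s(t) is an optional
PIP2-depletion factor: during a VSP-style depolarizing step the conductance
scales by exp(-t / tau_dep(V)), fully resetting between sweeps (the
inter-sweep interval regenerates PIP2).  Capacitive transients are not
modelled; current is continuous within segments but may jump at segment
boundaries.

The default reversal potential E_K = -84 mV follows the Nernst potential at
room temperature for 140 mM internal / 5.4 mM external K+.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError

E_K_DEFAULT = -84.0     # mV


def boltzmann(v: np.ndarray | float, v_half: float, k: float):
    """Steady-state activation 1 / (1 + exp((V1/2 - V) / k))."""
    return 1.0 / (1.0 + np.exp((v_half - np.asarray(v, dtype=float)) / k))


@dataclass(frozen=True)
class VoltageProtocol:
    """Sweep family: per sweep an ordered list of (level mV, duration ms)
    segments, all sampled at ``sample_interval`` ms."""

    holding: float
    sweeps: tuple[tuple[tuple[float, float], ...], ...]
    sample_interval: float = 1.0

    def __post_init__(self):
        for sweep in self.sweeps:
            for level, dur in sweep:
                if dur <= 0:
                    raise ConfigurationError("segment durations must be > 0")
                n = dur / self.sample_interval
                if abs(n - round(n)) > 1e-9:
                    raise ConfigurationError(
                        "sample interval must divide every segment duration")

    @classmethod
    def activation(cls, v_min: float = -100.0, v_max: float = 20.0,
                   dv: float = 10.0, step_ms: float = 1500.0,
                   tail_mv: float = 0.0, tail_ms: float = 300.0,
                   holding: float = -80.0, sample_interval: float = 1.0
                   ) -> "VoltageProtocol":
        """1.5-s steps from -100 to +20 mV in 10-mV increments followed by a
        300-ms tail at 0 mV, from a -80 mV holding potential."""
        levels = np.arange(v_min, v_max + dv / 2, dv)
        return cls(holding=holding, sweeps=tuple(
            ((float(v), step_ms), (tail_mv, tail_ms)) for v in levels),
            sample_interval=sample_interval)

    @classmethod
    def vsp(cls, v_min: float = -20.0, v_max: float = 100.0, dv: float = 20.0,
            step_ms: float = 10000.0, holding: float = -70.0,
            leak_mv: float = -60.0, leak_ms: float = 100.0,
            sample_interval: float = 1.0) -> "VoltageProtocol":
        """10-s depolarizations in 20-mV steps from -20 to +100 mV, each
        preceded by a brief -60 mV step used for linear-leak estimation."""
        levels = np.arange(v_min, v_max + dv / 2, dv)
        return cls(holding=holding, sweeps=tuple(
            ((holding, leak_ms), (leak_mv, leak_ms), (float(v), step_ms))
            for v in levels), sample_interval=sample_interval)

    def step_levels(self) -> list[float]:
        """Level of the main (longest) segment of each sweep."""
        return [max(sweep, key=lambda seg: seg[1])[0] for sweep in self.sweeps]


TauSpec = Union[float, Mapping[float, float], Callable[[float], float]]


@dataclass(frozen=True)
class GatingModelParams:
    v_half: float                       # mV
    k: float                            # mV per e-fold; != 0
    tau_act: TauSpec = 100.0            # ms
    g_max: float = 10.0                 # nS
    e_k: float = E_K_DEFAULT            # mV
    g_leak: float = 0.5                 # nS
    e_leak: float = 0.0                 # mV
    c_m: float = 10.0                   # pF
    noise_sd: float = 2.0               # pA
    tau_dep: Optional[Mapping[float, float]] = None   # s, per step voltage
    seed: int = 0

    def __post_init__(self):
        if self.k == 0:
            raise ConfigurationError("slope factor k must be nonzero")
        if self.g_max <= 0 or self.c_m <= 0:
            raise ConfigurationError("g_max and C_m must be positive")

    def tau_at(self, v: float) -> float:
        if callable(self.tau_act):
            tau = self.tau_act(v)
        elif isinstance(self.tau_act, Mapping):
            if v not in self.tau_act:
                raise ConfigurationError(f"no tau_act entry for {v} mV")
            tau = self.tau_act[v]
        else:
            tau = float(self.tau_act)
        if tau <= 0:
            raise ConfigurationError("tau_act must be positive")
        return tau

    def p_inf(self, v: float) -> float:
        return float(boltzmann(v, self.v_half, self.k))


@dataclass
class Sweep:
    times: np.ndarray                   # ms from sweep start
    current: np.ndarray                 # pA
    voltage: np.ndarray                 # mV per sample
    segments: list[tuple[float, float, float]]  # (level, t_start, t_end)

    @property
    def step_level(self) -> float:
        return max(self.segments, key=lambda s: s[2] - s[1])[0]

    def segment_slice(self, seg: int) -> slice:
        _, t0, t1 = self.segments[seg]
        i0 = int(np.searchsorted(self.times, t0, side="left"))
        i1 = int(np.searchsorted(self.times, t1, side="right"))
        return slice(i0, i1)

    def main_segment(self) -> int:
        return int(np.argmax([t1 - t0 for _, t0, t1 in self.segments]))


@dataclass
class SweepSet:
    protocol: VoltageProtocol
    sweeps: list[Sweep]
    capacitance: float                  # pF
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, sw in enumerate(self.sweeps):
            rows.append(pd.DataFrame({
                "sweep_id": i, "step_mV": sw.step_level,
                "time_ms": sw.times, "current_pA": sw.current,
                "voltage_mV": sw.voltage}))
        return pd.concat(rows, ignore_index=True)


def _params_hash(params: GatingModelParams, protocol: VoltageProtocol) -> str:
    blob = json.dumps({"v_half": params.v_half, "k": params.k,
                       "g_max": params.g_max, "e_k": params.e_k,
                       "g_leak": params.g_leak, "e_leak": params.e_leak,
                       "c_m": params.c_m, "noise_sd": params.noise_sd,
                       "seed": params.seed,
                       "holding": protocol.holding,
                       "sweeps": protocol.sweeps}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _simulate(params: GatingModelParams, protocol: VoltageProtocol,
              depletion: bool) -> SweepSet:
    rng = np.random.default_rng(params.seed)
    dt = protocol.sample_interval
    sweeps: list[Sweep] = []
    for sweep_segments in protocol.sweeps:
        p = params.p_inf(protocol.holding)   # equilibrated at holding
        times_all, current_all, volt_all, seg_meta = [], [], [], []
        t_offset = 0.0
        main_dur = max(dur for _, dur in sweep_segments)
        for level, dur in sweep_segments:
            n = int(round(dur / dt))
            t = (np.arange(n) + 1) * dt     # within-segment time
            tau = params.tau_at(level)
            p_inf = params.p_inf(level)
            p_t = p_inf + (p - p_inf) * np.exp(-t / tau)
            scale = np.ones(n)
            if depletion and dur == main_dur:
                if params.tau_dep is None or level not in params.tau_dep:
                    raise ConfigurationError(
                        f"no depletion time constant for {level} mV")
                tau_dep_ms = params.tau_dep[level] * 1000.0
                if math.isfinite(tau_dep_ms):
                    scale = np.exp(-t / tau_dep_ms)
            i_t = (params.g_max * p_t * scale * (level - params.e_k)
                   + params.g_leak * (level - params.e_leak))
            if params.noise_sd > 0:
                i_t = i_t + rng.normal(0.0, params.noise_sd, size=n)
            times_all.append(t + t_offset)
            current_all.append(i_t)
            volt_all.append(np.full(n, level))
            seg_meta.append((level, t_offset, t_offset + dur))
            t_offset += dur
            p = float(p_t[-1])              # gate state carries over
        sweeps.append(Sweep(times=np.concatenate(times_all),
                            current=np.concatenate(current_all),
                            voltage=np.concatenate(volt_all),
                            segments=seg_meta))
    return SweepSet(protocol=protocol, sweeps=sweeps,
                    capacitance=params.c_m,
                    metadata={"params_hash": _params_hash(params, protocol),
                              "seed": params.seed, "e_k": params.e_k,
                              "v_half": params.v_half, "k": params.k})


def generate_activation_sweeps(params: GatingModelParams,
                               protocol: VoltageProtocol) -> SweepSet:
    """Activation sweep family (no PIP2 depletion)."""
    return _simulate(params, protocol, depletion=False)


def generate_vsp_sweeps(params: GatingModelParams,
                        protocol: VoltageProtocol) -> SweepSet:
    """VSP-style sweeps: conductance decays as exp(-t/tau_dep(V)) during the
    long depolarizing segment of each sweep and is fully restored between
    sweeps."""
    if params.tau_dep is None:
        raise ConfigurationError("tau_dep table required for VSP sweeps")
    return _simulate(params, protocol, depletion=True)
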
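"""0-D left ventricle: time-varying elastance blending ESPVR and EDPVR.

The ventricle is described by an instantaneous pressure-volume relation
that interpolates between a linear end-systolic law

    P_es(V) = Ees * (V - Vd)

and an exponential end-diastolic law

    P_ed(V) = P0 * exp(beta * V)

weighted by a smooth periodic activation function eps(t) in [0, 1]:

    P_lv(V, t) = eps(t) * P_es(V) + (1 - eps(t)) * P_ed(V)

Filling comes from a constant-pressure source (Pfill) through a resistive
mitral path; ejection passes through a resistive aortic path.  Both valves
are ideal diodes (one-way, no inertance, no regurgitation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace
from functools import lru_cache

import numpy as np

__all__ = [
    "VentricleParams",
    "VentricleState",
    "espvr_pressure",
    "edpvr_pressure",
    "activation",
    "ventricular_pressure",
    "valve_flows",
    "edpvr_equilibrium_volume",
]


@dataclass(frozen=True)
class VentricleParams:
    """Left-ventricle and valve parameters.

    Attributes
    ----------
    Ees : end-systolic elastance, mmHg/mL
    Vd : dead volume (zero-pressure intercept of the ESPVR), mL
    P0 : dead pressure of the EDPVR, mmHg
    beta : diastolic stiffness, 1/mL
    Pfill : constant filling (preload source) pressure, mmHg
    period : cardiac cycle length, s
    t_systole : activation duration scale, s
    Rmitral : filling path resistance, mmHg.s/mL
    Raortic : ejection path resistance, mmHg.s/mL (0 = direct coupling
        to the arterial root through the wave-solver interface)
    act_rise_frac, act_decay_frac, act_m1, act_m2 : shape parameters of
        the double-Hill activation (time constants relative to t_systole
        and Hill exponents).
    """

    Ees: float = 3.2
    Vd: float = 15.0
    P0: float = 2.3
    beta: float = 0.013
    Pfill: float = 11.5
    period: float = 0.8
    t_systole: float = 0.3
    Rmitral: float = 0.005
    Raortic: float = 0.018
    act_rise_frac: float = 0.72
    act_decay_frac: float = 1.25
    act_m1: float = 1.46
    act_m2: float = 27.4

    def __post_init__(self) -> None:
        if not (self.Ees > 0 and self.beta > 0 and self.P0 > 0):
            raise ValueError("Ees, beta and P0 must be positive")
        if not self.period > 0:
            raise ValueError("period must be positive")
        if not 0 < self.t_systole < self.period:
            raise ValueError("t_systole must lie in (0, period)")
        if not self.Pfill > self.P0:
            raise ValueError(
                "Pfill must exceed P0, otherwise the ventricle can never "
                "fill above V = 0"
            )
        if self.Rmitral <= 0 or self.Raortic < 0:
            raise ValueError("Rmitral must be > 0 and Raortic >= 0")

    def replace(self, **kw) -> "VentricleParams":
        return _dc_replace(self, **kw)


@dataclass
class VentricleState:
    """Instantaneous LV state: volume (mL) and time within the cycle (s)."""

    V: float
    t: float

    def __post_init__(self) -> None:
        if self.V < 0:
            raise ValueError("LV volume cannot be negative")


def espvr_pressure(V, params: VentricleParams):
    """Linear end-systolic pressure-volume relation, Ees*(V - Vd), mmHg.

    May be negative below the dead volume; the activation blend keeps
    physiologic states non-negative.
    """
    return params.Ees * (np.asarray(V, dtype=float) - params.Vd)


def edpvr_pressure(V, params: VentricleParams):
    """Exponential end-diastolic pressure-volume relation, P0*exp(beta*V)."""
    return params.P0 * np.exp(params.beta * np.asarray(V, dtype=float))


def edpvr_equilibrium_volume(params: VentricleParams) -> float:
    """Volume at which the EDPVR balances the filling pressure.

    Closed form ln(Pfill/P0)/beta: the volume a passively filling
    ventricle approaches over a long diastole.
    """
    return math.log(params.Pfill / params.P0) / params.beta


@lru_cache(maxsize=64)
def _activation_norm(period, t_systole, rise_frac, decay_frac, m1, m2):
    """Peak of the un-normalized double-Hill shape over one cycle."""
    t = np.linspace(0.0, period, 4096, endpoint=False)
    return float(np.max(_double_hill(t, t_systole, rise_frac, decay_frac,
                                     m1, m2)))


def _double_hill(t, t_systole, rise_frac, decay_frac, m1, m2):
    tau1 = rise_frac * t_systole
    tau2 = decay_frac * t_systole
    x1 = (t / tau1) ** m1
    return (x1 / (1.0 + x1)) / (1.0 + (t / tau2) ** m2)


def activation(t, params: VentricleParams):
    """Normalized activation eps(t) in [0, 1].

    Double-Hill shape: a shallow Hill rise times a steep Hill cutoff,
    rescaled so the cycle maximum is exactly 1.  eps(0) = 0, the maximum
    is reached during systole, and the function has returned to ~0 well
    before the end of the cycle.  Times outside [0, period) are reduced
    modulo the period.
    """
    t = np.mod(np.asarray(t, dtype=float), params.period)
    norm = _activation_norm(params.period, params.t_systole,
                            params.act_rise_frac, params.act_decay_frac,
                            params.act_m1, params.act_m2)
    return _double_hill(t, params.t_systole, params.act_rise_frac,
                        params.act_decay_frac, params.act_m1,
                        params.act_m2) / norm


def ventricular_pressure(V, t, params: VentricleParams):
    """Instantaneous LV pressure: activation-weighted ESPVR/EDPVR blend."""
    eps = activation(t, params)
    return eps * espvr_pressure(V, params) + (1.0 - eps) * edpvr_pressure(
        V, params)


def valve_flows(P_lv, P_root, params: VentricleParams):
    """Mitral inflow and aortic outflow through ideal resistive diodes.

    Returns (Q_in, Q_out) in mL/s.  Q_in = max(0, (Pfill - P_lv)/Rmitral);
    Q_out = max(0, (P_lv - P_root)/Raortic).  A zero Raortic means the
    ejection coupling is handled by the wave solver, so Q_out is reported
    as 0 here.
    """
    P_lv = np.asarray(P_lv, dtype=float)
    q_in = np.maximum(0.0, (params.Pfill - P_lv) / params.Rmitral)
    if params.Raortic > 0:
        q_out = np.maximum(0.0, (P_lv - np.asarray(P_root, float))
                           / params.Raortic)
    else:
        q_out = np.zeros_like(P_lv)
    return q_in, q_out
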
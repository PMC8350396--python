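"""Coupled heart + arterial-tree simulation to a periodic steady state."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cardiac import VentricleParams, activation
from .network import ArterialTree, total_peripheral_resistance
from .solver import NetworkSolver

__all__ = ["RunControls", "BeatResult", "ConvergenceError",
           "run_to_periodic", "pv_loop", "stroke_work"]


class ConvergenceError(RuntimeError):
    """Beat-to-beat convergence not reached within the beat budget."""

    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


@dataclass(frozen=True)
class RunControls:
    """Numerical controls for :func:`run_to_periodic`.

    dx in cm; tol is the L-infinity root-pressure difference between
    consecutive beats (mmHg) accepted as periodic; output_hz the analytic
    resampling rate.
    """

    dx: float = 0.5
    cfl: float = 0.9
    tol: float = 0.5
    max_beats: int = 30
    output_hz: float = 1000.0
    linearized: bool = False
    p_init: float | None = None
    wall_damping: float = 0.0


@dataclass
class BeatResult:
    """One converged cardiac cycle plus its scalar metrics.

    Waveforms share a uniform time grid over a single period: aortic root
    pressure (mmHg) and flow (mL/s), LV pressure (mmHg) and volume (mL).
    """

    t: np.ndarray
    P_root: np.ndarray
    Q_root: np.ndarray
    P_lv: np.ndarray
    V_lv: np.ndarray
    period: float
    beats_run: int = 0
    converged: bool = True
    residual: float = 0.0
    inflow_volume: float = 0.0
    outflow_volume: float = 0.0
    residual_history: list = field(default_factory=list)

    @property
    def EDV(self) -> float:
        return float(np.max(self.V_lv))

    @property
    def ESV(self) -> float:
        return float(np.min(self.V_lv))

    @property
    def SV(self) -> float:
        return self.EDV - self.ESV

    @property
    def EF(self) -> float:
        return 100.0 * self.SV / self.EDV

    @property
    def CO(self) -> float:
        """Cardiac output, mL/s."""
        return self.SV / self.period

    @property
    def MAP(self) -> float:
        return float(np.mean(self.P_root))

    @property
    def max_flow(self) -> float:
        return float(np.max(self.Q_root))

    @property
    def peak_lv_pressure(self) -> float:
        return float(np.max(self.P_lv))

    def metrics(self) -> dict:
        return {
            "SV": self.SV, "EDV": self.EDV, "ESV": self.ESV,
            "EF": self.EF, "CO": self.CO, "MAP": self.MAP,
            "max_flow": self.max_flow,
            "peak_lv_pressure": self.peak_lv_pressure,
            "period": self.period, "beats_run": self.beats_run,
            "residual": self.residual,
        }

    # -- round-tripping -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "P_root": self.P_root,
                             "Q_root": self.Q_root, "P_lv": self.P_lv,
                             "V_lv": self.V_lv})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_metrics(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metrics(), fh, indent=1)

    @classmethod
    def from_csv(cls, path, period: float | None = None) -> "BeatResult":
        df = pd.read_csv(path)
        t = df["t"].to_numpy()
        per = period if period is not None else float(
            t[-1] + (t[1] - t[0]))
        return cls(t=t, P_root=df["P_root"].to_numpy(),
                   Q_root=df["Q_root"].to_numpy(),
                   P_lv=df["P_lv"].to_numpy(),
                   V_lv=df["V_lv"].to_numpy(), period=per)


def _resample(t_src, y, t_dst, period):
    """Periodic linear interpolation onto the output grid."""
    return np.interp(t_dst, np.append(t_src, period),
                     np.append(y, y[0]))


def run_to_periodic(heart: VentricleParams, tree: ArterialTree,
                    ctrl: RunControls = RunControls()) -> BeatResult:
    """Integrate the coupled system beat by beat until periodic.

    Convergence: L-infinity difference of the root pressure between two
    consecutive beats below ``ctrl.tol``.  The tree starts uniformly
    pressurized near a mean-pressure estimate and the ventricle at its
    EDPVR/Pfill equilibrium volume, which makes convergence fast and
    scenario independent.  Raises :class:`ConvergenceError` with the
    residual history when the beat budget is exhausted.
    """
    if ctrl.p_init is not None:
        p_init = ctrl.p_init
    else:
        # crude MAP estimate from a nominal 90 mL/s output
        p_init = min(120.0, 90.0 * total_peripheral_resistance(tree))
    solver = NetworkSolver(tree, dx=ctrl.dx, cfl=ctrl.cfl,
                           linearized=ctrl.linearized, p_init=p_init,
                           wall_damping=ctrl.wall_damping)
    solver.init_ventricle(heart)

    nsteps = int(np.ceil(heart.period / solver.dt))
    solver.dt = heart.period / nsteps
    tg = solver.dt * np.arange(nsteps)
    act = np.asarray(activation(tg, heart), dtype=float)

    prev = None
    history = []
    rec = None
    for beat in range(1, ctrl.max_beats + 1):
        rec = solver.run_beat(heart, nsteps, act)
        if prev is not None:
            resid = float(np.max(np.abs(rec["P_root"] - prev)))
            history.append(resid)
            if resid < ctrl.tol:
                break
        prev = rec["P_root"].copy()
    else:
        raise ConvergenceError(
            f"no periodic state after {ctrl.max_beats} beats "
            f"(last residual {history[-1]:.3f} mmHg)", history)

    t_out = np.arange(0.0, heart.period, 1.0 / ctrl.output_hz)
    result = BeatResult(
        t=t_out,
        P_root=_resample(tg, rec["P_root"], t_out, heart.period),
        Q_root=_resample(tg, rec["Q_root"], t_out, heart.period),
        P_lv=_resample(tg, rec["P_lv"], t_out, heart.period),
        V_lv=_resample(tg, rec["V_lv"], t_out, heart.period),
        period=heart.period,
        beats_run=beat,
        converged=True,
        residual=history[-1] if history else np.nan,
        inflow_volume=float(np.sum(rec["Q_root"]) * solver.dt),
        outflow_volume=float(np.sum(rec["Q_out"]) * solver.dt),
        residual_history=history,
    )
    return result


def pv_loop(beat: BeatResult) -> np.ndarray:
    """Ordered, closed (V, P) loop over one cycle, shape (n+1, 2)."""
    pts = np.column_stack([beat.V_lv, beat.P_lv])
    return np.vstack([pts, pts[:1]])


def stroke_work(beat: BeatResult) -> float:
    """Loop area  -∮P dV (mmHg.mL), positive for a counter-clockwise loop
    in the (V, P) plane traversed as ejection-then-filling."""
    loop = pv_loop(beat)
    v, p = loop[:, 0], loop[:, 1]
    return float(-np.trapezoid(p, v))
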
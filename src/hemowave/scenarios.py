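"""The three hemodynamic states and the ventricular remodeling loop.

Banding reduces the compliance of the proximal aortic segment group by a
fraction (default 80%) without narrowing the lumen; the peripheral
resistance is raised (default +30%) to reproduce the observed mean
pressure rise at conserved cardiac output; the dead volume drops by
5 mL (acute enhancement of systolic function under afterload); and the
filling pressure is re-tuned so the stroke volume is conserved
(Frank-Starling compensation).

Chronic adaptation is concentric hypertrophy driven by a Laplace-law
stress surrogate, sigma = P * EDV^(1/3) / Ees: the end-systolic
elastance (with the diastolic stiffness beta scaled proportionally) is
iterated until sigma returns to its baseline value within 1%, with an
inner loop conserving stroke volume at every step.  Dead volume and all
arterial parameters are held fixed throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .cardiac import VentricleParams
from .network import ArterialTree, total_peripheral_resistance
from .simulate import BeatResult, RunControls, run_to_periodic
from .solver import SolverInstability

__all__ = ["ScenarioSpec", "RemodelingResult", "apply_banding",
           "scale_tpr", "tune_pfill", "stress_index", "remodel"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioSpec:
    """Directives for one banding/remodeling study.

    banding_fraction: fractional proximal compliance reduction;
    tpr_scale: total-peripheral-resistance multiplier; vd_shift: acute
    dead-volume change in mL; sv_target: stroke volume to conserve
    (taken from the baseline beat when None).
    """

    name: str = "baseline"
    banding_fraction: float = 0.80
    tpr_scale: float = 1.30
    vd_shift: float = -5.0
    sv_target: float | None = None

    def __post_init__(self) -> None:
        if self.name not in ("baseline", "banding", "remodeling"):
            raise ValueError(f"unknown scenario name {self.name!r}")
        if not 0 <= self.banding_fraction < 1:
            raise ValueError("banding_fraction must lie in [0, 1)")
        if self.tpr_scale <= 0:
            raise ValueError("tpr_scale must be positive")


@dataclass
class RemodelingResult:
    """Converged output of the stress-optimization loop."""

    Ees_remodel: float
    beta_remodel: float
    Pfill_remodel: float
    sigma_target: float
    sigma_final: float
    iterations: int
    beat: BeatResult
    heart: VentricleParams
    trace: list = field(default_factory=list)


def apply_banding(tree: ArterialTree, fraction: float) -> ArterialTree:
    """Scale the proximal-flagged segment compliances by (1 - fraction).

    All other segments and all terminal compliances are untouched, so
    total_compliance drops by exactly fraction * (proximal share of CT).
    """
    if not 0 <= fraction < 1:
        raise ValueError("banding fraction must lie in [0, 1)")
    if not any(s.proximal for s in tree.segments):
        raise ValueError("tree has no proximal-flagged segments to band")
    segs = [s.replace(compliance_per_length=s.compliance_per_length
                      * (1.0 - fraction)) if s.proximal else s
            for s in tree.segments]
    return ArterialTree(segs, dict(tree.children), dict(tree.terminals),
                        tree.pref)


def scale_tpr(tree: ArterialTree, factor: float) -> ArterialTree:
    """Scale the total peripheral resistance by ``factor``.

    Each terminal's (Z1 + R2) budget is multiplied by a common factor m,
    with Z1 kept at the matched value and the change absorbed by R2;
    m is solved so the tree's DC input resistance scales exactly.
    Terminal compliances are unchanged.
    """
    if factor <= 0:
        raise ValueError("TPR factor must be positive")
    if factor == 1.0:
        return tree
    target = factor * total_peripheral_resistance(tree)

    def scaled(m: float) -> ArterialTree:
        terms = {k: t.replace(R2=m * (t.Z1 + t.R2) - t.Z1)
                 for k, t in tree.terminals.items()}
        return ArterialTree(list(tree.segments), dict(tree.children),
                            terms, tree.pref)

    m = brentq(lambda m: total_peripheral_resistance(scaled(m)) - target,
               0.5 * factor, 2.0 * factor, xtol=1e-12)
    return scaled(m)


def stress_index(P: float, EDV: float, Ees: float) -> float:
    """Laplace-law wall-stress surrogate sigma = P * EDV^(1/3) / Ees.

    P and EDV characterize the pressure and radius terms of wall stress;
    Ees is proportional to wall thickness in concentric hypertrophy.
    """
    if P <= 0 or EDV <= 0 or Ees <= 0:
        raise ValueError("stress_index inputs must be positive")
    return P * EDV ** (1.0 / 3.0) / Ees


#: inner-loop stroke volume tolerance (relative)
SV_RTOL = 0.005
#: Pfill search bracket relative to P0 and an absolute ceiling, mmHg
PFILL_MAX = 40.0


def tune_pfill(heart: VentricleParams, tree: ArterialTree,
               sv_target: float,
               ctrl: RunControls = RunControls()) -> tuple[VentricleParams,
                                                           BeatResult]:
    """Adjust Pfill so the converged stroke volume matches sv_target.

    SV(Pfill) is empirically monotone increasing (Frank-Starling), so a
    secant iteration from the current Pfill converges in a few beats;
    it falls back to bisection on [1.1*P0, 40] mmHg.  Raises ValueError
    with the SV(Pfill) trace when the bracket cannot produce the target.
    """
    lo, hi = 1.1 * heart.P0, PFILL_MAX
    trace = []

    def sv_at(pf: float) -> BeatResult:
        try:
            beat = run_to_periodic(heart.replace(Pfill=pf), tree, ctrl)
        except SolverInstability as exc:
            raise ValueError(
                f"sv_target {sv_target:.1f} mL not attainable: the beat at "
                f"Pfill {pf:.2f} mmHg left the solver's validity range "
                f"({exc}); SV(Pfill) trace: {trace}") from exc
        trace.append((pf, beat.SV))
        return beat

    pf = min(max(heart.Pfill, lo), hi)
    beat = sv_at(pf)
    for _ in range(12):
        if abs(beat.SV - sv_target) / sv_target < SV_RTOL:
            return heart.replace(Pfill=pf), beat
        pf2 = min(pf * 1.05, hi)
        beat2 = sv_at(pf2)
        slope = (beat2.SV - beat.SV) / (pf2 - pf)
        if slope <= 0:
            break
        pf_new = pf + (sv_target - beat.SV) / slope
        if not lo <= pf_new <= hi:
            break
        pf, beat = pf_new, sv_at(pf_new)
    else:
        raise ValueError(f"tune_pfill did not converge; SV(Pfill) trace: "
                         f"{trace}")

    # bisection fallback on the full bracket
    b_lo, b_hi = sv_at(lo), sv_at(hi)
    if not b_lo.SV <= sv_target <= b_hi.SV:
        raise ValueError(
            f"sv_target {sv_target:.1f} mL not attainable in the Pfill "
            f"bracket [{lo:.2f}, {hi:.1f}] mmHg; SV(Pfill) trace: {trace}")
    for _ in range(40):
        pf = 0.5 * (lo + hi)
        beat = sv_at(pf)
        if abs(beat.SV - sv_target) / sv_target < SV_RTOL:
            return heart.replace(Pfill=pf), beat
        if beat.SV < sv_target:
            lo = pf
        else:
            hi = pf
    raise ValueError(f"tune_pfill bisection stalled; trace: {trace}")


def remodel(banded_heart: VentricleParams, banded_tree: ArterialTree,
            sigma_target: float, sv_target: float,
            ctrl: RunControls = RunControls(), max_iter: int = 25,
            damping: float = 0.7, tol: float = 0.01) -> RemodelingResult:
    """Concentric-hypertrophy loop: raise Ees (and beta proportionally)
    until the stress index returns to ``sigma_target`` within ``tol``.

    Outer update: multiplicative fixed point Ees <- Ees*(1 + damping *
    (sigma/sigma_target - 1)); inner loop: Pfill re-tuned at every step
    so the stroke volume stays at sv_target.  The dead volume and every
    arterial parameter are left untouched.  The stress index uses the
    peak LV pressure of the converged beat.
    """
    base_Ees, base_beta = banded_heart.Ees, banded_heart.beta
    heart, beat = tune_pfill(banded_heart, banded_tree, sv_target, ctrl)
    trace = []
    sigma = stress_index(beat.peak_lv_pressure, beat.EDV, heart.Ees)
    for it in range(max_iter + 1):
        err = sigma / sigma_target - 1.0
        trace.append((heart.Ees, sigma))
        log.info("remodel iter %d: Ees=%.3f sigma=%.2f err=%+.3f",
                 it, heart.Ees, sigma, err)
        if abs(err) <= tol:
            return RemodelingResult(
                Ees_remodel=heart.Ees,
                beta_remodel=heart.beta,
                Pfill_remodel=heart.Pfill,
                sigma_target=sigma_target,
                sigma_final=sigma,
                iterations=it,
                beat=beat,
                heart=heart,
                trace=trace,
            )
        new_Ees = heart.Ees * (1.0 + damping * err)
        heart = heart.replace(Ees=new_Ees,
                              beta=base_beta * new_Ees / base_Ees)
        heart, beat = tune_pfill(heart, banded_tree, sv_target, ctrl)
        sigma = stress_index(beat.peak_lv_pressure, beat.EDV, heart.Ees)
    raise RuntimeError(f"remodeling loop exceeded {max_iter} iterations; "
                       f"sigma trace: {trace}")
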
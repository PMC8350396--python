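"""Synthetic study inputs: reduced arterial tree, heart configurations,
and analytic pressure/flow pairs with known forward/backward composition.

The tree stands in for a full anatomical arterial network with a
deliberately small topology: a five-segment proximal aortic chain
(ascending aorta + arch + proximal thoracic aorta, the banding target),
four side branches (brachiocephalic, carotid, celiac, renal/mesenteric
groups), a descending/abdominal aortic continuation, and six terminal
Windkessels.  Free parameters are the total arterial compliance CT, the
fraction of CT held by the proximal chain, and the total peripheral
resistance TPR.

Geometry and the compliance-distribution rules below were calibrated
once against the study's baseline hemodynamics (stroke volume, ejection
fraction, central pressures, characteristic impedance, and the timing
of the first reflected wave) and then frozen.  The proximal chain is an
impedance "horn": its compliance is allocated ∝ L*A^8, which makes the
characteristic impedance rise smoothly from ~0.037 at the root to ~0.23
mmHg.s/mL at its distal end, avoiding a single large reflection site
directly behind the aortic valve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cardiac import VentricleParams
from .network import (ArterialTree, Segment, WindkesselTerminal,
                      segment_char_impedance, total_peripheral_resistance)

__all__ = ["FixtureSpec", "default_tree", "fixture_spec", "heart_config",
           "analytic_pq", "random_pq_draw", "AGES", "STATES"]

AGES = ("study-default", "30", "70")
STATES = ("baseline", "banding", "remodeling-init")

# frozen fixture geometry: (id, length cm, reference area cm^2)
_PROXIMAL_CHAIN = [
    ("ao_root", 3.0, 6.0),
    ("ao_asc", 2.0, 5.5),
    ("ao_arch1", 2.0, 5.0),
    ("ao_arch2", 2.0, 4.5),
    ("ao_thorA", 3.0, 4.0),
]

_DISTAL = [
    ("brachioceph", 8.0, 1.2),
    ("carotid", 8.0, 1.0),
    ("celiac", 6.0, 1.0),
    ("desc_thor1", 6.0, 3.0),
    ("desc_thor2", 6.0, 2.7),
    ("renal", 6.0, 1.0),
    ("desc_abdominal", 21.8, 2.3),
    ("mesenteric", 8.0, 0.9),
    ("abdominal_ao", 16.0, 1.6),
]

_CHILDREN = {
    "ao_root": ["ao_asc", "brachioceph"],
    "ao_asc": ["ao_arch1"],
    "ao_arch1": ["ao_arch2", "carotid"],
    "ao_arch2": ["ao_thorA"],
    "ao_thorA": ["celiac", "desc_thor1"],
    "desc_thor1": ["desc_thor2"],
    "desc_thor2": ["renal", "desc_abdominal"],
    "desc_abdominal": ["mesenteric", "abdominal_ao"],
}

#: exponent of the proximal compliance allocation C_i ~ L_i * A_i^tilt
_PROXIMAL_TILT = 8.0

#: share of the NON-proximal compliance budget carried by each distal
#: segment wall; the remainder goes to the terminal Windkessel C's
_DISTAL_WALL_SHARE = {
    "brachioceph": 0.0064,
    "carotid": 0.0043,
    "celiac": 0.0107,
    "desc_thor1": 0.0174,
    "desc_thor2": 0.0697,
    "renal": 0.0063,
    "desc_abdominal": 0.0925,
    "mesenteric": 0.0063,
    "abdominal_ao": 0.0410,
}

#: fraction of cardiac output (DC conductance weight) per terminal
_CONDUCTANCE = {
    "brachioceph": 0.107,
    "carotid": 0.071,
    "celiac": 0.286,
    "renal": 0.200,
    "mesenteric": 0.086,
    "abdominal_ao": 0.250,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Budget-level description of a fixture tree.

    ct_total in mL/mmHg, tpr_total in mmHg.s/mL; proximal_fraction is the
    share of CT in the proximal aortic chain.  ``seed`` switches on a
    reproducible +/-10% geometric perturbation for robustness tests.
    """

    ct_total: float = 0.96
    proximal_fraction: float = (1.0 - 0.58 / 0.96) / 0.80
    tpr_total: float = 0.92
    n_terminals: int = 6
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.proximal_fraction < 1:
            raise ValueError("proximal_fraction must lie in (0, 1)")
        if self.ct_total <= 0 or self.tpr_total <= 0:
            raise ValueError("compliance and resistance budgets must be "
                             "positive")
        if self.n_terminals != 6:
            raise ValueError("the reduced fixture geometry has exactly 6 "
                             "terminals")


def fixture_spec(age: str = "study-default") -> FixtureSpec:
    """CT/TPR budgets for the shipped ages.

    The proximal fraction of each age is pinned by the identity
    CT_banded = CT * (1 - 0.8 * f) applied to that age's banded CT
    (0.58, 0.86 and 0.62 mL/mmHg for the study default, 30 y and 70 y).
    """
    age = str(age)
    if age == "study-default":
        return FixtureSpec(0.96, (1 - 0.58 / 0.96) / 0.8, 0.92)
    if age == "30":
        return FixtureSpec(1.6, (1 - 0.86 / 1.6) / 0.8, 1.0)
    if age == "70":
        return FixtureSpec(0.90, (1 - 0.62 / 0.90) / 0.8, 1.22)
    raise ValueError(f"unknown age {age!r}; expected one of {AGES}")


def default_tree(spec: FixtureSpec | None = None) -> ArterialTree:
    """Construct the reduced fixture tree for the given budgets.

    Compliance bookkeeping is exact: segment compliances plus terminal
    C's sum to ct_total, with proximal_fraction of it in the flagged
    chain.  Terminal R2's are solved so the DC input resistance equals
    tpr_total, with Z1 matched to the attached segment's characteristic
    impedance (which minimizes spurious high-frequency terminal
    reflections).
    """
    spec = spec or FixtureSpec()
    chain, distal = _PROXIMAL_CHAIN, _DISTAL
    if spec.seed is not None:
        rng = np.random.default_rng(spec.seed)
        perturb = lambda rows: [(sid, L * rng.uniform(0.9, 1.1),
                                 a0 * rng.uniform(0.9, 1.1))
                                for sid, L, a0 in rows]
        chain, distal = perturb(chain), perturb(distal)

    prox_budget = spec.proximal_fraction * spec.ct_total
    non_prox = spec.ct_total - prox_budget

    w = np.array([L * a0 ** _PROXIMAL_TILT for _, L, a0 in chain])
    w = w / w.sum()
    segments = [Segment(sid, L, a0, prox_budget * wi / L, proximal=True)
                for (sid, L, a0), wi in zip(chain, w)]
    for sid, L, a0 in distal:
        c_seg = non_prox * _DISTAL_WALL_SHARE[sid]
        segments.append(Segment(sid, L, a0, c_seg / L))

    term_c_budget = non_prox * (1.0 - sum(_DISTAL_WALL_SHARE.values()))
    if term_c_budget <= 0:
        raise ValueError("infeasible compliance budgets: terminal "
                         "compliance would be non-positive")

    by_id = {s.id: s for s in segments}
    terminals = {}
    for leaf, wl in _CONDUCTANCE.items():
        z1 = segment_char_impedance(by_id[leaf])
        r2 = spec.tpr_total / wl - z1
        if r2 <= 0:
            raise ValueError("infeasible resistance budget: terminal R2 "
                             f"non-positive at {leaf}")
        terminals[leaf] = WindkesselTerminal(
            Z1=z1, R2=r2, C=term_c_budget * wl, Pout=0.0)

    tree = ArterialTree(segments, dict(_CHILDREN), terminals)

    # absorb viscous path resistances into R2 so TPR is exact
    for _ in range(6):
        err = total_peripheral_resistance(tree) - spec.tpr_total
        if abs(err) < 1e-10:
            break
        for leaf, wl in _CONDUCTANCE.items():
            t = tree.terminals[leaf]
            tree.terminals[leaf] = t.replace(R2=t.R2 - err / wl)
    return tree


_HEARTS = {
    # age -> baseline (Ees mmHg/mL, Vd mL, P0 mmHg, beta 1/mL, Pfill mmHg)
    "study-default": dict(Ees=3.2, Vd=15.0, P0=2.3, beta=0.013, Pfill=11.5),
    "30": dict(Ees=2.5, Vd=15.0, P0=2.3, beta=0.013, Pfill=11.5),
    "70": dict(Ees=3.0, Vd=15.0, P0=2.3, beta=0.015, Pfill=13.0),
}


def heart_config(state: str = "baseline",
                 age: str = "study-default") -> VentricleParams:
    """Ventricle parameter set for a study state and age.

    ``banding`` starts from the age's baseline with the dead volume
    lowered by 5 mL (the acute leftward ESPVR shift under afterload
    augmentation); its Pfill is subsequently tuned by the scenario
    layer.  ``remodeling-init`` is the banding set (the remodeling loop
    then finds Ees, beta and Pfill).
    """
    age = str(age)
    if age not in _HEARTS:
        raise ValueError(f"unknown age {age!r}; expected one of {AGES}")
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}; expected one of "
                         f"{STATES}")
    kw = dict(_HEARTS[age])
    if state in ("banding", "remodeling-init"):
        kw["Vd"] -= 5.0
    return VentricleParams(**kw)


# --------------------------------------------------------------------------
# analytic waveform pairs for the wave-separation oracle
# --------------------------------------------------------------------------

def _gaussian_pulse(t, t0, width, amp, base, period=None):
    """Gaussian pulse; when ``period`` is given the pulse is periodized
    by summing its images in the adjacent cycles (no wrap discontinuity)."""
    out = base + amp * np.exp(-0.5 * ((t - t0) / width) ** 2)
    if period is not None:
        for shift in (-period, period):
            out = out + amp * np.exp(-0.5 * ((t - t0 + shift) / width) ** 2)
    return out


def analytic_pq(period: float = 0.8, n: int = 1024, *,
                amp: float = 30.0, base: float = 30.0, t0: float = 0.12,
                width: float = 0.035, reflection_scale: float = 0.5,
                delay: float = 0.12, Zc_true: float = 0.06,
                reflection_width: float = 0.0):
    """Build (t, P, Q) from a known forward pulse and its scaled echo.

    The forward wave F is a Gaussian pulse; the backward wave is a
    scaled, delayed (periodically shifted) copy.  ``reflection_width``
    optionally disperses the echo: the reflected Gaussian is broadened
    by that amount (in s) with its peak reduced to conserve area, the
    way distributed reflection sites smear a returning wave.  On a
    transmission line of characteristic impedance Zc_true the
    components compose exactly as P = F + B and Q = (F - B)/Zc_true.
    Returns (t, P, Q, F, B) so tests can compare a recovered separation
    with the ground truth.
    """
    if delay < 0:
        raise ValueError("delay must be non-negative")
    if not 0 <= reflection_scale < 1:
        raise ValueError("reflection_scale must lie in [0, 1)")
    t = np.linspace(0.0, period, n, endpoint=False)
    F = _gaussian_pulse(t, t0, width, amp, base, period)
    wb = np.hypot(width, reflection_width)
    B = reflection_scale * _gaussian_pulse(
        np.mod(t - delay, period), t0, wb, amp * width / wb, base, period)
    P = F + B
    Q = (F - B) / Zc_true
    return t, P, Q, F, B


def random_pq_draw(rng: np.random.Generator, period: float = 0.8,
                   n: int = 1024) -> dict:
    """One randomized analytic waveform draw (for recovery property tests).

    Reflections are kept later than the 9th-harmonic period so that the
    3-9 harmonic impedance average isolates the true line impedance.
    """
    kw = dict(
        amp=float(rng.uniform(15.0, 45.0)),
        base=float(rng.uniform(20.0, 40.0)),
        t0=float(rng.uniform(0.08, 0.14)),
        width=float(rng.uniform(0.02, 0.05)),
        reflection_scale=float(rng.uniform(0.1, 0.8)),
        delay=float(rng.uniform(period / 9.0, 0.3)),
        Zc_true=float(rng.uniform(0.03, 0.20)),
        reflection_width=float(rng.uniform(0.08, 0.12)),
    )
    t, P, Q, F, B = analytic_pq(period, n, **kw)
    return dict(t=t, P=P, Q=Q, F=F, B=B, **kw, period=period)
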
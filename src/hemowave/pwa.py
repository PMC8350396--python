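"""Time-domain pulse wave analysis of the aortic pressure wave.

Extracts the classical central-pressure indices: systolic/diastolic/mean
pressures, the systolic inflection point ("shoulder") where the reflected
wave merges with the forward wave, the augmentation pressure AP and
augmentation index AIx = 100*AP/PP, and the Murgo-style phenotype:

* Type A — late-peaking wave, the shoulder precedes the peak and
  AIx > 10%;
* Type C — early-peaking wave, the peak precedes the shoulder and
  AIx < 0;
* Indeterminate otherwise (Murgo's intermediate Type B is deliberately
  collapsed into this class).

All timings are referenced to the foot of the systolic upstroke located
with the intersecting-tangent construction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = ["PressureWaveMetrics", "basic_pressures", "find_foot",
           "find_inflection", "augmentation", "classify_phenotype",
           "analyze_pressure", "aix"]

#: zero-phase low-pass cutoff applied before differentiation, Hz
LOWPASS_HZ = 25.0
#: upstroke-slope fraction defining the pre-peak knee
KNEE_SLOPE_FRAC = 0.27
#: the slope must stay below the knee threshold this long, s
KNEE_SUSTAIN_S = 0.02
#: minimal late-systolic rise (fraction of PP) for an augmented shoulder
KNEE_RISE_MIN = 0.09
#: absolute floor of that rise, mmHg (rejects ripples on small pulses)
KNEE_RISE_MIN_MMHG = 4.0


@dataclass(frozen=True)
class PressureWaveMetrics:
    """Scalar pulse-wave-analysis summary of one central pressure beat.

    Pressures in mmHg, times in s relative to the foot of the upstroke.
    ``AP``/``AIx``/``t_inflection``/``P_inflection`` are None when no
    systolic shoulder is detectable (phenotype is then Indeterminate).
    """

    aSBP: float
    aDBP: float
    MAP: float
    aPP: float
    t_peak: float
    t_inflection: float | None
    P_inflection: float | None
    AP: float | None
    AIx: float | None
    phenotype: str

    def to_dict(self) -> dict:
        return asdict(self)


def aix(ap: float, pp: float) -> float:
    """Augmentation index in percent, 100*AP/PP."""
    if pp == 0:
        raise ValueError("pulse pressure is zero")
    return 100.0 * ap / pp


def basic_pressures(P) -> tuple[float, float, float, float]:
    """(aSBP, aDBP, MAP, aPP) of one uniformly sampled cycle."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 1 or P.size < 4:
        raise ValueError("need one full uniformly sampled cycle")
    sbp = float(np.max(P))
    dbp = float(np.min(P))
    return sbp, dbp, float(np.mean(P)), sbp - dbp


def _smooth_periodic(P, fs, cutoff=LOWPASS_HZ):
    """Zero-phase Butterworth low-pass with periodic extension."""
    b, a = butter(4, cutoff, fs=fs)
    ext = np.concatenate([P, P, P])
    return filtfilt(b, a, ext)[P.size:2 * P.size]


def find_foot(t, P, fs=None) -> float:
    """Foot of the systolic upstroke by the intersecting-tangent method.

    The tangent at the point of maximal dP/dt is intersected with the
    horizontal line through the diastolic minimum; the crossing time is
    the foot.
    """
    t = np.asarray(t, float)
    P = np.asarray(P, float)
    fs = fs or 1.0 / (t[1] - t[0])
    ps = _smooth_periodic(P, fs)
    dp = np.gradient(ps, t)
    i = int(np.argmax(dp))
    pmin = float(np.min(ps))
    return float(t[i] - (ps[i] - pmin) / dp[i])


def _zero_crossings(y):
    s = np.sign(y)
    return np.nonzero(np.diff(s) != 0)[0] + 1


def find_inflection(t, P, period=None):
    """First systolic shoulder of a central pressure wave.

    Two-stage detection on the 25-Hz low-passed wave:

    1. *Pre-peak shoulder* (augmented, late-peaking waves): the knee
       where the upstroke slope first falls below 25% of its maximum.
       It is accepted only when the wave still rises substantially
       afterwards (systolic peak at least 6% of pulse pressure above
       the knee) — otherwise the knee is merely the top of the upstroke.
    2. *Post-peak shoulder* (early-peaking waves): the first zero
       crossing of the fourth derivative after the peak, where the
       reflected wave pauses the systolic decline; the second
       derivative serves as fallback.

    Returns (t_inflection, P_inflection) with time measured from the
    foot of the upstroke, or (None, None) when no shoulder exists.
    """
    t = np.asarray(t, float)
    P = np.asarray(P, float)
    period = period if period is not None else float(t[-1] + t[1] - t[0])
    fs = 1.0 / (t[1] - t[0])
    ps = _smooth_periodic(P, fs)
    pp = float(np.max(P) - np.min(P))
    if pp <= 0:
        return None, None
    foot = find_foot(t, P, fs)

    d1 = np.gradient(ps, t)
    d2 = np.gradient(d1, t)
    d4 = np.gradient(np.gradient(d2, t), t)
    i_up = int(np.argmax(d1))
    if d1[i_up] <= 0:
        return None, None
    i_peak = int(np.argmax(ps))
    guard = max(2, int(0.012 * fs))

    # stage 1: pre-peak knee (sustained slope drop, not a transient dip)
    thr = KNEE_SLOPE_FRAC * d1[i_up]
    sustain = max(2, int(KNEE_SUSTAIN_S * fs))
    for i in range(i_up, max(i_up, i_peak - guard)):
        if d1[i] < thr and np.all(d1[i:i + sustain] < thr):
            rise = np.max(P) - P[i]
            if rise / pp >= KNEE_RISE_MIN and rise >= KNEE_RISE_MIN_MMHG:
                return float(t[i] - foot), float(P[i])
            break

    # stage 2: post-peak shoulder
    hi = int(min(ps.size - 2, (foot + 0.5 * period) * fs))
    lo = i_peak + guard
    if hi <= lo:
        return None, None
    for dn in (d4, d2):
        cand = _zero_crossings(dn[lo:hi]) + lo
        if cand.size:
            i = int(cand[0])
            return float(t[i] - foot), float(P[i])
    return None, None


def augmentation(t, P, period=None):
    """(AP, AIx) from the shoulder/peak geometry.

    AP = aSBP - P_inflection when the shoulder precedes the peak
    (late-peak, augmented wave); AP = P_inflection - aSBP when the peak
    precedes the shoulder (early-peak wave, negative augmentation).
    Returns (None, None) when no shoulder is detectable.
    """
    t = np.asarray(t, float)
    P = np.asarray(P, float)
    sbp, _, _, pp = basic_pressures(P)
    t_inf, p_inf = find_inflection(t, P, period)
    if t_inf is None:
        return None, None
    foot = find_foot(t, P)
    t_peak = float(t[int(np.argmax(P))] - foot)
    ap = sbp - p_inf if t_inf < t_peak else p_inf - sbp
    return float(ap), aix(ap, pp)


def classify_phenotype(AIx, t_inflection, t_peak) -> str:
    """Murgo classification from augmentation index and wave timing."""
    if AIx is None or t_inflection is None:
        return "Indeterminate"
    if t_inflection < t_peak and AIx > 10.0:
        return "TypeA"
    if t_peak < t_inflection and AIx < 0.0:
        return "TypeC"
    return "Indeterminate"


def analyze_pressure(t, P, period=None) -> PressureWaveMetrics:
    """Full pulse-wave analysis of one central pressure cycle."""
    t = np.asarray(t, float)
    P = np.asarray(P, float)
    sbp, dbp, mean, pp = basic_pressures(P)
    foot = find_foot(t, P)
    t_peak = float(t[int(np.argmax(P))] - foot)
    t_inf, p_inf = find_inflection(t, P, period)
    if t_inf is None:
        ap = ai = None
    else:
        ap = sbp - p_inf if t_inf < t_peak else p_inf - sbp
        ai = aix(ap, pp) if pp > 0 else None
    return PressureWaveMetrics(
        aSBP=sbp, aDBP=dbp, MAP=mean, aPP=pp,
        t_peak=t_peak, t_inflection=t_inf, P_inflection=p_inf,
        AP=ap, AIx=ai,
        phenotype=classify_phenotype(ai, t_inf, t_peak),
    )
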
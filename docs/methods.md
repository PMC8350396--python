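# Methods

This note documents the models, numerical choices, and design decisions
behind `hemowave`, and what the shipped synthetic fixtures do and do not
represent.

## Ventricular model

The left ventricle is a 0-D time-varying elastance chamber. Its
instantaneous pressure is an activation-weighted blend of a systolic and
a diastolic law,

    P_lv(V, t) = ε(t)·E_es·(V − V_d) + (1 − ε(t))·P_0·exp(β·V),

with E_es the end-systolic elastance (mmHg/mL), V_d the dead volume
(mL), P_0 the dead pressure (mmHg), and β the diastolic stiffness
(1/mL). Defaults are the study-default baseline set E_es = 3.2,
V_d = 15, P_0 = 2.3, β = 0.013, filling pressure P_fill = 11.5 mmHg; the
30- and 70-year-old variants alter E_es, β and P_fill
(`fixtures.heart_config`).

**Activation.** ε(t) is a normalized double-Hill product,

    ε(t) ∝ [(t/τ1)^m1 / (1 + (t/τ1)^m1)] · [1 / (1 + (t/τ2)^m2)],

rescaled so its maximum over the cycle is exactly 1. The time constants
are expressed relative to the activation duration scale `t_systole`
(default 0.3 s): τ1 = 0.72·t_systole, τ2 = 1.25·t_systole, with Hill
exponents m1 = 1.46 and m2 = 27.4. These four shape parameters are
exposed on `VentricleParams`. They were calibrated once — together with
the fixture geometry, see below — so that the baseline beat reproduces
the study conditions (SV ≈ 74 mL, EF ≈ 61%, central pressures ≈ 106/59
mmHg, early systolic peak), and then frozen. The same activation is
used for every state: chronic remodeling alters E_es, β and P_fill
only.

**Valves and preload.** Both valves are ideal resistive diodes without
inertance or regurgitation. The mitral path resistance is 0.005
mmHg·s/mL, which lets diastolic filling approach the closed-form
EDPVR/P_fill equilibrium V = ln(P_fill/P_0)/β. The aortic path carries a
small resistance (default 0.018 mmHg·s/mL). A strictly zero aortic
resistance is supported, but with a purely resistive valve and no blood
inertance the ejection becomes unphysiologically impulsive (peak root
flow approaching 900 mL/s); the small default restores a realistic flow
pulse while keeping the transvalvular gradient of a healthy valve
(≈10 mmHg at peak flow).

**Heart rate.** The cycle length is not part of the study conditions;
the default is 0.8 s (75 bpm), configurable, and recorded in every
report row.

## Arterial network

Blood flow in each segment obeys the 1-D mass/momentum system with a
*linear* area–pressure wall law A(p) = A0 + C_A·(p − p_ref),

    ∂A/∂t + ∂Q/∂x = 0
    ∂Q/∂t + ∂/∂x(Q²/A + K·A²/(2ρC_A)) = −k_f·Q/A,

where K = 1333.22 dyn/cm²/mmHg, ρ = 1.06 g/mL, and the friction
coefficient k_f = 2(ζ+2)πμ/ρ uses a power-law velocity profile with
ζ = 9 and μ = 0.04 P. The linear wall law makes compliance bookkeeping
exact — the banding intervention is then an exact scaling of C_T — at
the cost of ignoring the strain-stiffening of real arteries.

**Numerics.** Explicit MacCormack predictor–corrector on uniform
per-segment grids (Δx ≈ 0.5 cm); junctions, terminals, and the inlet are
coupled through linearized Riemann invariants p ± Z_c·Q with pressure
continuity and flow conservation. The time step satisfies a CFL bound
evaluated at the maximal expected distension (230 mmHg) plus an
advective margin; instability is detected (NaN) and reported with the
offending segment and its CFL number. A `linearized` solver mode drops
the advective flux and evaluates wall/friction terms at the reference
area, making the scheme exactly linear (used for superposition
oracles). An optional Voigt-type wall damping (momentum diffusion,
`wall_damping` in cm²/s) is available; the default is 0, i.e. the purely
elastic wall law.

**Terminals.** Three-element Windkessels. Z1 is set to the attached
segment's characteristic impedance, which minimizes spurious
high-frequency terminal reflections; R2 carries the resistance budget
(solved so the DC input resistance of the whole tree equals the target
TPR exactly); terminal C carries the compliance budget not assigned to
segment walls. R2 = 0 degenerates the element to a pure resistor — used
to build reflection-free matched terminations in tests.

## The synthetic fixture tree

The tree replaces a full anatomical network by the smallest structure
that supports the study's phenomena: a five-segment proximal aortic
chain (the banding target, 12 cm), brachiocephalic and carotid branches
off the arch, a celiac-like branch at the arch/descending junction,
renal and mesenteric branches along a descending/abdominal aortic
continuation, and six terminals.

Free parameters are only the budgets: total compliance C_T, proximal
fraction, and TPR. The proximal fraction is pinned by the banding
identity C_T,banded = C_T·(1 − 0.8·f): f = 0.4948 for the study default
(0.96 → 0.58 mL/mmHg), 0.578 for the 30-year-old (1.6 → 0.86) and 0.389
for the 70-year-old (0.90 → 0.62).

Within the proximal chain, compliance is allocated ∝ L·A^8. This makes
the chain an impedance *horn*: Z_c rises smoothly from ≈0.037 at the
root to ≈0.23 mmHg·s/mL at its distal end. The strongly tapered
allocation, the celiac branch position, the distal wall/terminal
compliance split, and the descending lengths were chosen once by a
randomized search against the baseline study conditions (central
pressures, Z_c band estimate, reflection timing, and the three-state
trend structure) and then frozen as package constants. A seeded ±10%
geometric perturbation variant is available for robustness tests; it
preserves the budgets exactly.

What the fixture does **not** emulate: anatomical branch counts and
dimensions (side-branch wave speeds are stiffer than physiologic),
cerebral/coronary beds, nonlinear and viscoelastic wall behavior,
gravity and curvature. Quantities that depend on the detailed
reflection pattern of a real tree (absolute AP/AIx values, reflection
coefficients) therefore carry fixture-scale tolerances; the package's
tests check the *structure* of the three-state response, not exact
pressures.

## Scenario pipeline

Order of operations for the acute state: proximal compliance cut, TPR
scaling (+30%), dead-volume shift (−5 mL), then P_fill tuning. P_fill is
adjusted by a bracketed secant/bisection on the empirically monotone
SV(P_fill) map until the stroke volume matches the baseline within
0.5%.

The remodeling loop drives the stress surrogate σ = P·EDV^{1/3}/E_es
back to its baseline value: the outer iteration updates
E_es ← E_es·(1 + 0.7·(σ/σ_target − 1)) with β scaled proportionally to
E_es, the inner loop re-tunes P_fill, and convergence requires
|σ − σ_target|/σ_target ≤ 1% (typically 3–5 outer iterations). V_d and
all arterial parameters are held fixed. For "P" in σ the package uses
the peak LV pressure of the converged beat; with the small default
aortic resistance this is within a few mmHg of aortic systolic
pressure, and the converged E_es ratio is insensitive to the choice.

Convergence to the periodic state uses the L∞ difference of root
pressure between consecutive beats (tolerance 0.5 mmHg, at most 30
beats); the tree starts uniformly pressurized near a mean-pressure
estimate and the ventricle at its passive filling equilibrium, which
makes every shipped scenario converge in 6–10 beats. Beats are
resampled to 1 kHz for analytics regardless of the solver step.

## Pulse wave analysis

Timings are referenced to the foot of the upstroke found by the
intersecting-tangent construction. Before differentiation the wave is
low-passed with a zero-phase 4th-order Butterworth at 25 Hz on a
periodic extension.

The systolic shoulder is detected in two stages:

1. *Pre-peak (augmented) shoulder*: the knee where dP/dt first drops —
   and stays for ≥20 ms — below 27% of its upstroke maximum
   (`KNEE_SLOPE_FRAC`). The knee counts as a
   shoulder only if the wave still rises substantially afterwards
   (≥9% of pulse pressure and ≥4 mmHg); otherwise it is merely the top
   of the upstroke.
2. *Post-peak shoulder*: the first zero crossing of the fourth
   derivative after the systolic peak (second derivative as fallback),
   where the reflected wave pauses the decline of an early-peaking
   wave.

AP = aSBP − P_inflection when the shoulder precedes the peak, and
P_inflection − aSBP when the peak comes first; AIx = 100·AP/PP. The
phenotype is Type A (shoulder before peak and AIx > 10%), Type C (peak
before shoulder and AIx < 0), otherwise Indeterminate — the
intermediate Type B class is deliberately collapsed into Indeterminate
because the study distinguishes only A and C. The knee thresholds were
fixed against synthetic two-component waves and the three pipeline
states; they are module constants, not per-wave tuning.

## Wave separation

Input impedance is the harmonic-wise ratio of the Fourier-transformed
pressure and flow of exactly one periodic cycle (no windowing — beat
periodicity is guaranteed upstream). Z_c is the unweighted mean of the
modulus over harmonics 3–9; harmonics with vanishing flow content are
excluded with a warning, and fewer than three usable harmonics is an
error. Separation is the standard linear decomposition
P_f = (P + Z_c·Q)/2, P_b = (P − Z_c·Q)/2, exact by construction; no
re-basing is applied, so component peaks are absolute pressures and
amplitudes are max − min excursions. The forward-wave maximal slope is
measured on the same 25-Hz filtered signal as the time-domain
analytics.

The analytic waveform generator used as the separation oracle composes
a periodized Gaussian forward pulse with a scaled, delayed echo on a
line of known impedance. Randomized draws disperse the echo (broadened
by 0.08–0.12 s with area conserved), the way distributed reflection
sites smear a returning wave; this keeps the 3–9 harmonic band
reflection-poor, so the Z_c estimator is accurate there (≤3% error),
while the time-domain backward wave remains large.

## Problem sizes and determinism

The default study (three states, including the P_fill and remodeling
loops) integrates ~40 cardiac cycles of a ~240-node network at
Δt ≈ 0.18 ms and completes in a few seconds; the aging variants are
equally light. Everything is deterministic: there is no randomness in
the solver, and all synthetic-data randomness is seeded.

## Known limitations

* No heart-rate compensation, baroreflex, or vascular smooth-muscle
  activation; no atrial contraction; no valve inertance or
  regurgitation; no afterload-dependence of the normalized activation.
* Linear wall law and linearized junction coupling: correct to first
  order in distension; the advective nonlinearity is retained in the
  flux but junction transmission is linear.
* The reduced tree reproduces trend structure, not patient-level
  pressures; absolute AIx and reflection-coefficient values carry
  fixture-scale tolerances.
* Windkessel terminal states are advanced with explicit Euler at the
  solver step; this is adequate because terminal time constants are
  ≥50× the step.
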
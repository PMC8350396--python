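"""Physical constants and unit conventions.

All quantities in the package use a mixed CGS/clinical convention:
pressures in mmHg, flows in mL/s, volumes in mL, lengths in cm,
areas in cm^2, compliances in mL/mmHg, resistances in mmHg.s/mL,
time in s.  Conversions to dynamically consistent CGS units happen
only inside the wave solver, through the factor below.
"""

#: dyn/cm^2 per mmHg
MMHG = 1333.22

#: blood density, g/mL
RHO_BLOOD = 1.06

#: blood dynamic viscosity, poise (g/cm/s)
MU_BLOOD = 0.04

#: velocity-profile constant of the Poiseuille-type friction term
ZETA = 9.0


def friction_coefficient(zeta: float = ZETA, mu: float = MU_BLOOD,
                         rho: float = RHO_BLOOD) -> float:
    """Momentum-loss coefficient k such that dQ/dt includes -k*Q/A (cm^2/s).

    Derived from a power-law axial velocity profile of exponent ``zeta``:
    k = 2*(zeta + 2)*pi*mu/rho.
    """
    import math
    return 2.0 * (zeta + 2.0) * math.pi * mu / rho
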
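"""Explicit 1-D blood-flow solver on an arterial tree.

Each segment carries a uniform staggered grid of (A, Q) nodes advanced
with the explicit MacCormack predictor-corrector applied to the
conservative 1-D mass/momentum system with a linear area-pressure wall
law,

    dA/dt + dQ/dx = 0
    dQ/dt + d/dx(Q^2/A + K A^2 / (2 rho C_A)) = -k_f Q / A

where K converts mmHg to dyn/cm^2 and C_A is the area compliance per
unit length.  Junctions, terminals and the inlet are coupled through
linearized characteristics: along each boundary the incoming Riemann
invariant p -/+ Zc*Q is taken from the adjacent interior node and
combined with pressure continuity / flow conservation (junctions), the
three-element Windkessel relation (leaves), or the ventricular
pressure-flow law (root inlet).

A ``linearized`` mode drops the advective flux and evaluates the wall
and friction terms at the reference area, which makes the system exactly
linear (used for superposition checks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .cardiac import VentricleParams, activation, edpvr_equilibrium_volume
from .network import ArterialTree, segment_char_impedance, segment_wave_speed
from .units import MMHG, RHO_BLOOD, friction_coefficient

__all__ = ["CompiledTree", "NetworkSolver", "SolverInstability",
           "stable_dt"]


class SolverInstability(RuntimeError):
    """Raised when the explicit scheme diverges (NaN/overflow)."""


# --------------------------------------------------------------------------
# numba kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _run_kernel(nsteps, dt,
                A, Q, As, Qs,
                soff, snn, sdx, szc, sa0, sca,
                jparent, jcoff, jchild,
                tseg, tz1, tr2, tc, tpout, pc,
                pref, fric, wdiff, linearized,
                mode, qin, act, hp, vstate,
                proot, qroot, plv_rec, vlv_rec, qterm_rec):
    ns = soff.shape[0]
    nj = jparent.shape[0]
    nt = tseg.shape[0]
    K = 1333.22
    rho = 1.06

    Ees = hp[0]; Vd = hp[1]; P0 = hp[2]; beta = hp[3]
    Pfill = hp[4]; Rmit = hp[5]; Rao = hp[6]

    ntot = A.shape[0]
    Aold = np.empty(ntot)
    Qold = np.empty(ntot)

    for k in range(nsteps):
        for i in range(ntot):
            Aold[i] = A[i]
            Qold[i] = Q[i]

        # predictor (forward differences) + corrector (backward) per segment
        for s in range(ns):
            o = soff[s]
            n = snn[s]
            dx = sdx[s]
            a0 = sa0[s]
            ca = sca[s]
            wall = K / (2.0 * rho * ca)          # nonlinear wall flux coef
            wlin = K * a0 / (rho * ca)           # linearized wall flux coef
            r = dt / dx
            # predictor into As, Qs
            for i in range(n - 1):
                ia = o + i
                ib = ia + 1
                if linearized == 1:
                    f2a = wlin * Aold[ia]
                    f2b = wlin * Aold[ib]
                    src = -fric * Qold[ia] / a0
                else:
                    f2a = Qold[ia] * Qold[ia] / Aold[ia] + wall * Aold[ia] * Aold[ia]
                    f2b = Qold[ib] * Qold[ib] / Aold[ib] + wall * Aold[ib] * Aold[ib]
                    src = -fric * Qold[ia] / Aold[ia]
                As[ia] = Aold[ia] - r * (Qold[ib] - Qold[ia])
                Qs[ia] = Qold[ia] - r * (f2b - f2a) + dt * src
            As[o + n - 1] = Aold[o + n - 1]
            Qs[o + n - 1] = Qold[o + n - 1]
            # corrector for interior nodes
            for i in range(1, n - 1):
                ia = o + i
                ibm = ia - 1
                if linearized == 1:
                    f2a = wlin * As[ia]
                    f2b = wlin * As[ibm]
                    src = -fric * Qs[ia] / a0
                else:
                    f2a = Qs[ia] * Qs[ia] / As[ia] + wall * As[ia] * As[ia]
                    f2b = Qs[ibm] * Qs[ibm] / As[ibm] + wall * As[ibm] * As[ibm]
                    src = -fric * Qs[ia] / As[ia]
                A[ia] = 0.5 * (Aold[ia] + As[ia]) - 0.5 * r * (Qs[ia] - Qs[ibm])
                Q[ia] = 0.5 * (Qold[ia] + Qs[ia]) - 0.5 * r * (f2a - f2b) \
                    + 0.5 * dt * src

        # Voigt-type wall damping: momentum diffusion of rate wdiff
        # (cm^2/s), applied to interior nodes as a first-order sub-step
        if wdiff > 0.0:
            for s in range(ns):
                o = soff[s]
                n = snn[s]
                lam = wdiff * dt / (sdx[s] * sdx[s])
                qm = Q[o]
                for i in range(1, n - 1):
                    qc = Q[o + i]
                    Q[o + i] = qc + lam * (qm - 2.0 * qc + Q[o + i + 1])
                    qm = qc

        # ---- boundaries from time-n characteristics ----
        # root inlet (segment 0, node 0)
        o0 = soff[0]
        zc0 = szc[0]
        pn1 = pref + (Aold[o0 + 1] - sa0[0]) / sca[0]
        v_in = pn1 - zc0 * Qold[o0 + 1]
        p_lv = 0.0
        if mode == 1:
            eps = act[k]
            V = vstate[0]
            p_lv = eps * Ees * (V - Vd) + (1.0 - eps) * P0 * np.exp(beta * V)
            q_av = (p_lv - v_in) / (zc0 + Rao)
            if q_av < 0.0:
                q_av = 0.0
            q_mit = (Pfill - p_lv) / Rmit
            if q_mit < 0.0:
                q_mit = 0.0
            vstate[0] = V + dt * (q_mit - q_av)
        else:
            q_av = qin[k]
        p_in = v_in + zc0 * q_av
        Q[o0] = q_av
        A[o0] = sa0[0] + sca[0] * (p_in - pref)

        # junctions
        for j in range(nj):
            sp = jparent[j]
            ep = soff[sp] + snn[sp] - 1
            pint = pref + (Aold[ep - 1] - sa0[sp]) / sca[sp]
            w = pint + szc[sp] * Qold[ep - 1]
            num = w / szc[sp]
            den = 1.0 / szc[sp]
            for ci in range(jcoff[j], jcoff[j + 1]):
                c = jchild[ci]
                i1 = soff[c] + 1
                pcint = pref + (Aold[i1] - sa0[c]) / sca[c]
                vc = pcint - szc[c] * Qold[i1]
                num += vc / szc[c]
                den += 1.0 / szc[c]
            pstar = num / den
            Q[ep] = (w - pstar) / szc[sp]
            A[ep] = sa0[sp] + sca[sp] * (pstar - pref)
            for ci in range(jcoff[j], jcoff[j + 1]):
                c = jchild[ci]
                i1 = soff[c] + 1
                pcint = pref + (Aold[i1] - sa0[c]) / sca[c]
                vc = pcint - szc[c] * Qold[i1]
                Q[soff[c]] = (pstar - vc) / szc[c]
                A[soff[c]] = sa0[c] + sca[c] * (pstar - pref)

        # terminals
        q_out_sum = 0.0
        for ti in range(nt):
            s = tseg[ti]
            e = soff[s] + snn[s] - 1
            pint = pref + (Aold[e - 1] - sa0[s]) / sca[s]
            w = pint + szc[s] * Qold[e - 1]
            if tr2[ti] > 0.0:
                q = (w - pc[ti]) / (szc[s] + tz1[ti])
                pt = pc[ti] + tz1[ti] * q
                pc[ti] = pc[ti] + dt * (q - (pc[ti] - tpout[ti]) / tr2[ti]) \
                    / tc[ti]
            else:
                q = (w - tpout[ti]) / (szc[s] + tz1[ti])
                pt = tpout[ti] + tz1[ti] * q
            Q[e] = q
            A[e] = sa0[s] + sca[s] * (pt - pref)
            q_out_sum += q

        proot[k] = pref + (A[o0] - sa0[0]) / sca[0]
        qroot[k] = Q[o0]
        plv_rec[k] = p_lv
        vlv_rec[k] = vstate[0]
        qterm_rec[k] = q_out_sum

    return 0


# --------------------------------------------------------------------------
# tree flattening
# --------------------------------------------------------------------------

@dataclass
class CompiledTree:
    """Flat array view of an :class:`ArterialTree` for the kernel."""

    tree: ArterialTree
    order: list[str]
    soff: np.ndarray
    snn: np.ndarray
    sdx: np.ndarray
    szc: np.ndarray
    sa0: np.ndarray
    sca: np.ndarray
    jparent: np.ndarray
    jcoff: np.ndarray
    jchild: np.ndarray
    tseg: np.ndarray
    tz1: np.ndarray
    tr2: np.ndarray
    tc: np.ndarray
    tpout: np.ndarray
    ntot: int

    @classmethod
    def build(cls, tree: ArterialTree, dx: float = 0.5) -> "CompiledTree":
        order: list[str] = []
        stack = [tree.root.id]
        while stack:                       # BFS so the root is segment 0
            sid = stack.pop(0)
            order.append(sid)
            stack.extend(tree.children.get(sid, []))
        index = {sid: i for i, sid in enumerate(order)}

        nn, dxs, zc, a0, ca, off = [], [], [], [], [], []
        tot = 0
        for sid in order:
            seg = tree.segment(sid)
            n = max(3, int(round(seg.length / dx)) + 1)
            off.append(tot)
            nn.append(n)
            dxs.append(seg.length / (n - 1))
            zc.append(segment_char_impedance(seg))
            a0.append(seg.area0)
            ca.append(seg.compliance_per_length)
            tot += n

        jp, jc_flat, jcoff = [], [], [0]
        for sid in order:
            kids = tree.children.get(sid, [])
            if kids:
                jp.append(index[sid])
                jc_flat.extend(index[c] for c in kids)
                jcoff.append(len(jc_flat))

        tseg, tz1, tr2, tcc, tpo = [], [], [], [], []
        for leaf in tree.leaves:
            t = tree.terminals[leaf]
            tseg.append(index[leaf])
            tz1.append(t.Z1)
            tr2.append(t.R2)
            tcc.append(t.C)
            tpo.append(t.Pout)

        return cls(
            tree=tree, order=order,
            soff=np.array(off, dtype=np.int64),
            snn=np.array(nn, dtype=np.int64),
            sdx=np.array(dxs), szc=np.array(zc),
            sa0=np.array(a0), sca=np.array(ca),
            jparent=np.array(jp, dtype=np.int64),
            jcoff=np.array(jcoff, dtype=np.int64),
            jchild=np.array(jc_flat, dtype=np.int64),
            tseg=np.array(tseg, dtype=np.int64),
            tz1=np.array(tz1), tr2=np.array(tr2),
            tc=np.array(tcc), tpout=np.array(tpo),
            ntot=tot,
        )

    def node_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-node (a0, C_A) arrays matching the state layout."""
        a0n = np.empty(self.ntot)
        can = np.empty(self.ntot)
        for s in range(len(self.order)):
            sl = slice(self.soff[s], self.soff[s] + self.snn[s])
            a0n[sl] = self.sa0[s]
            can[sl] = self.sca[s]
        return a0n, can


def stable_dt(tree: ArterialTree, dx: float = 0.5, cfl: float = 0.9,
              p_max: float = 230.0, u_max: float = 200.0,
              wall_damping: float = 0.0) -> float:
    """Largest time step satisfying the CFL bound with safety margins.

    The local wave speed grows with distension, so the bound is evaluated
    at the area reached at ``p_max`` mmHg and the advective speed is
    padded by ``u_max`` cm/s.
    """
    dt = np.inf
    for seg in tree.segments:
        a_hi = seg.area0 + seg.compliance_per_length * (p_max - tree.pref)
        c_hi = np.sqrt(a_hi * MMHG / (RHO_BLOOD * seg.compliance_per_length))
        n = max(3, int(round(seg.length / dx)) + 1)
        h = seg.length / (n - 1)
        dt = min(dt, cfl * h / (c_hi + u_max))
        if wall_damping > 0.0:
            dt = min(dt, 0.4 * h * h / wall_damping)
    return float(dt)


# --------------------------------------------------------------------------
# python-facing solver
# --------------------------------------------------------------------------

_EMPTY = np.zeros(0)
_HP_NULL = np.zeros(7)


class NetworkSolver:
    """Stateful wrapper advancing an arterial tree with a prescribed or
    ventricle-driven root inflow.

    Parameters
    ----------
    tree : ArterialTree
    dx : target grid spacing, cm
    cfl : Courant number for the automatic time step
    linearized : run the exactly linear variant of the scheme
    viscous : include the Poiseuille-type friction term
    p_init : initial uniform pressure, mmHg (defaults to tree.pref)
    """

    def __init__(self, tree: ArterialTree, dx: float = 0.5, cfl: float = 0.9,
                 dt: float | None = None, linearized: bool = False,
                 viscous: bool = True, p_init: float | None = None,
                 wall_damping: float = 0.0):
        self.tree = tree
        self.ct = CompiledTree.build(tree, dx)
        self.wall_damping = wall_damping
        self.dt = dt if dt is not None else stable_dt(tree, dx, cfl,
                                                     wall_damping=wall_damping)
        self.cfl = cfl
        self.linearized = 1 if linearized else 0
        self.fric = friction_coefficient() if viscous else 0.0
        p0 = tree.pref if p_init is None else p_init
        a0n, can = self.ct.node_arrays()
        self.A = a0n + can * (p0 - tree.pref)
        self.Q = np.zeros(self.ct.ntot)
        self._As = np.empty(self.ct.ntot)
        self._Qs = np.empty(self.ct.ntot)
        self.pc = np.array([p0 for _ in tree.leaves], dtype=float)
        self.vstate = np.zeros(1)
        self.time = 0.0

    # -- inspection ----------------------------------------------------
    def pressures(self) -> np.ndarray:
        """Per-node pressures, mmHg, in compiled node order."""
        a0n, can = self.ct.node_arrays()
        return self.tree.pref + (self.A - a0n) / can

    def segment_slice(self, sid: str) -> slice:
        s = self.ct.order.index(sid)
        return slice(int(self.ct.soff[s]), int(self.ct.soff[s] + self.ct.snn[s]))

    def network_volume(self) -> float:
        """Blood volume stored in the 1-D segments, mL (trapezoid in x)."""
        v = 0.0
        for s in range(len(self.ct.order)):
            sl = self.segment_slice(self.ct.order[s])
            a = self.A[sl]
            v += np.sum(0.5 * (a[1:] + a[:-1])) * self.ct.sdx[s]
        return float(v)

    # -- stepping ------------------------------------------------------
    def run(self, q_inlet, nsteps: int):
        """Advance ``nsteps`` with prescribed root inflow.

        ``q_inlet`` is an array of length nsteps (mL/s) or a callable of
        time.  Returns dict with per-step root pressure/flow and summed
        terminal outflow.
        """
        if callable(q_inlet):
            t = self.time + self.dt * np.arange(nsteps)
            qin = np.asarray([q_inlet(tt) for tt in t], dtype=float)
        else:
            qin = np.asarray(q_inlet, dtype=float)
            if qin.shape[0] != nsteps:
                raise ValueError("q_inlet length must equal nsteps")
        rec = {k: np.empty(nsteps) for k in
               ("P_root", "Q_root", "P_lv", "V_lv", "Q_out")}
        _run_kernel(nsteps, self.dt, self.A, self.Q, self._As, self._Qs,
                    self.ct.soff, self.ct.snn, self.ct.sdx, self.ct.szc,
                    self.ct.sa0, self.ct.sca,
                    self.ct.jparent, self.ct.jcoff, self.ct.jchild,
                    self.ct.tseg, self.ct.tz1, self.ct.tr2, self.ct.tc,
                    self.ct.tpout, self.pc,
                    self.tree.pref, self.fric, self.wall_damping,
                    self.linearized,
                    0, qin, _EMPTY, _HP_NULL, self.vstate,
                    rec["P_root"], rec["Q_root"], rec["P_lv"], rec["V_lv"],
                    rec["Q_out"])
        self.time += nsteps * self.dt
        self._check_finite()
        return rec

    def step(self, q: float):
        """Advance a single step with root inflow ``q`` (mL/s)."""
        return self.run(np.array([q]), 1)

    def run_beat(self, heart: VentricleParams, nsteps: int,
                 act: np.ndarray):
        """Advance one cardiac cycle coupled to the elastance ventricle."""
        hp = np.array([heart.Ees, heart.Vd, heart.P0, heart.beta,
                       heart.Pfill, heart.Rmitral, heart.Raortic])
        rec = {k: np.empty(nsteps) for k in
               ("P_root", "Q_root", "P_lv", "V_lv", "Q_out")}
        _run_kernel(nsteps, self.dt, self.A, self.Q, self._As, self._Qs,
                    self.ct.soff, self.ct.snn, self.ct.sdx, self.ct.szc,
                    self.ct.sa0, self.ct.sca,
                    self.ct.jparent, self.ct.jcoff, self.ct.jchild,
                    self.ct.tseg, self.ct.tz1, self.ct.tr2, self.ct.tc,
                    self.ct.tpout, self.pc,
                    self.tree.pref, self.fric, self.wall_damping,
                    self.linearized,
                    1, _EMPTY, act, hp, self.vstate,
                    rec["P_root"], rec["Q_root"], rec["P_lv"], rec["V_lv"],
                    rec["Q_out"])
        self.time += nsteps * self.dt
        self._check_finite()
        return rec

    def init_ventricle(self, heart: VentricleParams,
                       V0: float | None = None) -> None:
        self.vstate[0] = (edpvr_equilibrium_volume(heart)
                          if V0 is None else V0)

    def _check_finite(self) -> None:
        if np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.Q)):
            return
        for i, sid in enumerate(self.ct.order):
            sl = self.segment_slice(sid)
            if not (np.all(np.isfinite(self.A[sl]))
                    and np.all(np.isfinite(self.Q[sl]))):
                seg = self.tree.segment(sid)
                c = segment_wave_speed(seg)
                cfl = c * self.dt / self.ct.sdx[i]
                raise SolverInstability(
                    f"solver diverged in segment {sid!r} "
                    f"(reference CFL number {cfl:.3f}, dt={self.dt:.2e} s)")
        raise SolverInstability("solver diverged (non-finite state)")
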
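"""Arterial tree description: compliant 1-D segments + Windkessel terminals.

A tree is a single-rooted, acyclic collection of segments.  Each segment
has a reference cross-sectional area, a (linear) area compliance per unit
length, and a viscous resistance per unit length; each leaf carries a
three-element Windkessel (Z1 - proximal/characteristic resistance, R2 -
peripheral resistance, C - peripheral compliance, Pout - outflow pressure)
representing the distal vasculature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace

import yaml

from .units import MMHG, MU_BLOOD, RHO_BLOOD, ZETA

__all__ = [
    "Segment",
    "WindkesselTerminal",
    "ArterialTree",
    "total_compliance",
    "total_peripheral_resistance",
    "segment_wave_speed",
    "segment_char_impedance",
]


@dataclass(frozen=True)
class Segment:
    """One compliant vessel segment.

    length in cm, area0 (reference area at the tree's reference pressure)
    in cm^2, compliance_per_length dA/dP in cm^2/mmHg, optional
    resistance_per_length in mmHg.s/mL/cm (derived from Poiseuille flow in
    the reference lumen when omitted).  ``proximal`` flags membership of
    the proximal-aortic group targeted by banding.
    """

    id: str
    length: float
    area0: float
    compliance_per_length: float
    proximal: bool = False
    resistance_per_length: float | None = None

    def __post_init__(self) -> None:
        if self.length <= 0 or self.area0 <= 0:
            raise ValueError(f"segment {self.id}: length and area0 must be "
                             "positive")
        if self.compliance_per_length <= 0:
            raise ValueError(f"segment {self.id}: compliance_per_length "
                             "must be positive")

    @property
    def compliance(self) -> float:
        """Total segment compliance C_A * L, mL/mmHg."""
        return self.compliance_per_length * self.length

    @property
    def poiseuille_resistance_per_length(self) -> float:
        """Viscous resistance per cm from the power-law profile, mmHg.s/mL/cm."""
        return 2.0 * (ZETA + 2.0) * math.pi * MU_BLOOD / (
            self.area0 ** 2 * MMHG)

    @property
    def resistance(self) -> float:
        rpl = (self.resistance_per_length
               if self.resistance_per_length is not None
               else self.poiseuille_resistance_per_length)
        return rpl * self.length

    def replace(self, **kw) -> "Segment":
        return _dc_replace(self, **kw)


@dataclass(frozen=True)
class WindkesselTerminal:
    """Three-element Windkessel: Z1 + (R2 || C), referenced to Pout.

    R2 = 0 collapses the element to a pure resistor Z1 against Pout
    (used for reflection-free matched terminations).
    """

    Z1: float
    R2: float
    C: float
    Pout: float = 0.0

    def __post_init__(self) -> None:
        if self.Z1 < 0 or self.R2 < 0:
            raise ValueError("Windkessel resistances must be non-negative")
        if self.C <= 0:
            raise ValueError("Windkessel compliance must be positive")

    @property
    def resistance(self) -> float:
        return self.Z1 + self.R2

    def replace(self, **kw) -> "WindkesselTerminal":
        return _dc_replace(self, **kw)


def segment_wave_speed(segment: Segment) -> float:
    """Pulse wave speed sqrt(A0 / (rho * C_A)) in cm/s.

    C_A is converted from cm^2/mmHg to CGS so the speed is dynamically
    consistent; speed falls with the square root of compliance.
    """
    ca_cgs = segment.compliance_per_length / MMHG
    return math.sqrt(segment.area0 / (RHO_BLOOD * ca_cgs))


def segment_char_impedance(segment: Segment) -> float:
    """Characteristic impedance rho*c/A0, in mmHg.s/mL."""
    return RHO_BLOOD * segment_wave_speed(segment) / (segment.area0 * MMHG)


@dataclass
class ArterialTree:
    """Segments + connectivity + terminal Windkessels.

    ``children`` maps a segment id to the ids fed by its distal end; ids
    absent from the map (or mapped to []) are leaves and must appear in
    ``terminals``.  ``pref`` is the reference pressure (mmHg) at which
    every segment has area area0.
    """

    segments: list[Segment]
    children: dict[str, list[str]] = field(default_factory=dict)
    terminals: dict[str, WindkesselTerminal] = field(default_factory=dict)
    pref: float = 75.0

    def __post_init__(self) -> None:
        self.validate()

    # -- structure -----------------------------------------------------
    def segment(self, sid: str) -> Segment:
        return self._by_id[sid]

    @property
    def root(self) -> Segment:
        return self._by_id[self._root_id]

    @property
    def leaves(self) -> list[str]:
        return [s.id for s in self.segments if not self.children.get(s.id)]

    def parent_of(self, sid: str) -> str | None:
        for p, kids in self.children.items():
            if sid in kids:
                return p
        return None

    def validate(self) -> None:
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate segment ids")
        self._by_id = {s.id: s for s in self.segments}
        child_ids = [c for kids in self.children.values() for c in kids]
        if len(set(child_ids)) != len(child_ids):
            raise ValueError("a segment has two parents (not a tree)")
        for p, kids in self.children.items():
            if p not in self._by_id:
                raise ValueError(f"unknown parent id {p!r}")
            for c in kids:
                if c not in self._by_id:
                    raise ValueError(f"unknown child id {c!r}")
        roots = [i for i in ids if i not in child_ids]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, got {roots}")
        self._root_id = roots[0]
        # connectivity / acyclicity: walk from the root
        seen: set[str] = set()
        stack = [self._root_id]
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise ValueError("cycle detected in tree topology")
            seen.add(sid)
            stack.extend(self.children.get(sid, []))
        if seen != set(ids):
            raise ValueError("tree is not connected")
        for leaf in self.leaves:
            if leaf not in self.terminals:
                raise ValueError(f"leaf segment {leaf!r} has no terminal "
                                 "Windkessel")

    # -- aggregate properties ------------------------------------------
    def total_compliance(self) -> float:
        return total_compliance(self)

    def total_peripheral_resistance(self) -> float:
        return total_peripheral_resistance(self)

    def replace_segment(self, sid: str, new: Segment) -> "ArterialTree":
        segs = [new if s.id == sid else s for s in self.segments]
        return ArterialTree(segs, dict(self.children), dict(self.terminals),
                            self.pref)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "pref": self.pref,
            "segments": [
                {
                    "id": s.id,
                    "length": float(s.length),
                    "area0": float(s.area0),
                    "compliance_per_length": float(s.compliance_per_length),
                    "proximal": bool(s.proximal),
                    **({"resistance_per_length":
                        float(s.resistance_per_length)}
                       if s.resistance_per_length is not None else {}),
                }
                for s in self.segments
            ],
            "children": {k: list(v) for k, v in self.children.items() if v},
            "terminals": {
                k: {"Z1": float(t.Z1), "R2": float(t.R2),
                    "C": float(t.C), "Pout": float(t.Pout)}
                for k, t in self.terminals.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArterialTree":
        segs = [Segment(**s) for s in d["segments"]]
        terms = {k: WindkesselTerminal(**t)
                 for k, t in d.get("terminals", {}).items()}
        return cls(segs, dict(d.get("children", {})), terms,
                   float(d.get("pref", 75.0)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ArterialTree":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def total_compliance(tree: ArterialTree) -> float:
    """Total arterial compliance CT: segment compliances + terminal C, mL/mmHg."""
    return (sum(s.compliance for s in tree.segments)
            + sum(t.C for t in tree.terminals.values()))


def total_peripheral_resistance(tree: ArterialTree) -> float:
    """DC input resistance of the tree seen from the root, mmHg.s/mL.

    Series viscous segment resistances combined with the parallel
    reduction of the branches; each terminal contributes Z1 + R2.
    """

    def subtree(sid: str) -> float:
        seg = tree.segment(sid)
        kids = tree.children.get(sid, [])
        if not kids:
            return seg.resistance + tree.terminals[sid].resistance
        g = sum(1.0 / subtree(c) for c in kids)
        return seg.resistance + 1.0 / g

    return subtree(tree.root.id)
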
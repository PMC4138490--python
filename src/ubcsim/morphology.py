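"""Compartmental morphology of the unipolar brush cell (UBC).

The canonical cell is a 13-compartment chain: a dendritic brush and shaft,
a spherical soma, five axon-initial-segment (AIS) compartments of
decreasing diameter, and five identical axonal compartments.  A recording
pipette (series access resistance, sealed end, no capacitance) can be
attached to the soma for voltage-clamp protocols.

Geometry is stored in um; membrane areas are reported in um^2 and
converted to cm^2 (1 um^2 = 1e-8 cm^2) where absolute conductances or
capacitances are needed.  Each compartment carries a dimensionless
``area_scale`` so that effective membrane area (hence capacitance and
total channel conductance) can be calibrated independently of the axial
geometry — the brush membrane of a real UBC is folded into dendrioles and
its effective area exceeds the plain cylinder area, while the effective
axonal area is smaller than its nominal geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Compartment",
    "PipetteModel",
    "Morphology",
    "membrane_area",
    "axial_resistance",
    "axial_conductance",
    "build_canonical_ubc",
]

_SHAPES = ("sphere", "cylinder", "frustum")


@dataclass
class Compartment:
    """One electrical compartment.

    Parameters
    ----------
    name
        Unique identifier within the morphology.
    shape
        ``sphere`` (length unused), ``cylinder``, or ``frustum``
        (truncated cone; ``diameter`` proximal, ``diameter_distal`` distal).
    length, diameter, diameter_distal
        Geometry in um.
    axial_resistivity
        Cytoplasmic resistivity Ra, ohm*cm.
    specific_capacitance
        Cm, uF/cm^2.
    channel_densities
        Map mechanism name -> maximum conductance density (S/cm^2), or
        permeability (cm/s) for GHK mechanisms.
    area_scale
        Effective-area multiplier applied to membrane area (capacitance
        and channel totals); does not affect axial coupling.
    end_caps
        Include the flat end-cap areas of a cylinder in its membrane area.
    """

    name: str
    shape: str = "cylinder"
    length: float = 0.0
    diameter: float = 1.0
    diameter_distal: float | None = None
    axial_resistivity: float = 100.0
    specific_capacitance: float = 1.0
    channel_densities: dict[str, float] = field(default_factory=dict)
    area_scale: float = 1.0
    end_caps: bool = False

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.diameter <= 0:
            raise ValueError(f"{self.name}: diameter must be > 0")
        if self.length < 0:
            raise ValueError(f"{self.name}: length must be >= 0")
        if self.shape != "sphere" and self.length == 0 and self.shape == "frustum":
            raise ValueError(f"{self.name}: frustum needs length > 0")
        if any(g < 0 for g in self.channel_densities.values()):
            raise ValueError(f"{self.name}: channel densities must be >= 0")

    @property
    def effective_area_um2(self) -> float:
        """Membrane area (um^2) after applying the area scale."""
        return membrane_area(self) * self.area_scale

    @property
    def capacitance_pF(self) -> float:
        """Membrane capacitance in pF (1 uF/cm^2 == 0.01 pF/um^2)."""
        return self.effective_area_um2 * self.specific_capacitance * 0.01


@dataclass
class PipetteModel:
    """Recording pipette: sealed end, zero wall capacitance, infinite wall
    resistance — electrically just a series access resistance (Mohm)."""

    access_resistance: float = 20.0

    def __post_init__(self) -> None:
        if self.access_resistance <= 0:
            raise ValueError("access_resistance must be > 0")


@dataclass
class Morphology:
    """A tree of compartments (soma-rooted; the canonical UBC is a chain)."""

    compartments: list[Compartment]
    parents: dict[str, str | None]
    pipette: PipetteModel | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate compartment names")
        roots = [n for n, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise ValueError("morphology must have exactly one root")
        # tree check: every node reaches the root without cycles
        for n in names:
            seen = set()
            while n is not None:
                if n in seen:
                    raise ValueError("connectivity contains a cycle")
                seen.add(n)
                n = self.parents[n]

    @property
    def root(self) -> str:
        return next(n for n, p in self.parents.items() if p is None)

    def __getitem__(self, name: str) -> Compartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compartments]

    def total_capacitance_pF(self) -> float:
        return sum(c.capacitance_pF for c in self.compartments)

    def to_dict(self) -> dict:
        comps = []
        for c in self.compartments:
            d = {
                "name": c.name,
                "shape": c.shape,
                "length": c.length,
                "diameter": c.diameter,
                "parent": self.parents[c.name],
                "area_scale": c.area_scale,
                "channel_densities": dict(c.channel_densities),
            }
            if c.diameter_distal is not None:
                d["diameter_distal"] = c.diameter_distal
            comps.append(d)
        out = {"compartments": comps}
        if self.pipette is not None:
            out["pipette"] = {"access_resistance": self.pipette.access_resistance}
        return out

    @classmethod
    def from_dict(
        cls,
        data: dict,
        axial_resistivity: float = 100.0,
        specific_capacitance: float = 1.0,
    ) -> "Morphology":
        comps, parents = [], {}
        for d in data["compartments"]:
            comps.append(
                Compartment(
                    name=d["name"],
                    shape=d.get("shape", "cylinder"),
                    length=d.get("length", 0.0),
                    diameter=d["diameter"],
                    diameter_distal=d.get("diameter_distal"),
                    axial_resistivity=axial_resistivity,
                    specific_capacitance=specific_capacitance,
                    channel_densities=dict(d.get("channel_densities", {})),
                    area_scale=d.get("area_scale", 1.0),
                )
            )
            parents[d["name"]] = d.get("parent")
        pip = None
        if "pipette" in data:
            pip = PipetteModel(access_resistance=data["pipette"]["access_resistance"])
        return cls(compartments=comps, parents=parents, pipette=pip)


def membrane_area(comp: Compartment) -> float:
    """Geometric membrane area in um^2 (before the area scale).

    sphere: pi d^2; cylinder: pi d L (+ end caps if requested);
    frustum: lateral surface of the truncated cone.
    """
    d = comp.diameter
    if comp.shape == "sphere":
        return math.pi * d * d
    if comp.shape == "cylinder":
        a = math.pi * d * comp.length
        if comp.end_caps:
            a += 2.0 * math.pi * (d / 2.0) ** 2
        return a
    r1 = d / 2.0
    r2 = (comp.diameter_distal if comp.diameter_distal is not None else d) / 2.0
    if r2 <= 0:
        raise ValueError(f"{comp.name}: distal diameter must be > 0")
    slant = math.hypot(comp.length, r1 - r2)
    return math.pi * (r1 + r2) * slant


def _half_axial_resistance_Mohm(comp: Compartment) -> float:
    """Axial resistance (Mohm) of half the compartment, from its center to
    its end.  Spheres are iso-potential nodes (zero internal resistance)."""
    if comp.shape == "sphere":
        return 0.0
    if comp.diameter <= 0:
        raise ValueError(f"{comp.name}: zero diameter")
    L_cm = comp.length * 1e-4 / 2.0
    if comp.shape == "cylinder":
        r_cm = comp.diameter / 2.0 * 1e-4
        area = math.pi * r_cm * r_cm
    else:  # frustum: use half the cone from proximal radius to mid radius
        r1 = comp.diameter / 2.0 * 1e-4
        r2 = (comp.diameter_distal if comp.diameter_distal is not None else comp.diameter) / 2.0 * 1e-4
        rm = 0.5 * (r1 + r2)
        area = math.pi * r1 * rm  # R = Ra L /(pi r1 r2) for a cone segment
    return comp.axial_resistivity * L_cm / area / 1e6


def axial_resistance(comp: Compartment) -> float:
    """Full-section axial resistance in Mohm (Ra * L / (pi r^2))."""
    return 2.0 * _half_axial_resistance_Mohm(comp)


def axial_conductance(child: Compartment, parent: Compartment) -> float:
    """Coupling conductance (uS) between the centers of two connected
    compartments: series combination of the two half-compartment axial
    resistances.  Ra -> 0 gives an infinite (iso-potential) coupling."""
    r = _half_axial_resistance_Mohm(child) + _half_axial_resistance_Mohm(parent)
    if r <= 0.0:
        return math.inf
    return 1.0 / r  # 1/Mohm == uS


# ---------------------------------------------------------------------------
# canonical build

#: AIS diameters, um — linear steps between the reported 3.2 and 0.8 um
AIS_DIAMETERS = (3.2, 2.6, 2.0, 1.4, 0.8)

#: capacitance split reported for the canonical cell, pF
CAP_SOMA, CAP_DEND, CAP_AXON = 2.0, 12.7, 2.0


def _canonical_area_scales() -> tuple[float, float, float]:
    """Area scales for (soma, brush, axon+AIS) reproducing the 2 / 12.7 / 2
    pF capacitance split at Cm = 1 uF/cm^2.  The shaft keeps scale 1; the
    brush absorbs the dendritic correction (its membrane is folded into
    dendrioles, so its effective area exceeds the plain cylinder)."""
    a_soma = math.pi * 8.0**2
    a_shaft = math.pi * 2.0 * 50.0
    a_brush = math.pi * 10.0 * 25.25
    a_axon = 5 * math.pi * 0.5 * 80.0 + sum(math.pi * d * 0.5 for d in AIS_DIAMETERS)
    s_soma = CAP_SOMA * 100.0 / a_soma  # 1 pF == 100 um^2 at 1 uF/cm^2
    s_brush = (CAP_DEND * 100.0 - a_shaft) / a_brush
    s_axon = CAP_AXON * 100.0 / a_axon
    return s_soma, s_brush, s_axon


def build_canonical_ubc(
    channel_densities: dict[str, dict[str, float]] | None = None,
    axial_resistivity: float = 100.0,
    specific_capacitance: float = 1.0,
    pipette_access_resistance: float = 20.0,
) -> Morphology:
    """Build the canonical 13-compartment UBC morphology.

    Parameters
    ----------
    channel_densities
        Map compartment-name -> {mechanism -> density}; by default the
        densities of the packaged canonical model are used.
    """
    if channel_densities is None:
        from .model import canonical_densities

        channel_densities = canonical_densities()
    s_soma, s_brush, s_axon = _canonical_area_scales()

    def comp(name, shape, length, diameter, scale):
        return Compartment(
            name=name,
            shape=shape,
            length=length,
            diameter=diameter,
            axial_resistivity=axial_resistivity,
            specific_capacitance=specific_capacitance,
            channel_densities=dict(channel_densities.get(name, {})),
            area_scale=scale,
        )

    comps = [
        comp("brush", "cylinder", 25.25, 10.0, s_brush),
        comp("shaft", "cylinder", 50.0, 2.0, 1.0),
        comp("soma", "sphere", 0.0, 8.0, s_soma),
    ]
    parents: dict[str, str | None] = {"brush": "shaft", "shaft": "soma", "soma": None}
    prev = "soma"
    for i, d in enumerate(AIS_DIAMETERS, start=1):
        name = f"ais{i}"
        comps.append(comp(name, "cylinder", 0.5, d, s_axon))
        parents[name] = prev
        prev = name
    for i in range(1, 6):
        name = f"axon{i}"
        comps.append(comp(name, "cylinder", 80.0, 0.5, s_axon))
        parents[name] = prev
        prev = name
    return Morphology(
        compartments=comps,
        parents=parents,
        pipette=PipetteModel(access_resistance=pipette_access_resistance),
    )


def chain_order(morph: Morphology) -> list[str]:
    """Order compartments so that the coupling matrix is tridiagonal.

    The canonical UBC is an unbranched chain through the soma
    (brush - shaft - soma - ais1..5 - axon1..5); a depth-first ordering of
    any chain-topology tree yields a tridiagonal Hines matrix.
    """
    children: dict[str, list[str]] = {n: [] for n in morph.names}
    for n, p in morph.parents.items():
        if p is not None:
            children[p].append(n)
    root = morph.root
    if len(children[root]) > 2 or any(
        len(children[n]) > 1 for n in morph.names if n != root
    ):
        raise ValueError("morphology is not a chain through the root")
    order: list[str] = []
    kids = children[root]
    if kids:
        # walk the first branch outward, reverse it, then root, then 2nd branch
        branch: list[str] = []
        n = kids[0]
        while True:
            branch.append(n)
            nxt = children[n]
            if not nxt:
                break
            n = nxt[0]
        order.extend(reversed(branch))
    order.append(root)
    if len(kids) == 2:
        n = kids[1]
        while True:
            order.append(n)
            nxt = children[n]
            if not nxt:
                break
            n = nxt[0]
    return order


def coupling_matrix(morph: Morphology, order: list[str] | None = None):
    """Symmetric axial coupling conductances (uS) in ``order``; returns
    (order, lower-diagonal array g[i] coupling node i to node i-1)."""
    if order is None:
        order = chain_order(morph)
    g = np.zeros(len(order))
    for i in range(1, len(order)):
        a, b = morph[order[i]], morph[order[i - 1]]
        pa = morph.parents[a.name]
        pb = morph.parents[b.name]
        if pa == b.name or pb == a.name:
            g[i] = axial_conductance(a, b)
        else:
            raise ValueError("order is not a chain ordering")
    return order, g
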
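"""Reduced arterial-tree model.

A rooted tree of elastic segments (transmission lines) terminated by
two-element Windkessels, with named measurement sites. The tree is the
generator of pressure/flow waveforms and of the analytic ground truth:

* aortic characteristic impedance  Z_ao = sqrt(rho / (A * C_A))  evaluated at
  the aortic root (water-hammer relation; A cross-sectional area, C_A area
  compliance per unit length),
* total arterial compliance  C_T = sum of segmental volume compliances
  (C_A * length) plus the terminal Windkessel compliances.

The default topology is a 13-segment reduction of a full anatomical tree:
the aorta (ascending, two arch pieces, thoracic, abdominal), left iliac and
femoral, left common carotid, left subclavian/brachial/radial, plus lumped
brachiocephalic (right-side) and visceral beds. It is the smallest tree that
contains the five clinical measurement sites and distinct carotid-femoral and
carotid-radial transmission paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .units import BLOOD_DENSITY, csi_to_clinical, zsi_to_clinical

SITE_NAMES = ("aortic_root", "brachial_L", "carotid_L", "radial_L", "femoral_L")


@dataclass
class ArterialSegment:
    """One elastic segment (uniform lossless transmission line).

    Parameters are SI: length [m], lumen_area [m^2], area_compliance
    [m^2/Pa] (area change per unit pressure, per unit length of vessel).
    """

    name: str
    length: float
    lumen_area: float
    area_compliance: float
    parent: str | None = None

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"segment {self.name}: length must be > 0")
        if self.lumen_area <= 0:
            raise ValueError(f"segment {self.name}: lumen_area must be > 0")
        if self.area_compliance <= 0:
            raise ValueError(f"segment {self.name}: area_compliance must be > 0")

    @property
    def wave_speed(self) -> float:
        """Pulse wave speed c = sqrt(A / (rho * C_A)) [m/s]."""
        return math.sqrt(self.lumen_area / (BLOOD_DENSITY * self.area_compliance))

    @property
    def volume_compliance(self) -> float:
        """Volume compliance c_i = C_A * length [m^3/Pa]."""
        return self.area_compliance * self.length

    @property
    def characteristic_impedance(self) -> float:
        """Z_c = rho * c / A [Pa s/m^3]."""
        return BLOOD_DENSITY * self.wave_speed / self.lumen_area


@dataclass
class TerminalWindkessel:
    """Two-element Windkessel load (R parallel C) closing a leaf segment."""

    attached_segment: str
    resistance: float  # Pa s/m^3
    compliance: float  # m^3/Pa

    def __post_init__(self):
        if self.resistance <= 0:
            raise ValueError(f"terminal at {self.attached_segment}: resistance must be > 0")
        if self.compliance < 0:
            raise ValueError(f"terminal at {self.attached_segment}: compliance must be >= 0")

    def impedance(self, omega: float | np.ndarray) -> complex | np.ndarray:
        return self.resistance / (1.0 + 1j * omega * self.resistance * self.compliance)


@dataclass
class CardiacInflow:
    """Ventricular ejection wave imposed at the aortic root.

    Shapes: 'asymmetric' (default) — half-cosine rise over the first 20% of
    ejection followed by a half-cosine fall, mimicking the rapid acceleration
    and slower deceleration of ventricular outflow; 'half-sine'; 'triangular'.
    Stroke volume is prescribed; ejection duration is expressed as a fraction
    of the cardiac period.
    """

    heart_rate: float          # beats/min
    stroke_volume: float       # mL
    ejection_fraction_of_period: float
    waveform_shape: str = "asymmetric"
    rise_fraction: float = 0.2  # asymmetric shape: fraction of ejection spent rising

    def __post_init__(self):
        if not (20.0 <= self.heart_rate <= 200.0):
            raise ValueError("heart rate out of range [20, 200] bpm")
        if self.stroke_volume <= 0:
            raise ValueError("stroke volume must be > 0")
        if not (0.0 < self.ejection_fraction_of_period < 1.0):
            raise ValueError("ejection fraction must be in (0, 1)")
        if self.waveform_shape not in ("asymmetric", "half-sine", "triangular"):
            raise ValueError(f"unknown waveform shape {self.waveform_shape!r}")
        if not (0.0 < self.rise_fraction < 1.0):
            raise ValueError("rise_fraction must be in (0, 1)")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def ejection_time(self) -> float:
        return self.ejection_fraction_of_period * self.period

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Flow [m^3/s] at times t (one period, t in [0, T))."""
        sv = self.stroke_volume * 1e-6  # m^3
        ts = self.ejection_time
        q = np.zeros_like(t, dtype=float)
        eject = t < ts
        if self.waveform_shape == "asymmetric":
            tp = self.rise_fraction * ts
            qmax = 2.0 * sv / ts  # integral of the two half-cosine lobes = qmax*ts/2
            up = eject & (t < tp)
            down = eject & (t >= tp)
            q[up] = qmax * (1.0 - np.cos(math.pi * t[up] / tp)) / 2.0
            q[down] = qmax * (1.0 + np.cos(math.pi * (t[down] - tp) / (ts - tp))) / 2.0
        elif self.waveform_shape == "half-sine":
            qmax = math.pi * sv / (2.0 * ts)
            q[eject] = qmax * np.sin(math.pi * t[eject] / ts)
        else:  # triangular, peak at ts/3
            qmax = 2.0 * sv / ts
            tp = ts / 3.0
            up = eject & (t <= tp)
            down = eject & (t > tp)
            q[up] = qmax * t[up] / tp
            q[down] = qmax * (ts - t[down]) / (ts - tp)
        return q


def default_ejection_fraction(heart_rate: float) -> float:
    """Systolic duration 0.33*sqrt(T) seconds, expressed as a period fraction."""
    period = 60.0 / heart_rate
    return min(0.33 * math.sqrt(period) / period, 0.55)


@dataclass
class ArterialTreeModel:
    """Rooted tree of segments + terminal loads + named measurement sites."""

    segments: dict[str, ArterialSegment]
    terminals: list[TerminalWindkessel]
    sites: dict[str, tuple[str, float]]
    blood_density: float = BLOOD_DENSITY
    _children: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._children = {name: [] for name in self.segments}
        roots = []
        for seg in self.segments.values():
            if seg.parent is None:
                roots.append(seg.name)
            else:
                if seg.parent not in self.segments:
                    raise ValueError(f"segment {seg.name}: unknown parent {seg.parent}")
                self._children[seg.parent].append(seg.name)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        self._root = roots[0]
        # acyclicity / connectivity: walk from root and count
        seen: set[str] = set()
        stack = [self._root]
        while stack:
            s = stack.pop()
            if s in seen:
                raise ValueError("cycle detected in tree")
            seen.add(s)
            stack.extend(self._children[s])
        if seen != set(self.segments):
            raise ValueError("tree is not connected")
        term_map = {t.attached_segment: t for t in self.terminals}
        if len(term_map) != len(self.terminals):
            raise ValueError("more than one terminal on a segment")
        for name, kids in self._children.items():
            if not kids and name not in term_map:
                raise ValueError(f"leaf segment {name} has no terminal Windkessel")
        for site, (seg, frac) in self.sites.items():
            if seg not in self.segments:
                raise ValueError(f"site {site} refers to unknown segment {seg}")
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"site {site}: fractional position must be in [0, 1]")
        self._terminal_map = term_map

    # -- structure ----------------------------------------------------------
    @property
    def root(self) -> ArterialSegment:
        return self.segments[self._root]

    def children(self, name: str) -> list[str]:
        return self._children[name]

    def terminal(self, name: str) -> TerminalWindkessel | None:
        return self._terminal_map.get(name)

    def ancestors(self, name: str) -> list[str]:
        """Chain of segment names from `name` up to (and including) the root."""
        chain = [name]
        while self.segments[chain[-1]].parent is not None:
            chain.append(self.segments[chain[-1]].parent)
        return chain

    def depth_to_inlet(self, name: str) -> float:
        """Path length from the root inlet to the inlet of segment `name`."""
        d = 0.0
        for anc in self.ancestors(name)[1:]:
            d += self.segments[anc].length
        return d

    # -- ground truth -------------------------------------------------------
    def total_peripheral_resistance(self) -> float:
        """Parallel combination of terminal resistances [Pa s/m^3]."""
        return 1.0 / sum(1.0 / t.resistance for t in self.terminals)


def compute_zao(tree: ArterialTreeModel) -> float:
    """Aortic characteristic impedance, water-hammer form, in mmHg·s/mL.

    Z_ao = sqrt(rho / (A * C_A)) at the aortic root.
    """
    root = tree.root
    if root.lumen_area <= 0 or root.area_compliance <= 0:
        raise ValueError("root area and compliance must be positive")
    z_si = math.sqrt(tree.blood_density / (root.lumen_area * root.area_compliance))
    return zsi_to_clinical(z_si)


def compute_ct(tree: ArterialTreeModel) -> float:
    """Total arterial compliance in mL/mmHg.

    Sum of segmental volume compliances plus terminal Windkessel compliances.
    """
    c_si = sum(s.volume_compliance for s in tree.segments.values())
    c_si += sum(t.compliance for t in tree.terminals)
    return csi_to_clinical(c_si)


def travel_length(tree: ArterialTreeModel, site_a: str, site_b: str) -> float:
    """Length [m] of the unique tree path between two named sites.

    Sum of segment lengths (and partial lengths at the site segments) along
    the path through the sites' nearest common ancestor.
    """
    for s in (site_a, site_b):
        if s not in tree.sites:
            raise KeyError(f"unknown site {s!r}")
    seg_a, frac_a = tree.sites[site_a]
    seg_b, frac_b = tree.sites[site_b]
    la = tree.segments[seg_a].length
    lb = tree.segments[seg_b].length
    if seg_a == seg_b:
        return abs(frac_a - frac_b) * la
    anc_a = tree.ancestors(seg_a)
    anc_b = tree.ancestors(seg_b)
    # distance from root inlet to each site
    da = tree.depth_to_inlet(seg_a) + frac_a * la
    db = tree.depth_to_inlet(seg_b) + frac_b * lb
    if seg_b in anc_a:  # b's segment is an ancestor of a's
        return da - (tree.depth_to_inlet(seg_b) + frac_b * lb) if da >= db else db - da
    if seg_a in anc_b:
        return abs(db - da)
    common = next(s for s in anc_a if s in set(anc_b))
    d_junction = tree.depth_to_inlet(common) + tree.segments[common].length
    return (da - d_junction) + (db - d_junction)
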
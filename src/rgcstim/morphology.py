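"""Retinal ganglion cell morphologies: SWC I/O, synthetic generation, edits.

A morphology is a tree of straight cylindrical sections with region labels
(``dendrite``, ``soma``, ``hillock``, ``ais``, ``axon``).  The coordinate
convention places the retina in the x-y plane with the somatic center of the
focal cell at the origin; +z points toward the vitreous, where the stimulating
electrode sits (all electrode heights are positive z).

The soma is a cylinder of length equal to its diameter, whose lateral area
``pi*d**2`` equals the surface area of the equivalent sphere.  The axon hillock
is the first 50 um of axon leaving the soma and the axon initial segment (AIS)
spans path distances 25-75 um from the somatic center; where the two
definitions overlap the AIS label wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "SegmentedCell",
    "MorphologyError",
    "read_swc",
    "write_swc",
    "soma_cylinder",
    "generate_rgc",
    "extend_axon",
    "edit_remove_dendrites",
    "edit_shift_proximal_axon",
    "segmentize",
]

REGIONS = ("dendrite", "soma", "hillock", "ais", "axon")
AXONAL = ("hillock", "ais", "axon")

#: hillock spans the first HILLOCK_LEN um of axonal arc from the soma
HILLOCK_LEN = 50.0
#: AIS spans [AIS_START, AIS_END] um of path distance from the somatic center
AIS_START, AIS_END = 25.0, 75.0

_SWC_TYPE_TO_REGION = {1: "soma", 2: "axon", 3: "dendrite", 4: "dendrite"}
_REGION_TO_SWC = {"soma": 1, "axon": 2, "hillock": 2, "ais": 2, "dendrite": 3}


class MorphologyError(ValueError):
    """Structural or format error in a morphology or SWC file."""


@dataclass
class Section:
    """One straight cylindrical neurite piece.

    ``parent`` is the id of the parent section (-1 for the root soma); the
    section runs from ``p0`` to ``p1`` (um) with constant ``diameter`` (um).
    """

    id: int
    region: str
    parent: int
    p0: np.ndarray
    p1: np.ndarray
    diameter: float

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    @property
    def area(self) -> float:
        """Lateral membrane area in um^2."""
        return math.pi * self.diameter * self.length

    def copy(self) -> "Section":
        return Section(self.id, self.region, self.parent,
                       self.p0.copy(), self.p1.copy(), self.diameter)


@dataclass
class Morphology:
    """Tree of sections; exactly one root, which must be the soma."""

    sections: list = field(default_factory=list)
    somatic_center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.somatic_center = np.asarray(self.somatic_center, dtype=float)
        self._index = {s.id: s for s in self.sections}

    # -- structure ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.sections)

    def section(self, sid: int) -> Section:
        return self._index[sid]

    @property
    def root(self) -> Section:
        roots = [s for s in self.sections if s.parent < 0]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        return roots[0]

    def children(self, sid: int) -> list:
        return [s for s in self.sections if s.parent == sid]

    def validate(self) -> None:
        root = self.root
        if root.region != "soma":
            raise MorphologyError("root section must be the soma")
        if abs(root.length - root.diameter) > 1e-6:
            raise MorphologyError("soma must be a cylinder with length == diameter")
        for s in self.sections:
            if s.diameter <= 0:
                raise MorphologyError(f"section {s.id} has non-positive diameter")
            if s.parent >= 0 and s.parent not in self._index:
                raise MorphologyError(f"section {s.id} references missing parent {s.parent}")
        # cycle check via iterative parent walk
        for s in self.sections:
            seen = set()
            cur = s
            while cur.parent >= 0:
                if cur.id in seen:
                    raise MorphologyError("parent links contain a cycle")
                seen.add(cur.id)
                cur = self._index[cur.parent]

    def topological_order(self) -> list:
        """Sections ordered root-first (every parent before its children)."""
        order, stack = [], [self.root]
        kids = {}
        for s in self.sections:
            kids.setdefault(s.parent, []).append(s)
        while stack:
            s = stack.pop()
            order.append(s)
            stack.extend(sorted(kids.get(s.id, []), key=lambda c: c.id, reverse=True))
        if len(order) != len(self.sections):
            raise MorphologyError("tree is disconnected or cyclic")
        return order

    # -- measurements ------------------------------------------------------
    def axon_arc_of(self) -> dict:
        """Arc distance (um) from the soma junction to each axonal section start."""
        arcs = {}
        for s in self.topological_order():
            if s.region not in AXONAL:
                continue
            parent = self._index.get(s.parent)
            if parent is not None and parent.region in AXONAL:
                arcs[s.id] = arcs[parent.id] + parent.length
            else:
                arcs[s.id] = 0.0
        return arcs

    def axon_path_length(self) -> float:
        arcs = self.axon_arc_of()
        if not arcs:
            return 0.0
        return max(arcs[sid] + self._index[sid].length for sid in arcs)

    def axon_polyline(self) -> np.ndarray:
        """Ordered (n, 3) points tracing the main axonal path from the soma."""
        axonal = [s for s in self.sections if s.region in AXONAL]
        if not axonal:
            return np.empty((0, 3))
        arcs = self.axon_arc_of()
        ordered = sorted(axonal, key=lambda s: arcs[s.id])
        pts = [ordered[0].p0] + [s.p1 for s in ordered]
        return np.asarray(pts)

    def dendritic_field_diameter(self) -> float:
        """Max pairwise in-plane distance over dendritic section endpoints."""
        pts = [s.p1[:2] for s in self.sections if s.region == "dendrite"]
        if len(pts) < 2:
            return 0.0
        pts = np.asarray(pts)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        return float(np.sqrt(d2.max()))

    def relabel_axon(self) -> None:
        """Assign hillock/AIS/axon labels from path distance (in place)."""
        arcs = self.axon_arc_of()
        if not arcs:
            return
        # offset from somatic center to the axon root attachment point
        first = min(arcs, key=arcs.get)
        offset = float(np.linalg.norm(self._index[first].p0 - self.somatic_center))
        for sid, arc in arcs.items():
            s = self._index[sid]
            mid = arc + 0.5 * s.length
            from_center = offset + mid
            if AIS_START <= from_center <= AIS_END:
                s.region = "ais"
            elif mid <= HILLOCK_LEN:
                s.region = "hillock"
            else:
                s.region = "axon"

    # -- transforms --------------------------------------------------------
    def copy(self) -> "Morphology":
        return Morphology([s.copy() for s in self.sections], self.somatic_center.copy())

    def translated(self, dx: float, dy: float, dz: float = 0.0) -> "Morphology":
        m = self.copy()
        shift = np.array([dx, dy, dz])
        for s in m.sections:
            s.p0 += shift
            s.p1 += shift
        m.somatic_center = m.somatic_center + shift
        return m


# ---------------------------------------------------------------------------
# SWC I/O (standard 7-column dialect)
# ---------------------------------------------------------------------------

def read_swc(path) -> Morphology:
    """Read a 7-column SWC file into a :class:`Morphology`.

    SWC type codes map 1=soma, 2=axon, 3/4=dendrite; hillock and AIS are
    derived labels assigned afterwards by path distance, since SWC has no
    code for them.  The soma may be given as 1, 2 or 3 points; it is
    reconstructed as a cylinder in all cases.
    """
    nodes = {}
    order = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise MorphologyError(f"{path}:{lineno}: expected 7 columns")
            nid, typ = int(parts[0]), int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            par = int(parts[6])
            if nid in nodes:
                raise MorphologyError(f"{path}:{lineno}: duplicate node id {nid}")
            nodes[nid] = (typ, np.array([x, y, z]), r, par)
            order.append(nid)
    if not nodes:
        raise MorphologyError(f"{path}: empty SWC file")
    for nid in order:
        par = nodes[nid][3]
        if par != -1 and par not in nodes:
            raise MorphologyError(f"node {nid} references undefined parent {par}")
    # cycle detection
    for nid in order:
        seen = set()
        cur = nid
        while cur != -1:
            if cur in seen:
                raise MorphologyError("SWC parent links contain a cycle")
            seen.add(cur)
            cur = nodes[cur][3]

    soma_ids = [nid for nid in order if nodes[nid][0] == 1]
    if not soma_ids:
        raise MorphologyError("SWC file has no soma node")
    soma_pts = np.array([nodes[nid][1] for nid in soma_ids])
    soma_r = nodes[soma_ids[0]][2]
    d = 2.0 * soma_r
    if len(soma_ids) == 1:
        center = soma_pts[0]
        p0 = center - np.array([d / 2, 0, 0])
        p1 = center + np.array([d / 2, 0, 0])
    else:
        # outermost pair of soma points define the cylinder axis
        i, j = 0, len(soma_pts) - 1
        best = -1.0
        for a in range(len(soma_pts)):
            for b in range(a + 1, len(soma_pts)):
                dist = np.linalg.norm(soma_pts[a] - soma_pts[b])
                if dist > best:
                    best, i, j = dist, a, b
        p0, p1 = soma_pts[i], soma_pts[j]
        center = 0.5 * (p0 + p1)

    sections = [Section(0, "soma", -1, p0, p1, d)]
    sec_of_node = {nid: 0 for nid in soma_ids}
    next_id = 1
    for nid in order:
        typ, pt, r, par = nodes[nid]
        if typ == 1:
            continue
        region = _SWC_TYPE_TO_REGION.get(typ, "dendrite")
        if par == -1:
            raise MorphologyError(f"non-soma node {nid} cannot be the root")
        if par in soma_ids:
            start = nodes[par][1]
            parent_sec = 0
        else:
            if nodes[par][0] == 1:  # pragma: no cover - handled above
                start, parent_sec = nodes[par][1], 0
            else:
                start = nodes[par][1]
                parent_sec = sec_of_node[par]
        sections.append(Section(next_id, region, parent_sec, start, pt, 2.0 * r))
        sec_of_node[nid] = next_id
        next_id += 1

    m = Morphology(sections, center)
    m.relabel_axon()
    return m


def write_swc(m: Morphology, path) -> None:
    """Write a morphology as standard 7-column SWC (3-point soma)."""
    root = m.root
    lines = ["# SWC written by rgcstim"]
    center = 0.5 * (root.p0 + root.p1)
    r = root.diameter / 2.0

    def fmt(nid, typ, pt, rad, par):
        return (f"{nid} {typ} {pt[0]:.9g} {pt[1]:.9g} {pt[2]:.9g} "
                f"{rad:.9g} {par}")

    lines.append(fmt(1, 1, center, r, -1))
    lines.append(fmt(2, 1, root.p0, r, 1))
    lines.append(fmt(3, 1, root.p1, r, 1))
    soma_nodes = [(1, center), (2, root.p0), (3, root.p1)]
    node_of_sec = {}
    next_id = 4
    for s in m.topological_order():
        if s.region == "soma":
            continue
        if s.parent == root.id:
            # attach to the nearest of the three soma nodes
            par_node = min(soma_nodes, key=lambda nc: np.linalg.norm(nc[1] - s.p0))[0]
        else:
            par_node = node_of_sec[s.parent]
        lines.append(fmt(next_id, _REGION_TO_SWC[s.region], s.p1, s.diameter / 2.0, par_node))
        node_of_sec[s.id] = next_id
        next_id += 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Synthetic generation
# ---------------------------------------------------------------------------

def soma_cylinder(diameter: float) -> Section:
    """Soma as a cylinder of length == diameter centered at the origin.

    The lateral area pi*d^2 equals the surface area of a sphere of the same
    diameter, so the somatic membrane area is preserved.
    """
    if diameter <= 0:
        raise ValueError("soma diameter must be positive")
    h = diameter / 2.0
    return Section(0, "soma", -1, np.array([-h, 0.0, 0.0]),
                   np.array([h, 0.0, 0.0]), diameter)


def _axon_chain(sections, parent_id, start, length, diameter, next_id,
                soma_half, direction=(1.0, 0.0, 0.0)):
    """Append a straight axon split exactly at hillock/AIS label boundaries."""
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    b1 = max(AIS_START - soma_half, 0.0)   # hillock | AIS
    b2 = max(AIS_END - soma_half, b1)      # AIS | axon proper
    cuts = sorted({c for c in (b1, b2, HILLOCK_LEN) if 0.0 < c < length})
    edges = [0.0] + cuts + [length]
    pid = parent_id
    p = np.asarray(start, float)
    for a, b in zip(edges[:-1], edges[1:]):
        q = np.asarray(start, float) + u * b
        sec = Section(next_id, "axon", pid, p, q, diameter)
        sections.append(sec)
        pid = next_id
        next_id += 1
        p = q
    return next_id


def generate_rgc(field_diameter: float = 191.0, *, stratification_depth: float = 10.0,
                 n_branches: int = 4, midget: bool = False, seed: int = 0,
                 soma_diameter: float | None = None, axon_length: float = 200.0) -> Morphology:
    """Generate a synthetic RGC with a planar, stratified dendritic tree.

    The tree stands in for traced cells: ``field_diameter`` sets the in-plane
    dendritic span (honored within 10%), ``stratification_depth`` the depth of
    the dendritic plane below the somatic center (um, toward the inner
    plexiform layer, i.e. -z, away from the electrode).  The axon leaves the
    soma along +x in the retinal plane with hillock (first 50 um) and AIS
    (25-75 um path distance from the somatic center).  Midget-like cells get a
    compact two-level tree.  Deterministic under a fixed seed.
    """
    if field_diameter <= 0:
        raise ValueError("field diameter must be positive")
    if soma_diameter is None:
        soma_diameter = 10.0 if midget else 25.0
    if field_diameter <= soma_diameter:
        raise ValueError("field diameter must exceed the soma diameter")
    rng = np.random.default_rng(seed)
    soma = soma_cylinder(soma_diameter)
    sections = [soma]
    next_id = 1
    half = soma_diameter / 2.0

    next_id = _axon_chain(sections, soma.id, soma.p1, axon_length, 1.0,
                          next_id, half)

    radius = field_diameter / 2.0
    levels = 2 if midget else 3
    fracs = ([0.45, 1.0] if midget else [0.35, 0.7, 1.0])
    diams = [2.5, 1.4, 0.8, 0.6]
    spread = (2.0 * math.pi / n_branches) * 0.32

    def grow(parent_id, start, angle, level):
        nonlocal next_id
        r_t = radius * fracs[level] * (1.0 + 0.03 * rng.standard_normal())
        end = np.array([r_t * math.cos(angle), r_t * math.sin(angle),
                        -stratification_depth])
        sec = Section(next_id, "dendrite", parent_id, start, end,
                      diams[min(level, len(diams) - 1)])
        sections.append(sec)
        pid = next_id
        next_id += 1
        if level + 1 < levels:
            for sign in (-1.0, 1.0):
                child = angle + sign * spread * (0.6 + 0.25 * rng.random())
                grow(pid, end, child, level + 1)

    for k in range(n_branches):
        theta = 2.0 * math.pi * k / n_branches + rng.normal(0.0, 0.12)
        grow(soma.id, np.zeros(3), theta, 0)

    m = Morphology(sections)
    m.relabel_axon()
    m.validate()
    return m


def extend_axon(m: Morphology, length: float = 900.0) -> Morphology:
    """Linearly extend the axon by ``length`` um past its traced endpoint.

    The extension is collinear with the terminal axon segment and keeps its
    diameter, so the axon reaches well beyond any electrode test region.
    """
    if length < 0:
        raise ValueError("extension length must be non-negative")
    out = m.copy()
    if length == 0:
        return out
    arcs = out.axon_arc_of()
    if not arcs:
        raise MorphologyError("morphology has no axon to extend")
    term_id = max(arcs, key=lambda sid: arcs[sid] + out.section(sid).length)
    term = out.section(term_id)
    u = term.p1 - term.p0
    u = u / np.linalg.norm(u)
    new_id = max(s.id for s in out.sections) + 1
    out.sections.append(Section(new_id, "axon", term.id, term.p1.copy(),
                                term.p1 + u * length, term.diameter))
    out._index[new_id] = out.sections[-1]
    out.relabel_axon()
    return out


def edit_remove_dendrites(m: Morphology) -> Morphology:
    """Delete every dendrite-labelled section, leaving the rest untouched."""
    out = m.copy()
    out.sections = [s for s in out.sections if s.region != "dendrite"]
    out._index = {s.id: s for s in out.sections}
    return out


def edit_shift_proximal_axon(m: Morphology, first_len: float = 100.0,
                             dz: float = -2.0, taper: float = 20.0) -> Morphology:
    """Translate the first ``first_len`` um of axon (incl. AIS) by dz along z.

    A linear taper over ``taper`` um beyond ``first_len`` blends back into the
    unshifted distal axon so the path stays continuous.
    """
    if first_len <= 0:
        raise ValueError("first_len must be positive")
    out = m.copy()
    arcs = out.axon_arc_of()

    def weight(arc):
        if arc <= first_len:
            return 1.0
        if arc >= first_len + taper:
            return 0.0
        return 1.0 - (arc - first_len) / taper

    for sid, arc in arcs.items():
        s = out.section(sid)
        s.p0[2] += dz * weight(arc)
        s.p1[2] += dz * weight(arc + s.length)
    return out


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentedCell:
    """Compartmentalized morphology: arrays indexed by compartment.

    Compartments are ordered so every parent precedes its children (Hines
    ordering).  ``parent[0] == -1``; ``midpoint`` rows are 3-D um positions;
    ``area`` is lateral membrane area in um^2; ``path_from_center`` is the
    path distance of the compartment midpoint from the somatic center.
    """

    morphology: Morphology
    sec_id: np.ndarray
    parent: np.ndarray
    length: np.ndarray
    diameter: np.ndarray
    area: np.ndarray
    midpoint: np.ndarray
    region: np.ndarray
    path_from_center: np.ndarray
    max_segment_length: float

    @property
    def n_comp(self) -> int:
        return len(self.sec_id)

    @property
    def soma_index(self) -> int:
        """Soma compartment nearest the somatic center (reporting site)."""
        idx = np.flatnonzero(self.region == "soma")
        d = np.linalg.norm(self.midpoint[idx] - self.morphology.somatic_center, axis=1)
        return int(idx[np.argmin(d)])

    def comps_in(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.region == region)

    def ais_sites(self) -> np.ndarray:
        """Proximal-end, mid-point and distal-end AIS compartment indices."""
        idx = self.comps_in("ais")
        if len(idx) == 0:
            raise MorphologyError("cell has no AIS compartments")
        order = idx[np.argsort(self.path_from_center[idx])]
        return np.array([order[0], order[len(order) // 2], order[-1]])


def segmentize(m: Morphology, max_len: float = 12.0) -> SegmentedCell:
    """Split sections into compartments strictly shorter than ``max_len`` um.

    Each section is cut into ``ceil(L / max_len)`` equal pieces, so the
    per-section membrane area is conserved exactly and compartment midpoints
    lie on the section geometry.
    """
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    m.validate()
    order = m.topological_order()

    sec_ids, parents, lengths, diams, areas, mids, regions, paths = \
        [], [], [], [], [], [], [], []
    last_comp_of_sec = {}
    path_at_start = {}
    center = m.somatic_center
    for s in order:
        if s.length <= 0 or s.diameter <= 0:
            raise MorphologyError(f"section {s.id} has zero length or diameter")
        if s.parent < 0:
            start_path = 0.0
            parent_comp = -1
        else:
            par = m.section(s.parent)
            if par.region == "soma":
                start_path = float(np.linalg.norm(s.p0 - center))
            else:
                start_path = path_at_start[s.parent] + par.length
            parent_comp = last_comp_of_sec[s.parent]
        path_at_start[s.id] = start_path
        n = max(1, math.ceil(s.length / max_len))
        seg_len = s.length / n
        u = (s.p1 - s.p0) / s.length
        for k in range(n):
            comp = len(sec_ids)
            sec_ids.append(s.id)
            parents.append(parent_comp)
            lengths.append(seg_len)
            diams.append(s.diameter)
            areas.append(math.pi * s.diameter * seg_len)
            mids.append(s.p0 + u * seg_len * (k + 0.5))
            regions.append(s.region)
            paths.append(start_path + seg_len * (k + 0.5))
            parent_comp = comp
        last_comp_of_sec[s.id] = parent_comp

    return SegmentedCell(
        morphology=m,
        sec_id=np.asarray(sec_ids, dtype=np.int64),
        parent=np.asarray(parents, dtype=np.int64),
        length=np.asarray(lengths),
        diameter=np.asarray(diams),
        area=np.asarray(areas),
        midpoint=np.asarray(mids),
        region=np.asarray(regions, dtype=object),
        path_from_center=np.asarray(paths),
        max_segment_length=max_len,
    )
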
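"""Neuron morphologies: SWC import/export, section classification, discretization,
and a surrogate generator for cerebellar Golgi cells.

A morphology is a tree of typed *sections* (soma, axon, AIS, basal_dendrite,
apical_dendrite), each an unbranched run of 3D sample points.  ``discretize``
splits every section into an odd number of cylindrical compartments suitable
for a center-sampled cable solver.  ``make_surrogate`` synthesizes Golgi-like
morphologies (soma in the granular layer, basal dendrites locally, apical
dendrites projecting into the molecular layer along +y, axon stemming from the
soma or a basal dendrite) so that the full pipeline can run without downloaded
reconstructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MorphPoint",
    "Section",
    "Compartment",
    "Morphology",
    "SurrogateParams",
    "read_swc",
    "write_swc",
    "classify_sections",
    "discretize",
    "make_surrogate",
    "validate_morphology",
]

# SWC type codes
SWC_SOMA = 1
SWC_AXON = 2
SWC_BASAL = 3
SWC_APICAL = 4

LABELS = ("soma", "axon", "AIS", "basal_dendrite", "apical_dendrite")

_TYPE_TO_LABEL = {
    SWC_SOMA: "soma",
    SWC_AXON: "axon",
    SWC_BASAL: "basal_dendrite",
    SWC_APICAL: "apical_dendrite",
}
_LABEL_TO_TYPE = {
    "soma": SWC_SOMA,
    "axon": SWC_AXON,
    "AIS": SWC_AXON,  # AIS is a sub-path of the axon in SWC terms
    "basal_dendrite": SWC_BASAL,
    "apical_dendrite": SWC_APICAL,
}


class SWCParseError(ValueError):
    """Raised when an SWC file violates the format contract."""


@dataclass
class MorphPoint:
    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent: int  # parent id, -1 for root

    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Compartment:
    """One cylindrical compartment of a discretized section.

    ``diameter`` is the length-weighted mean of the section's linearly
    interpolated diameter profile over the compartment's span, so that
    compartment areas sum exactly to the section area for any partition.
    """

    section: "Section"
    index: int  # position within the section
    length: float  # um
    diameter: float  # um
    area: float  # cm^2  (pi * diameter * length, cylinder)
    x: float
    y: float
    z: float
    r_axial_half: float  # MOhm, half-compartment axial resistance (uses section Ra)


@dataclass
class Section:
    label: str
    points: list  # ordered MorphPoint list; first point is the attachment anchor
    parent: "Section | None" = None
    parent_point_index: int = -1  # index into parent.points where this section attaches
    children: list = field(default_factory=list)
    compartments: list = field(default_factory=list)

    @property
    def parent_position(self) -> float:
        """Attachment position along the parent (0..1 of its arclength)."""
        if self.parent is None:
            return 0.0
        arcs = self.parent.arclengths()
        if arcs[-1] <= 0:
            return 1.0
        return float(arcs[self.parent_point_index] / arcs[-1])

    # --- geometry -----------------------------------------------------
    def arclengths(self) -> np.ndarray:
        """Cumulative path length (um) at each point, starting at 0."""
        pts = np.array([[p.x, p.y, p.z] for p in self.points])
        if len(pts) < 2:
            return np.zeros(len(pts))
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclengths()[-1])

    @property
    def area_cm2(self) -> float:
        """Lateral membrane area (cm^2): pi * integral of diameter along path."""
        s = self.arclengths()
        d = np.array([2.0 * p.radius for p in self.points])
        if len(s) < 2:
            # isolated point (single-point soma): treat as sphere-equivalent cylinder
            return math.pi * d[0] * d[0] * 1e-8
        integ = np.trapezoid(d, s)  # um^2
        return math.pi * integ * 1e-8  # -> cm^2

    def centroid(self) -> np.ndarray:
        pts = np.array([[p.x, p.y, p.z] for p in self.points])
        return pts.mean(axis=0)

    def diameter_at(self, s: float) -> float:
        """Interpolated diameter (um) at arclength s."""
        arcs = self.arclengths()
        d = np.array([2.0 * p.radius for p in self.points])
        return float(np.interp(s, arcs, d))

    def xyz_at(self, s: float) -> np.ndarray:
        arcs = self.arclengths()
        pts = np.array([[p.x, p.y, p.z] for p in self.points])
        return np.array([np.interp(s, arcs, pts[:, k]) for k in range(3)])


@dataclass
class Morphology:
    sections: list  # topological order: parent before child; sections[0] is soma
    provenance: dict = field(default_factory=dict)

    @property
    def soma(self) -> Section:
        return self.sections[0]

    def by_label(self, label: str) -> list:
        return [s for s in self.sections if s.label == label]

    @property
    def total_length(self) -> float:
        return sum(s.length for s in self.sections)

    @property
    def total_area(self) -> float:
        return sum(s.area_cm2 for s in self.sections)

    def all_compartments(self) -> list:
        out = []
        for s in self.sections:
            out.extend(s.compartments)
        return out


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path) -> Morphology:
    """Parse an SWC file into a Morphology.

    One Section is created per unbranched run of same-type points; the root
    run (type 1) becomes the soma.  Type codes map 1->soma, 2->axon,
    3->basal_dendrite, 4->apical_dendrite as initial labels (AIS is assigned
    later by :func:`classify_sections`).
    """
    points: dict[int, MorphPoint] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 7:
                raise SWCParseError(f"line {lineno}: expected 7 columns, got {len(cols)}")
            pid, tc = int(cols[0]), int(cols[1])
            x, y, z, r = (float(c) for c in cols[2:6])
            parent = int(cols[6])
            if r <= 0:
                raise SWCParseError(f"line {lineno}: non-positive radius {r}")
            if pid in points:
                raise SWCParseError(f"line {lineno}: duplicate id {pid}")
            points[pid] = MorphPoint(pid, tc, x, y, z, r, parent)

    if not points:
        raise SWCParseError("empty SWC file")
    for p in points.values():
        if p.parent != -1 and p.parent not in points:
            raise SWCParseError(f"point {p.id}: orphan parent id {p.parent}")

    roots = [p for p in points.values() if p.parent == -1]
    if len(roots) != 1:
        raise SWCParseError(f"expected exactly one root point, found {len(roots)}")
    root = roots[0]
    if root.type_code != SWC_SOMA:
        raise SWCParseError("root point must be soma (type 1)")

    children: dict[int, list] = {pid: [] for pid in points}
    for p in points.values():
        if p.parent != -1:
            children[p.parent].append(p.id)
    for sibs in children.values():
        sibs.sort()

    # Build sections: walk the tree splitting at branch points and type changes.
    sections: list[Section] = []

    def n_children(pid):
        return len(children[pid])

    # soma: the contiguous same-type run from the root
    soma_pts = [root]
    cur = root
    while True:
        nxt = [points[c] for c in children[cur.id] if points[c].type_code == SWC_SOMA]
        if len(nxt) == 1 and n_children(cur.id) >= 1:
            soma_pts.append(nxt[0])
            cur = nxt[0]
        else:
            break
    soma = Section("soma", soma_pts)
    sections.append(soma)
    soma_ids = {p.id for p in soma_pts}

    # point id -> (owning section, local index) for attachment lookup
    owner: dict[int, tuple] = {p.id: (soma, i) for i, p in enumerate(soma_pts)}

    queue = []
    for pid in sorted(points):
        p = points[pid]
        if pid in soma_ids:
            continue
        if p.parent in soma_ids:
            queue.append(p)
    while queue:
        queue.sort(key=lambda q: q.id)
        start = queue.pop(0)
        parent_sec, attach_idx = owner[start.parent]
        attach = points[start.parent]
        # the section's first point is a geometric anchor at the attachment
        # location, carrying the child's own radius (avoids soma-radius bleed)
        anchor = MorphPoint(-1, start.type_code, attach.x, attach.y, attach.z,
                            start.radius, -1)
        sec_pts = [anchor, start]
        cur = start
        while True:
            kid_ids = children[cur.id]
            same = [points[c] for c in kid_ids if points[c].type_code == cur.type_code]
            if len(kid_ids) == 1 and len(same) == 1:
                cur = same[0]
                sec_pts.append(cur)
            else:
                break
        label = _TYPE_TO_LABEL.get(start.type_code, "basal_dendrite")
        sec = Section(label, sec_pts, parent=parent_sec, parent_point_index=attach_idx)
        parent_sec.children.append(sec)
        sections.append(sec)
        for i, p in enumerate(sec_pts[1:], start=1):
            owner[p.id] = (sec, i)
        for c in children[cur.id]:
            queue.append(points[c])

    m = Morphology(sections, provenance={"file": str(path)})
    validate_morphology(m)
    return m


def write_swc(m: Morphology, path) -> None:
    """Write a Morphology as a standard 7-column SWC file (1-based ids)."""
    lines = ["# SWC export (golgisim)"]
    next_id = 1
    point_ids: dict[tuple, int] = {}  # (id(section), point index) -> swc id

    for sec in m.sections:
        tc = _LABEL_TO_TYPE[sec.label]
        if sec.parent is None:
            parent_swc = -1
            start = 0
        else:
            parent_swc = point_ids[(id(sec.parent), sec.parent_point_index)]
            start = 1  # the anchor point is owned by the parent
        for i in range(start, len(sec.points)):
            p = sec.points[i]
            pid = next_id
            next_id += 1
            point_ids[(id(sec), i)] = pid
            lines.append(
                f"{pid} {tc} {p.x:.17g} {p.y:.17g} {p.z:.17g} {p.radius:.17g} {parent_swc}"
            )
            parent_swc = pid
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def validate_morphology(m: Morphology) -> None:
    """Check the Morphology invariants; raise ValueError on violation."""
    if not m.sections or m.sections[0].label != "soma":
        raise ValueError("first section must be the soma")
    n_soma = sum(1 for s in m.sections if s.label == "soma")
    if n_soma != 1:
        raise ValueError(f"exactly one soma required, found {n_soma}")
    seen = set()
    for s in m.sections:
        if s.label not in LABELS:
            raise ValueError(f"unknown section label {s.label!r}")
        if s.label != "soma" and len(s.points) < 2:
            raise ValueError("non-soma section with fewer than 2 points")
        if s.parent is not None and id(s.parent) not in seen:
            raise ValueError("sections not in topological order (cycle?)")
        if s.parent is None and s is not m.sections[0]:
            raise ValueError("disconnected section (no parent, not soma)")
        seen.add(id(s))
        for p in s.points:
            if p.radius <= 0:
                raise ValueError("non-positive radius")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_sections(m: Morphology, pc_layer_y: float | None = None,
                      ais_length: float = 15.0) -> Morphology:
    """Relabel dendrites as apical/basal and carve the AIS out of the axon.

    Dendritic sections whose centroid lies beyond ``pc_layer_y`` along +y
    (toward the molecular layer) become apical, the rest basal.  The first
    ``ais_length`` um of the axon path become the AIS.  ``pc_layer_y``
    defaults to the soma centroid y + 20 um.
    """
    if pc_layer_y is None:
        pc_layer_y = float(m.soma.centroid()[1]) + 20.0

    _relabel_dendrites(m, pc_layer_y)

    # AIS: walk the axon from its origin, splitting at ais_length
    axon_roots = [s for s in m.sections
                  if s.label in ("axon", "AIS") and (s.parent is None or
                                                     s.parent.label not in ("axon", "AIS"))]
    if not axon_roots:
        import warnings
        warnings.warn("morphology has no axon; model valid for somatic protocols only")
        return m
    root = axon_roots[0]
    remaining = ais_length
    sec = root
    while True:
        L = sec.length
        if L >= remaining - 1e-9:
            if L > remaining + 1e-9:
                _split_section(m, sec, remaining, "AIS", "axon")
            else:
                sec.label = "AIS"
            break
        sec.label = "AIS"
        remaining -= L
        nxt = [c for c in sec.children if c.label in ("axon", "AIS")]
        if not nxt:
            break
        sec = nxt[0]
    return m


def _relabel_dendrites(m: Morphology, pc_layer_y: float) -> None:
    for sec in m.sections:
        if sec.label in ("basal_dendrite", "apical_dendrite"):
            sec.label = (
                "apical_dendrite" if sec.centroid()[1] > pc_layer_y else "basal_dendrite"
            )


def _split_section(m: Morphology, sec: Section, s_split: float,
                   label_prox: str, label_dist: str) -> None:
    """Split ``sec`` at arclength ``s_split`` into two sections."""
    arcs = sec.arclengths()
    pt = sec.xyz_at(s_split)
    d = sec.diameter_at(s_split)
    cut = MorphPoint(-1, _LABEL_TO_TYPE[label_prox], pt[0], pt[1], pt[2], d / 2.0, -1)
    i = int(np.searchsorted(arcs, s_split))
    prox_pts = sec.points[:i] + [cut]
    dist_pts = [cut] + sec.points[i:]
    if len(prox_pts) < 2:
        prox_pts = [sec.points[0], cut]
    old_children = sec.children
    sec.points = prox_pts
    sec.label = label_prox
    dist = Section(label_dist, dist_pts, parent=sec,
                   parent_point_index=len(prox_pts) - 1)
    # reattach the old children: those anchored beyond the cut move to `dist`
    sec.children = [dist]
    for c in old_children:
        j = c.parent_point_index
        if j >= i:  # old index i.. now lives in dist at offset j - i + 1
            c.parent = dist
            c.parent_point_index = j - i + 1
            dist.children.append(c)
        else:
            sec.children.append(c)
    m.sections.insert(m.sections.index(sec) + 1, dist)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize(m: Morphology, max_seg_length: float = 40.0, ra: float = 122.0) -> Morphology:
    """Split every section into an odd number of cylindrical compartments.

    Each compartment length is <= ``max_seg_length``; the count per section is
    forced odd so the voltage sample sits at the compartment center.  Membrane
    area is conserved exactly because the compartment diameter is the
    length-weighted mean diameter over its span.  ``ra`` (Ohm*cm) is used for
    the stored half-compartment axial resistances.
    """
    if max_seg_length <= 0:
        raise ValueError("max_seg_length must be positive")
    for sec in m.sections:
        sec.compartments = []
        L = sec.length
        if L <= 0:
            # single-point soma: one spherical-equivalent compartment
            p = sec.points[0]
            d = 2.0 * p.radius
            area = math.pi * d * d * 1e-8
            leng = d
            r_half = _axial_half_mohm(ra, leng / 2.0, d)
            sec.compartments.append(
                Compartment(sec, 0, leng, d, area, p.x, p.y, p.z, r_half))
            continue
        n = max(1, math.ceil(L / max_seg_length))
        if n % 2 == 0:
            n += 1
        edges = np.linspace(0.0, L, n + 1)
        arcs = sec.arclengths()
        dprof = np.array([2.0 * p.radius for p in sec.points])
        for i in range(n):
            s0, s1 = edges[i], edges[i + 1]
            leng = s1 - s0
            # length-weighted mean diameter over [s0, s1] of the piecewise
            # linear profile: exact integral via fine union grid
            grid = np.unique(np.concatenate([[s0, s1], arcs[(arcs > s0) & (arcs < s1)]]))
            dvals = np.interp(grid, arcs, dprof)
            integ = np.trapezoid(dvals, grid)
            dmean = integ / leng
            area = math.pi * dmean * leng * 1e-8  # cm^2
            mid = sec.xyz_at(0.5 * (s0 + s1))
            r_half = _axial_half_mohm(ra, leng / 2.0, dmean)
            sec.compartments.append(
                Compartment(sec, i, leng, dmean, area, mid[0], mid[1], mid[2], r_half))
    return m


def _axial_half_mohm(ra: float, half_len_um: float, diam_um: float) -> float:
    """Half-compartment axial resistance in MOhm (ra in Ohm*cm)."""
    # R = ra * l / A ; l in cm (1 um = 1e-4 cm), A in cm^2 (1 um^2 = 1e-8 cm^2)
    area_um2 = math.pi * (diam_um / 2.0) ** 2
    r_ohm = ra * (half_len_um * 1e-4) / (area_um2 * 1e-8)
    return r_ohm * 1e-6


# ---------------------------------------------------------------------------
# Surrogate generator
# ---------------------------------------------------------------------------

@dataclass
class SurrogateParams:
    """Parameters of the Golgi-like surrogate morphology generator.

    Defaults emulate the geometry of adult mouse Golgi cell reconstructions:
    a 16-27 um soma sitting in the granular layer, 3-5 basal dendrites
    branching locally (total basal length ~1-2 mm), 2-3 apical dendrites
    ascending into the molecular layer along +y (total apical length
    ~1-2 mm), and a descending axon with a distinct initial segment.  The
    axon stems from the soma or from a basal dendrite with equal probability,
    as in the reference reconstructions.
    """

    soma_diameter: float = 20.0  # um
    n_basal: int = 4
    basal_length: float = 110.0  # um per branch segment
    basal_branch_levels: int = 2  # each stem bifurcates this many times
    basal_diameter: float = 2.0  # um at the stem, tapering distally
    n_apical: int = 3
    apical_length: float = 160.0
    apical_branch_levels: int = 2
    apical_diameter: float = 1.6
    axon_length: float = 400.0
    axon_diameter: float = 1.2
    ais_diameter: float | None = None  # defaults to axon_diameter
    ais_length: float = 15.0
    pc_layer_offset: float = 20.0  # um above the soma centroid
    points_per_branch: int = 5
    jitter: float = 0.25  # direction jitter (radians scale)
    axon_from_soma_prob: float = 0.5
    taper: float = 0.6  # diameter shrink factor along a branch
    variability: float = 0.15  # relative spread of lengths/diameters across cells

    @classmethod
    def compact(cls) -> "SurrogateParams":
        """A scaled-down morphology (fewer, unbranched dendrites) for fast
        desk-scale optimization runs and tests; dendritic membrane area is
        kept large enough for a realistic (~300 MOhm) input resistance."""
        return cls(n_basal=3, basal_branch_levels=0, basal_length=200.0,
                   basal_diameter=2.8,
                   n_apical=2, apical_branch_levels=1, apical_length=220.0,
                   apical_diameter=0.9, axon_length=160.0,
                   axon_diameter=1.0, ais_diameter=0.8, ais_length=30.0,
                   points_per_branch=3)


def make_surrogate(params: SurrogateParams | None = None, seed: int = 0) -> Morphology:
    """Generate a synthetic Golgi-cell morphology (deterministic per seed)."""
    p = params or SurrogateParams()
    rng = np.random.default_rng(seed)

    def vary(x):
        if p.variability <= 0:
            return x
        return x * float(rng.uniform(1.0 - p.variability, 1.0 + p.variability))

    r = vary(p.soma_diameter) / 2.0
    soma_pts = [
        MorphPoint(1, SWC_SOMA, 0.0, -r, 0.0, r * 0.7, -1),
        MorphPoint(2, SWC_SOMA, 0.0, 0.0, 0.0, r, 1),
        MorphPoint(3, SWC_SOMA, 0.0, r, 0.0, r * 0.7, 2),
    ]
    soma = Section("soma", soma_pts)
    sections = [soma]

    def grow(parent_sec, attach_idx, direction, length, diam, label, levels):
        npts = p.points_per_branch
        origin = parent_sec.points[attach_idx]
        tc = _LABEL_TO_TYPE[label]
        pts = [MorphPoint(-1, tc, origin.x, origin.y, origin.z, diam / 2.0, -1)]
        pos = origin.xyz().astype(float)
        d = np.array(direction, dtype=float)
        d /= np.linalg.norm(d)
        step = length / (npts - 1)
        dia = diam
        for i in range(1, npts):
            d_jit = d + rng.normal(0.0, p.jitter, 3)
            d_jit /= np.linalg.norm(d_jit)
            pos = pos + d_jit * step
            dia = max(0.4, dia * (1.0 - (1.0 - p.taper) / (npts - 1)))
            pts.append(MorphPoint(-1, tc, *pos, dia / 2.0, -1))
        sec = Section(label, pts, parent=parent_sec, parent_point_index=attach_idx)
        parent_sec.children.append(sec)
        sections.append(sec)
        if levels > 0:
            for sign in (-1.0, 1.0):
                perp = np.cross(d, [0.0, 0.0, 1.0])
                if np.linalg.norm(perp) < 1e-6:
                    perp = np.array([1.0, 0.0, 0.0])
                perp /= np.linalg.norm(perp)
                child_dir = d + sign * 0.6 * perp
                grow(sec, len(pts) - 1, child_dir, length * 0.9, dia * 0.9,
                     label, levels - 1)
        return sec

    # basal dendrites: fan out sideways/below the soma (granular layer)
    basal_stems = []
    for i in range(p.n_basal):
        ang = 2.0 * math.pi * i / p.n_basal + rng.uniform(-0.2, 0.2)
        direction = [math.cos(ang), -0.35, math.sin(ang)]
        sec = grow(soma, 1, direction, vary(p.basal_length),
                   vary(p.basal_diameter), "basal_dendrite", p.basal_branch_levels)
        basal_stems.append(sec)

    # apical dendrites: ascend along +y into the molecular layer
    for i in range(p.n_apical):
        ang = 2.0 * math.pi * i / max(1, p.n_apical)
        direction = [0.35 * math.cos(ang), 1.0, 0.35 * math.sin(ang)]
        grow(soma, 2, direction, vary(p.apical_length),
             vary(p.apical_diameter), "apical_dendrite", p.apical_branch_levels)

    # axon: from soma or from a basal dendrite, descending (-y)
    if rng.random() < p.axon_from_soma_prob or not basal_stems:
        ax_parent, ax_attach = soma, 0
    else:
        stem = basal_stems[int(rng.integers(len(basal_stems)))]
        # attach at the stem's distal sample (an existing run boundary, so the
        # SWC round trip preserves the section decomposition)
        ax_parent, ax_attach = stem, len(stem.points) - 1

    origin = ax_parent.points[ax_attach]
    ais_d = p.ais_diameter if p.ais_diameter is not None else p.axon_diameter
    ais_pts = [MorphPoint(-1, SWC_AXON, origin.x, origin.y, origin.z,
                          ais_d / 2.0, -1)]
    pos = origin.xyz().astype(float)
    for i in range(1, 4):
        pos = pos + np.array([0.0, -p.ais_length / 3.0, 0.0])
        ais_pts.append(MorphPoint(-1, SWC_AXON, *pos, ais_d / 2.0, -1))
    ais = Section("AIS", ais_pts, parent=ax_parent, parent_point_index=ax_attach)
    ax_parent.children.append(ais)
    sections.append(ais)

    ax_pts = [MorphPoint(-1, SWC_AXON, *pos, p.axon_diameter / 2.0, -1)]
    npts = max(3, p.points_per_branch)
    for i in range(1, npts):
        drift = rng.normal(0.0, p.jitter, 3) + np.array([0.0, -1.0, 0.0])
        drift /= np.linalg.norm(drift)
        pos = pos + drift * (p.axon_length / (npts - 1))
        ax_pts.append(MorphPoint(-1, SWC_AXON, *pos, p.axon_diameter / 2.0, -1))
    axon = Section("axon", ax_pts, parent=ais, parent_point_index=len(ais_pts) - 1)
    ais.children.append(axon)
    sections.append(axon)

    m = Morphology(sections, provenance={"generator_seed": seed})
    # make generator labels consistent with the positional classification rule
    _relabel_dendrites(m, float(soma.centroid()[1]) + p.pc_layer_offset)
    validate_morphology(m)
    return m
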
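"""PT-like neuronal morphologies as labelled compartment trees.

A morphology is an ordered list of :class:`Compartment` edges (parent precedes
child), rooted at a single soma.  Dendritic compartments carry one of the
domains ``soma | basal | oblique | trunk | tuft``; the synthetic axon adds
``axon_hillock | ais | myelin``.  Positions on the tree are
``(compartment_id, arclength_fraction)`` pairs; all distances are path lengths
in micrometres measured from the soma centre (the soma itself contributes
zero length by convention).

The apical axis soma -> primary branch point (BP) -> most distal tuft tip is
mapped onto a normalized coordinate x with soma at 0, BP at 1 and the most
distal tuft point at 2; thalamocortical synapse density profiles and the
apical recording probe are expressed in this coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DomainError,
    FormatError,
    ParameterError,
    StateError,
    TreeLookupError,
)

__all__ = [
    "Compartment",
    "Morphology",
    "MorphologyParams",
    "Location",
    "DENDRITIC_DOMAINS",
    "APICAL_DOMAINS",
    "AXONAL_DOMAINS",
    "generate_pt_morphology",
    "attach_axon",
    "path_distance",
    "normalized_apical_coordinate",
    "read_swc",
    "write_swc",
]

DENDRITIC_DOMAINS = frozenset({"soma", "basal", "oblique", "trunk", "tuft"})
APICAL_DOMAINS = frozenset({"oblique", "trunk", "tuft"})
AXONAL_DOMAINS = frozenset({"axon_hillock", "ais", "myelin"})
ALL_DOMAINS = DENDRITIC_DOMAINS | AXONAL_DOMAINS

#: (compartment_id, arclength fraction in [0, 1])
Location = tuple[int, float]


@dataclass(frozen=True)
class Compartment:
    """One unbranched edge of the tree (a frustum of a cone).

    ``path_distance_to_soma`` is the path distance of the *distal* end; the
    proximal end sits at ``path_distance_to_soma - length`` (0 for the soma,
    which contributes no path length).
    """

    id: int
    parent_id: int | None
    domain: str
    length: float
    diameter_proximal: float
    diameter_distal: float
    path_distance_to_soma: float

    def __post_init__(self):
        if self.domain not in ALL_DOMAINS:
            raise ParameterError(f"unknown domain {self.domain!r}")
        if self.length <= 0:
            raise ParameterError(f"compartment {self.id}: length must be > 0")
        if self.diameter_proximal <= 0 or self.diameter_distal <= 0:
            raise ParameterError(f"compartment {self.id}: diameters must be > 0")

    @property
    def proximal_distance(self) -> float:
        if self.domain == "soma":
            return 0.0
        return self.path_distance_to_soma - self.length

    def area(self) -> float:
        """Lateral membrane area in µm² (frustum, slant ignored)."""
        return math.pi * 0.5 * (self.diameter_proximal + self.diameter_distal) * self.length


class Morphology:
    """Connected, acyclic compartment tree with a designated apical axis."""

    def __init__(self, compartments: list[Compartment], bp_id: int, tuft_tip_distance: float):
        self.compartments = list(compartments)
        self.bp_id = bp_id
        self.tuft_tip_distance = float(tuft_tip_distance)
        self._index = {c.id: c for c in self.compartments}
        if len(self._index) != len(self.compartments):
            raise ParameterError("duplicate compartment ids")
        self._children: dict[int, list[int]] = {c.id: [] for c in self.compartments}
        self._validate()

    # -- construction checks -------------------------------------------------
    def _validate(self):
        roots = [c for c in self.compartments if c.parent_id is None]
        if len(roots) != 1 or roots[0].domain != "soma":
            raise ParameterError("tree must have exactly one root of domain soma")
        seen: set[int] = set()
        for c in self.compartments:
            if c.parent_id is not None:
                if c.parent_id not in seen:
                    raise ParameterError(
                        f"compartment {c.id}: parent {c.parent_id} does not precede it"
                    )
                self._children[c.parent_id].append(c.id)
            seen.add(c.id)
        if self.bp_id not in self._index or self._index[self.bp_id].domain != "trunk":
            raise ParameterError("bp_id must lie on the trunk")
        if self.tuft_tip_distance <= self._index[self.bp_id].path_distance_to_soma:
            raise ParameterError("tuft_tip_distance must exceed the BP path distance")

    # -- queries -------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.compartments)

    def __getitem__(self, comp_id: int) -> Compartment:
        try:
            return self._index[comp_id]
        except KeyError:
            raise TreeLookupError(f"unknown compartment id {comp_id}") from None

    def __contains__(self, comp_id: int) -> bool:
        return comp_id in self._index

    def children(self, comp_id: int) -> list[int]:
        self[comp_id]
        return self._children[comp_id]

    @property
    def soma(self) -> Compartment:
        return self.compartments[0]

    @property
    def bp_distance(self) -> float:
        """Path distance of the primary branch point (distal end of bp_id)."""
        return self[self.bp_id].path_distance_to_soma

    @property
    def has_axon(self) -> bool:
        return any(c.domain in AXONAL_DOMAINS for c in self.compartments)

    def in_domains(self, domains) -> list[Compartment]:
        domains = {domains} if isinstance(domains, str) else set(domains)
        return [c for c in self.compartments if c.domain in domains]

    def total_length(self, domains=DENDRITIC_DOMAINS - {"soma"}) -> float:
        return sum(c.length for c in self.in_domains(domains))

    def path_distance(self, location: Location) -> float:
        return path_distance(self, location)

    def normalized_x(self, location: Location) -> float:
        return normalized_apical_coordinate(self, location)

    def location_at_distance(self, target: float, domains=("trunk",)) -> Location:
        """A location in ``domains`` whose path distance is closest to ``target``."""
        best: Location | None = None
        best_err = math.inf
        for c in self.in_domains(domains):
            lo, hi = c.proximal_distance, c.path_distance_to_soma
            d = min(max(target, lo), hi)
            err = abs(d - target)
            if err < best_err:
                best_err = err
                frac = 0.0 if c.length == 0 else (d - lo) / c.length
                best = (c.id, float(frac))
        if best is None:
            raise DomainError(f"no compartments in domains {domains}")
        return best

    def trunk_attachment(self, comp_id: int) -> Location:
        """Walk up parents until the trunk (or soma) is reached.

        Returns the attachment point of the subtree containing ``comp_id``
        on the soma-trunk axis, used to map obliques (and basals) onto the
        normalized apical coordinate.
        """
        c = self[comp_id]
        while c.domain not in ("trunk", "soma"):
            if c.parent_id is None:
                break
            c = self[c.parent_id]
        return (c.id, 1.0 if c.domain == "trunk" else 0.0)


# ---------------------------------------------------------------------------
# synthetic PT morphology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphologyParams:
    """Parameters of the synthetic PT-like morphology generator.

    The generated cell is a stylised layer-5 pyramidal tract neuron: a soma,
    ``n_basal`` tapering basal dendrites, an apical trunk ending at the
    primary branch point (at ``trunk_length * bp_depth_fraction`` µm from the
    soma), ``n_oblique`` oblique side branches off the trunk, and a tuft of
    ``n_tuft_primary`` bifurcating branches reaching ``tuft_depth`` µm beyond
    the BP.  Segments are straight; 3D embedding is cosmetic.
    """

    trunk_length: float = 620.0
    bp_depth_fraction: float = 1.0
    n_basal: int = 6
    basal_length_mean: float = 180.0
    basal_length_sd: float = 30.0
    n_oblique: int = 4
    oblique_length_mean: float = 150.0
    oblique_length_sd: float = 30.0
    tuft_depth: float = 400.0
    n_tuft_primary: int = 2
    soma_diameter: float = 20.0
    trunk_diameter_proximal: float = 5.0
    trunk_diameter_distal: float = 3.5
    basal_diameter: float = 1.2
    basal_taper: float = 0.5
    oblique_diameter: float = 0.9
    oblique_taper: float = 0.5
    tuft_diameter_proximal: float = 1.5
    tuft_diameter_distal: float = 0.5
    seed: int = 0

    def validate(self):
        if self.n_basal < 1:
            raise ParameterError("n_basal must be >= 1")
        if self.n_tuft_primary < 2:
            raise ParameterError("n_tuft_primary must be >= 2")
        if not (0.0 < self.bp_depth_fraction <= 1.0):
            raise ParameterError("bp_depth_fraction must lie in (0, 1]")
        for name in ("trunk_length", "basal_length_mean", "oblique_length_mean",
                     "tuft_depth", "soma_diameter", "basal_diameter",
                     "oblique_diameter", "trunk_diameter_proximal",
                     "trunk_diameter_distal", "tuft_diameter_proximal",
                     "tuft_diameter_distal"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.n_oblique < 0:
            raise ParameterError("n_oblique must be >= 0")


def generate_pt_morphology(params: MorphologyParams) -> Morphology:
    """Generate a synthetic PT-like morphology; deterministic given the seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    comps: list[Compartment] = []
    next_id = 0

    def add(parent_id, domain, length, d_prox, d_dist):
        nonlocal next_id
        parent_dist = 0.0 if parent_id is None else _dist_of(parent_id)
        c = Compartment(next_id, parent_id, domain, length, d_prox, d_dist,
                        parent_dist + (length if domain != "soma" else 0.0))
        comps.append(c)
        next_id += 1
        return c.id

    def _dist_of(comp_id):
        c = comps[comp_id]
        return c.path_distance_to_soma

    soma_id = add(None, "soma", params.soma_diameter, params.soma_diameter,
                  params.soma_diameter)

    # basal dendrites
    for _ in range(params.n_basal):
        length = max(20.0, rng.normal(params.basal_length_mean, params.basal_length_sd))
        add(soma_id, "basal", length, params.basal_diameter,
            params.basal_diameter * params.basal_taper)

    # trunk, split at oblique attachment points
    bp_depth = params.trunk_length * params.bp_depth_fraction
    if params.n_oblique > 0:
        fracs = np.sort(rng.uniform(0.15, 0.85, size=params.n_oblique))
    else:
        fracs = np.array([])
    cuts = np.concatenate([[0.0], fracs, [1.0]]) * bp_depth
    d0, d1 = params.trunk_diameter_proximal, params.trunk_diameter_distal
    parent = soma_id
    oblique_parents = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b - a < 1e-9:
            continue
        dp = d0 + (d1 - d0) * a / bp_depth
        dd = d0 + (d1 - d0) * b / bp_depth
        parent = add(parent, "trunk", b - a, dp, dd)
        oblique_parents.append(parent)
    bp_id = parent  # BP is the distal node of the last trunk piece

    # obliques off internal trunk nodes (not the BP itself)
    for k in range(params.n_oblique):
        length = max(20.0, rng.normal(params.oblique_length_mean, params.oblique_length_sd))
        add(oblique_parents[k], "oblique", length, params.oblique_diameter,
            params.oblique_diameter * params.oblique_taper)

    # tuft: primary branches from the BP, each bifurcating once
    half = params.tuft_depth / 2.0
    d_mid = 0.5 * (params.tuft_diameter_proximal + params.tuft_diameter_distal)
    for _ in range(params.n_tuft_primary):
        prim = add(bp_id, "tuft", half, params.tuft_diameter_proximal, d_mid)
        for _ in range(2):
            add(prim, "tuft", half, d_mid, params.tuft_diameter_distal)

    tip = bp_depth + params.tuft_depth
    return Morphology(comps, bp_id=bp_id, tuft_tip_distance=tip)


def attach_axon(morph: Morphology) -> Morphology:
    """Append the synthetic axon (hillock, AIS, myelinated section) at the soma.

    Geometry: hillock 20 µm tapering 3 -> 1.75 µm, AIS 30 µm tapering
    1.75 -> 1 µm, then 1 mm of myelinated axon at 1 µm diameter.
    """
    if morph.has_axon:
        raise StateError("morphology already has an axon attached")
    comps = list(morph.compartments)
    nid = max(c.id for c in comps) + 1
    soma_id = morph.soma.id
    hillock = Compartment(nid, soma_id, "axon_hillock", 20.0, 3.0, 1.75, 20.0)
    ais = Compartment(nid + 1, nid, "ais", 30.0, 1.75, 1.0, 50.0)
    myelin = Compartment(nid + 2, nid + 1, "myelin", 1000.0, 1.0, 1.0, 1050.0)
    return Morphology(comps + [hillock, ais, myelin], morph.bp_id, morph.tuft_tip_distance)


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def path_distance(morph: Morphology, location: Location) -> float:
    """Path distance (µm) from the soma centre to ``location``."""
    comp_id, frac = location
    c = morph[comp_id]
    if not (0.0 <= frac <= 1.0):
        raise ParameterError(f"arclength fraction {frac} outside [0, 1]")
    if c.domain == "soma":
        return 0.0
    return c.proximal_distance + frac * c.length


def normalized_apical_coordinate(morph: Morphology, location: Location) -> float:
    """Map a location on the soma-BP-tuft axis to x (soma 0, BP 1, tip 2).

    Obliques map through their trunk attachment point; axonal locations are
    outside the apical axis and raise :class:`DomainError`, as do basals.
    """
    comp_id, frac = location
    c = morph[comp_id]
    if c.domain in AXONAL_DOMAINS:
        raise DomainError("axonal locations have no apical coordinate")
    if c.domain == "basal":
        raise DomainError("basal locations are not on the soma-BP-tuft axis")
    if c.domain == "oblique":
        location = morph.trunk_attachment(comp_id)
    d = path_distance(morph, location)
    return normalized_x_from_distance(morph, d, on_tuft=(c.domain == "tuft"))


def normalized_x_from_distance(morph: Morphology, d: float, on_tuft: bool | None = None) -> float:
    """Piecewise-linear map of path distance to the normalized coordinate.

    Distances up to the BP scale to [0, 1]; beyond, to [1, 2] using the most
    distal tuft distance.  ``on_tuft`` overrides the branch choice for
    distances that could fall on either side of the BP.
    """
    bp = morph.bp_distance
    if on_tuft is None:
        on_tuft = d > bp
    if not on_tuft or d <= bp:
        return d / bp
    return 1.0 + (d - bp) / (morph.tuft_tip_distance - bp)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

_SWC_TYPE = {"soma": 1, "axon_hillock": 2, "ais": 2, "myelin": 2,
             "basal": 3, "oblique": 4, "trunk": 4, "tuft": 4}


def _layout_3d(morph: Morphology) -> dict[int, np.ndarray]:
    """Deterministic cosmetic 3D embedding preserving segment lengths."""
    pos = {morph.soma.id: np.zeros(3)}
    direction = {morph.soma.id: np.array([0.0, 1.0, 0.0])}
    golden = math.pi * (3.0 - math.sqrt(5.0))
    counters = {"basal": 0, "oblique": 0, "tuft": 0, "axon": 0}
    for c in morph.compartments[1:]:
        p = pos[c.parent_id]
        if c.domain == "trunk":
            d = np.array([0.0, 1.0, 0.0])
        elif c.domain in AXONAL_DOMAINS:
            d = np.array([0.0, -1.0, 0.0])
        else:
            key = c.domain if c.domain in counters else "basal"
            k = counters[key]
            counters[key] += 1
            az = golden * (k + 1)
            if c.domain == "basal":
                elev = -0.6
            elif c.domain == "oblique":
                elev = 0.15
            else:  # tuft spreads upward
                elev = 0.75 if morph[c.parent_id].domain == "trunk" else 0.55
            d = np.array([math.cos(az) * math.cos(elev), math.sin(elev),
                          math.sin(az) * math.cos(elev)])
        d = d / np.linalg.norm(d)
        pos[c.id] = p + d * c.length
        direction[c.id] = d
    return pos


def write_swc(morph: Morphology, stream, sidecar=None) -> None:
    """Write standard 7-column SWC; sub-domain labels go to ``sidecar``.

    SWC type codes only distinguish soma/axon/basal/apical, so the
    trunk/tuft/oblique (and hillock/AIS/myelin) labels are written as a
    two-column annotation (swc_id, domain) when a sidecar stream is given.
    """
    pos = _layout_3d(morph)
    node_of = {c.id: i + 1 for i, c in enumerate(morph.compartments)}
    stream.write("# id type x y z radius parent\n")
    for c in morph.compartments:
        x, y, z = pos[c.id]
        parent = -1 if c.parent_id is None else node_of[c.parent_id]
        radius = c.diameter_distal / 2.0
        stream.write(f"{node_of[c.id]} {_SWC_TYPE[c.domain]} {x:.6f} {y:.6f} {z:.6f} "
                     f"{radius:.6f} {parent}\n")
    if sidecar is not None:
        for c in morph.compartments:
            sidecar.write(f"{node_of[c.id]}\t{c.domain}\n")


def read_swc(stream, sidecar=None) -> Morphology:
    """Read a 7-column SWC file into a :class:`Morphology`.

    Forward parent references are accepted (nodes are topologically sorted).
    Without a sidecar annotation, apical sub-domains are inferred: the trunk
    is the unique soma -> BP path, the tuft everything distal to the BP, and
    obliques the apical side branches proximal to it.
    """
    rows = {}
    order = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise FormatError("expected 7 columns", lineno)
        try:
            nid, ntype = int(parts[0]), int(parts[1])
            x, y, z, radius = (float(v) for v in parts[2:6])
            parent = int(parts[6])
        except ValueError:
            raise FormatError("non-numeric field", lineno) from None
        if radius <= 0:
            raise FormatError(f"nonpositive radius {radius}", lineno)
        if nid in rows:
            raise FormatError(f"duplicate id {nid}", lineno)
        rows[nid] = (ntype, np.array([x, y, z]), radius, parent, lineno)
        order.append(nid)

    roots = [nid for nid in order if rows[nid][3] == -1]
    if len(roots) != 1:
        raise FormatError(f"expected exactly one root, found {len(roots)}")
    for nid in order:
        parent = rows[nid][3]
        if parent != -1 and parent not in rows:
            raise FormatError(f"orphan parent {parent}", rows[nid][4])

    # topological sort (tolerates forward references); leftover => cycle
    sorted_ids = []
    placed = set()
    pending = list(order)
    while pending:
        progressed = False
        remaining = []
        for nid in pending:
            parent = rows[nid][3]
            if parent == -1 or parent in placed:
                sorted_ids.append(nid)
                placed.add(nid)
                progressed = True
            else:
                remaining.append(nid)
        if not progressed:
            raise FormatError(f"cycle involving ids {remaining}", rows[remaining[0]][4])
        pending = remaining

    labels = {}
    if sidecar is not None:
        for lineno, raw in enumerate(sidecar, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError("sidecar expects two columns", lineno)
            if parts[1] not in ALL_DOMAINS:
                raise FormatError(f"unknown domain {parts[1]!r}", lineno)
            labels[int(parts[0])] = parts[1]

    base_domain = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
    comps: list[Compartment] = []
    cid_of = {}
    dist = {}
    for i, nid in enumerate(sorted_ids):
        ntype, xyz, radius, parent, lineno = rows[nid]
        dom = base_domain.get(ntype, "basal")
        if parent == -1:
            if labels and labels.get(nid) != "soma" and nid in labels:
                dom = labels[nid]
            comps.append(Compartment(i, None, "soma", 2 * radius, 2 * radius,
                                     2 * radius, 0.0))
            cid_of[nid] = i
            dist[i] = 0.0
            continue
        pcid = cid_of[parent]
        length = float(np.linalg.norm(xyz - rows[parent][1]))
        if length <= 0:
            raise FormatError("zero-length segment", lineno)
        parent_comp = comps[pcid]
        d_prox = (2 * radius if parent_comp.domain == "soma"
                  else parent_comp.diameter_distal)
        if nid in labels:
            domain = labels[nid]
        elif dom == "axon":
            domain = "ais"  # refined below for unlabelled axons
        elif dom == "apical":
            domain = "trunk"  # placeholder; resolved by _infer_apical
        else:
            domain = dom
        comps.append(Compartment(i, pcid, domain, length, d_prox, 2 * radius,
                                 dist[pcid] + length))
        cid_of[nid] = i
        dist[i] = dist[pcid] + length

    if not labels:
        comps = _infer_apical(comps)
    bp_id, tip = _find_bp(comps)
    return Morphology(comps, bp_id=bp_id, tuft_tip_distance=tip)


def _children_map(comps):
    ch = {c.id: [] for c in comps}
    for c in comps:
        if c.parent_id is not None:
            ch[c.parent_id].append(c.id)
    return ch


def _infer_apical(comps: list[Compartment]) -> list[Compartment]:
    """Resolve trunk/tuft/oblique labels for unlabelled apical compartments."""
    ch = _children_map(comps)
    apical = {c.id for c in comps if c.domain == "trunk"}  # placeholder label
    if not apical:
        return comps
    by_id = {c.id: c for c in comps}

    def subtree_tip(cid):
        best = by_id[cid].path_distance_to_soma
        for k in ch[cid]:
            if k in apical:
                best = max(best, subtree_tip(k))
        return best

    # deepest apical tip and the path to it
    tips = [cid for cid in apical if not any(k in apical for k in ch[cid])]
    deepest = max(tips, key=lambda cid: by_id[cid].path_distance_to_soma)
    path = []
    cur = deepest
    while cur is not None and cur in apical:
        path.append(cur)
        cur = by_id[cur].parent_id
    path.reverse()

    # BP: bifurcation on that path whose second-deepest apical subtree
    # (beyond the node) extends furthest
    best_bp, best_ext = path[-1], -1.0
    for cid in path:
        kids = [k for k in ch[cid] if k in apical]
        if len(kids) >= 2:
            exts = sorted(subtree_tip(k) - by_id[cid].path_distance_to_soma
                          for k in kids)
            second = exts[-2]
            if second >= best_ext:
                best_ext = second
                best_bp = cid
    trunk_path = set()
    cur = best_bp
    while cur is not None and cur in apical:
        trunk_path.add(cur)
        cur = by_id[cur].parent_id

    def beyond_bp(cid):
        cur = cid
        while cur is not None:
            if cur == best_bp:
                return True
            cur = by_id[cur].parent_id
        return False

    out = []
    for c in comps:
        if c.id not in apical:
            out.append(c)
        elif c.id in trunk_path:
            out.append(replace(c, domain="trunk"))
        elif beyond_bp(c.id):
            out.append(replace(c, domain="tuft"))
        else:
            out.append(replace(c, domain="oblique"))
    return out


def _find_bp(comps: list[Compartment]) -> tuple[int, float]:
    trunk = [c for c in comps if c.domain == "trunk"]
    if not trunk:
        raise FormatError("no trunk compartments; cannot locate the BP")
    bp = max(trunk, key=lambda c: c.path_distance_to_soma)
    tufts = [c for c in comps if c.domain == "tuft"]
    tip = (max(c.path_distance_to_soma for c in tufts) if tufts
           else bp.path_distance_to_soma + 1.0)
    return bp.id, tip
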
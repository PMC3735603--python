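"""Structured tetrahedral meshing of the idealized growth-cone geometry.

The non-spread growth cone is a quarter ball sitting on the substrate
(z = 0) with its flat vertical face (the neurite contact area) in the x = 0
plane and the solid extending toward +x; filopodia are half-cylinders lying
on the substrate, radiating outward from the cone along in-plane directions
near the +x axis.

Meshes are generated from mapped structured grids (spherical and
cylindrical coordinates) whose hexahedral cells are split into tetrahedra
with the Kuhn subdivision, which is face-consistent across a structured
grid; degenerate cells at coordinate singularities collapse to fewer
tetrahedra and are dropped.  No external geometry kernel is involved, so a
given geometry and target edge length always reproduce the identical mesh.

The cone and each filopodium are meshed as separate blocks; the
filopodium's proximal cap is joined to the cone by master-slave node ties
(inverse-distance weights over the nearest cone-surface nodes), recorded on
the mesh and honoured by the solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FilopodiumSpec", "ConeGeometry", "TetMesh", "build_mesh",
           "box_mesh", "mesh_volume"]

# Kuhn subdivision of a hexahedron (corner bits x,y,z -> 0..7) into six
# tetrahedra around the main diagonal 0-6; face-consistent on a grid.
_KUHN = [(0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6),
         (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6)]
_CORNER_BITS = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
                (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]


@dataclass(frozen=True)
class FilopodiumSpec:
    """One half-cylindrical filopodium on the substrate.

    ``length_frac`` is the length as a multiple of the growth-cone radius
    (the modelled range is [0.001, 2]); ``orientation_deg`` the in-plane
    angle from the +x axis; ``shaft_radius`` in um.
    """

    length_frac: float
    orientation_deg: float = 0.0
    shaft_radius: float = 0.1

    def __post_init__(self) -> None:
        if self.length_frac <= 0 or self.shaft_radius <= 0:
            raise ValueError("filopodium length and radius must be positive")
        if not -90.0 < self.orientation_deg < 90.0:
            raise ValueError("orientation must stay within the +x sector")


@dataclass(frozen=True)
class ConeGeometry:
    """Quarter-sphere growth cone with 1-3 emerging filopodia."""

    cone_radius: float = 1.14
    filopodia: tuple[FilopodiumSpec, ...] = (FilopodiumSpec(0.5),)

    def __post_init__(self) -> None:
        if self.cone_radius <= 0:
            raise ValueError("cone radius must be positive")
        if not 1 <= len(self.filopodia) <= 3:
            raise ValueError("the model carries 1-3 filopodia")
        specs = sorted(self.filopodia, key=lambda f: f.orientation_deg)
        for a, b in zip(specs[:-1], specs[1:]):
            gap = math.radians(b.orientation_deg - a.orientation_deg)
            # interpenetration of the shafts at the cone surface (tangency
            # of neighbouring half-cylinders is tolerated)
            min_gap = 0.9 * (a.shaft_radius + b.shaft_radius) / self.cone_radius
            if gap < min_gap:
                raise ValueError("filopodia placement self-intersects")


@dataclass
class TetMesh:
    """4-node tetrahedral mesh with named node sets and region tags.

    ``node_sets`` holds the boundary sets used by the standard BCs
    (``cone_bottom``, ``contact_area``, and per filopodium ``filo{i}_cap``,
    ``filo{i}_interface``, ``filo{i}_bottom``, ``filo{i}_end_line``);
    ``element_tags`` is 0 for cone elements and ``i + 1`` for filopodium
    ``i``; ``ties`` couples each cap node to cone-surface master nodes with
    interpolation weights.
    """

    nodes: np.ndarray                      # (N, 3)
    tets: np.ndarray                       # (M, 4)
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_tags: np.ndarray | None = None
    # (slave node, master nodes, weights, coupling direction): the slave's
    # displacement component along the direction follows the interpolated
    # master component; its transverse components stay free unknowns.
    ties: list[tuple[int, np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=list)

    def __post_init__(self) -> None:
        if np.any(_tet_volumes(self.nodes, self.tets) <= 0):
            raise ValueError("mesh contains non-positive-volume elements")
        for name, ids in self.node_sets.items():
            if ids.size and ids.max() >= len(self.nodes):
                raise ValueError(f"node set {name} references unknown nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)


def _tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def mesh_volume(mesh: TetMesh) -> float:
    return float(_tet_volumes(mesh.nodes, mesh.tets).sum())


class _Builder:
    """Accumulates deduplicated nodes and Kuhn-split tetrahedra."""

    def __init__(self) -> None:
        self.coords: list[np.ndarray] = []
        self._ids: dict[tuple, int] = {}
        self.tets: list[tuple[int, int, int, int]] = []

    def node(self, key: tuple, xyz) -> int:
        if key not in self._ids:
            self._ids[key] = len(self.coords)
            self.coords.append(np.asarray(xyz, dtype=float))
        return self._ids[key]

    def hex_cell(self, corner_ids: list[int]) -> None:
        pts = [self.coords[i] for i in corner_ids]
        for tet in _KUHN:
            ids = tuple(corner_ids[v] for v in tet)
            if len(set(ids)) < 4:
                continue
            a, b, c = (pts[tet[1]] - pts[tet[0]], pts[tet[2]] - pts[tet[0]],
                       pts[tet[3]] - pts[tet[0]])
            vol = float(np.dot(a, np.cross(b, c))) / 6.0
            if abs(vol) < 1e-18:
                continue
            if vol < 0:
                ids = (ids[0], ids[2], ids[1], ids[3])
            self.tets.append(ids)


def _mesh_quarter_ball(b: _Builder, radius: float, target_edge: float
                       ) -> None:
    n_r = max(3, round(radius / target_edge))
    n_t = max(4, round(0.5 * math.pi * radius / target_edge))
    n_p = max(6, 2 * round(0.5 * math.pi * radius / target_edge))

    def nid(i: int, j: int, k: int) -> int:
        if i == 0:
            return b.node(("qb", 0), (0.0, 0.0, 0.0))
        r = radius * i / n_r
        if j == 0:  # polar axis (+z)
            return b.node(("qb-axis", i), (0.0, 0.0, r))
        th = 0.5 * math.pi * j / n_t
        ph = -0.5 * math.pi + math.pi * k / n_p
        return b.node(("qb", i, j, k),
                      (r * math.sin(th) * math.cos(ph),
                       r * math.sin(th) * math.sin(ph),
                       r * math.cos(th)))

    for i in range(n_r):
        for j in range(n_t):
            for k in range(n_p):
                corners = [nid(i + di, j + dj, k + dk)
                           for (di, dj, dk) in _CORNER_BITS]
                b.hex_cell(corners)


def _mesh_half_cylinder(b: _Builder, tag: int, radius: float, spec:
                        FilopodiumSpec, target_edge: float) -> dict:
    """Half-cylinder lying on z = 0 from r = cone radius outward."""
    length = spec.length_frac * radius
    rho = spec.shaft_radius
    al = math.radians(spec.orientation_deg)
    e_ax = np.array([math.cos(al), math.sin(al), 0.0])
    e_q = np.array([-math.sin(al), math.cos(al), 0.0])
    e_z = np.array([0.0, 0.0, 1.0])
    n_s = max(2, round(length / target_edge))
    n_p = max(2, round(rho / target_edge))
    n_c = max(4, round(math.pi * rho / target_edge))

    def nid(m: int, p: int, c: int) -> int:
        s = radius + length * m / n_s
        if p == 0:
            return b.node(("fl-ax", tag, m), s * e_ax)
        r = rho * p / n_p
        chi = math.pi * c / n_c
        xyz = s * e_ax + r * math.cos(chi) * e_q + r * math.sin(chi) * e_z
        return b.node(("fl", tag, m, p, c), xyz)

    first = len(b.tets)
    for m in range(n_s):
        for p in range(n_p):
            for c in range(n_c):
                corners = [nid(m + dm, p + dp, c + dc)
                           for (dm, dp, dc) in _CORNER_BITS]
                b.hex_cell(corners)
    cap = {nid(0, p, c) for p in range(n_p + 1) for c in range(n_c + 1)}
    end_line = {nid(n_s, p, c)
                for p in range(n_p + 1) for c in range(n_c + 1)
                if p == 0 or c in (0, n_c)}
    bottom = {nid(m, p, c)
              for m in range(1, n_s) for p in range(n_p + 1)
              for c in range(n_c + 1) if p == 0 or c in (0, n_c)}
    ring = {nid(0, n_p, c) for c in range(n_c + 1)} | \
        {nid(0, p, c) for p in range(n_p + 1) for c in (0, n_c)}
    return {"cap": cap, "end_line": end_line, "bottom": bottom - cap - end_line,
            "ring": ring, "axis": e_ax, "slice": (first, len(b.tets))}


def _attachment_weights(attachment: np.ndarray, surface_ids: np.ndarray,
                        nodes: np.ndarray, window: float
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Smooth Gaussian window of cone-surface nodes around the attachment.

    All cap nodes of one filopodium share this master set and weighting, so
    the coupling (and the local patch stiffness it sees) varies smoothly
    when the filopodium is re-oriented relative to the cone grid.
    """
    d = np.linalg.norm(nodes[surface_ids] - attachment, axis=1)
    inside = d <= window
    if not inside.any():
        inside = d <= d.min() + 1e-12
    w = np.exp(-(d[inside] / (0.5 * window)) ** 2)
    return surface_ids[inside], w / w.sum()


def build_mesh(geometry: ConeGeometry, target_edge: float,
               cone_edge: float | None = None) -> TetMesh:
    """Mesh the quarter-sphere + half-cylinder union.

    ``target_edge`` must resolve the filopodium shaft (be smaller than its
    radius); the cone block may use the coarser ``cone_edge`` (default four
    times ``target_edge``) since its field is smooth.  Boundary node sets
    and region tags are populated; every element has positive volume.
    """
    for spec in geometry.filopodia:
        if target_edge >= spec.shaft_radius:
            raise ValueError(
                "target edge length must be smaller than the filopodium "
                "shaft radius")
    if cone_edge is None:
        cone_edge = 3.0 * target_edge
    b = _Builder()
    _mesh_quarter_ball(b, geometry.cone_radius, cone_edge)
    n_cone_elems = len(b.tets)
    filo_info = [
        _mesh_half_cylinder(b, i, geometry.cone_radius, spec, target_edge)
        for i, spec in enumerate(geometry.filopodia)
    ]
    nodes = np.asarray(b.coords)
    tets = np.asarray(b.tets, dtype=int)
    tags = np.zeros(len(tets), dtype=int)
    for i, info in enumerate(filo_info):
        lo, hi = info["slice"]
        tags[lo:hi] = i + 1

    tol = 1e-9
    r = np.linalg.norm(nodes, axis=1)
    cone_node_mask = np.zeros(len(nodes), dtype=bool)
    cone_node_mask[np.unique(tets[:n_cone_elems])] = True
    sets: dict[str, np.ndarray] = {
        "cone_bottom": np.flatnonzero(cone_node_mask & (np.abs(nodes[:, 2]) < tol)),
        "contact_area": np.flatnonzero(cone_node_mask & (np.abs(nodes[:, 0]) < tol)),
    }
    surface_ids = np.flatnonzero(
        cone_node_mask & (np.abs(r - geometry.cone_radius) < 1e-6 *
                          geometry.cone_radius))
    ties = []
    for i, info in enumerate(filo_info):
        sets[f"filo{i}_cap"] = np.asarray(sorted(info["cap"]), dtype=int)
        sets[f"filo{i}_interface"] = np.asarray(sorted(info["ring"]), dtype=int)
        sets[f"filo{i}_end_line"] = np.asarray(sorted(info["end_line"]), dtype=int)
        sets[f"filo{i}_bottom"] = np.asarray(sorted(info["bottom"]), dtype=int)
        spec = geometry.filopodia[i]
        attachment = geometry.cone_radius * info["axis"]
        window = max(2.5 * spec.shaft_radius, 0.6 * geometry.cone_radius)
        masters, w = _attachment_weights(attachment, surface_ids, nodes,
                                         window)
        for s in sorted(info["cap"]):
            ties.append((int(s), masters, w, info["axis"]))
    mesh = TetMesh(nodes, tets, sets, tags, ties)
    mesh.filopodium_axes = [info["axis"] for info in filo_info]
    return mesh


def box_mesh(lengths=(1.0, 1.0, 1.0), divisions=(4, 4, 4)) -> TetMesh:
    """Structured tet mesh of a box; used for patch and sanity tests."""
    (lx, ly, lz), (nx, ny, nz) = lengths, divisions
    b = _Builder()

    def nid(i, j, k):
        return b.node(("box", i, j, k), (lx * i / nx, ly * j / ny, lz * k / nz))

    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                b.hex_cell([nid(i + di, j + dj, k + dk)
                            for (di, dj, dk) in _CORNER_BITS])
    nodes = np.asarray(b.coords)
    tets = np.asarray(b.tets, dtype=int)
    tol = 1e-12
    sets = {
        "x0": np.flatnonzero(np.abs(nodes[:, 0]) < tol),
        "x1": np.flatnonzero(np.abs(nodes[:, 0] - lx) < tol),
        "boundary": np.flatnonzero(
            (np.abs(nodes[:, 0]) < tol) | (np.abs(nodes[:, 0] - lx) < tol)
            | (np.abs(nodes[:, 1]) < tol) | (np.abs(nodes[:, 1] - ly) < tol)
            | (np.abs(nodes[:, 2]) < tol) | (np.abs(nodes[:, 2] - lz) < tol)),
    }
    return TetMesh(nodes, tets, sets, np.zeros(len(tets), dtype=int))
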
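"""Small-strain linear elasticity on tet4 meshes with Von Mises recovery.

Quasi-static, isotropic, nearly incompressible (default nu = 0.47); plain
displacement formulation.  Boundary conditions combine per-axis prescribed
components (clamps, imposed shortening), "sliding" nodes restricted to move
only along a given unit direction (the transverse components are zero), and
the mesh's master-slave ties.  Constraints are eliminated through a sparse
transformation u = T a + u_p, and the reduced SPD system is solved
directly, so free nodes satisfy equilibrium to solver precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import linalg as sla

from .mesh import ConeGeometry, FilopodiumSpec, TetMesh, build_mesh

__all__ = ["Material", "BCSet", "ElasticSolution", "solve", "von_mises",
           "standard_bcs", "interface_max_vm", "sweep_surface", "write_vtk"]


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material (E in Pa)."""

    E: float = 1.0e6
    nu: float = 0.47

    def __post_init__(self) -> None:
        if self.E <= 0 or not 0.0 <= self.nu < 0.5:
            raise ValueError("need E > 0 and 0 <= nu < 0.5")

    @property
    def D(self) -> np.ndarray:
        lam = self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.E / (2 * (1 + self.nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] = lam + 2 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        return D


@dataclass
class BCSet:
    """Accumulated boundary conditions.

    ``components[node]`` is (mask, values): prescribed displacement on the
    masked global axes.  ``sliding[node]`` is a unit direction: the node
    may move only along it.  A node may not appear in both.
    """

    components: dict[int, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict)
    sliding: dict[int, np.ndarray] = field(default_factory=dict)

    def prescribe(self, node_ids, mask, values) -> "BCSet":
        mask = np.asarray(mask, dtype=bool)
        values = np.asarray(values, dtype=float)
        for n in np.atleast_1d(node_ids):
            n = int(n)
            if n in self.sliding:
                raise ValueError(f"node {n} already has a sliding constraint")
            if n in self.components:
                m0, v0 = self.components[n]
                m, v = m0 | mask, v0.copy()
                v[mask] = values[mask]
                self.components[n] = (m, v)
            else:
                self.components[n] = (mask.copy(), np.where(mask, values, 0.0))
        return self

    def fix(self, node_ids, values=(0.0, 0.0, 0.0)) -> "BCSet":
        return self.prescribe(node_ids, (True, True, True), values)

    def slide(self, node_ids, axis) -> "BCSet":
        e = np.asarray(axis, dtype=float)
        e = e / np.linalg.norm(e)
        for n in np.atleast_1d(node_ids):
            n = int(n)
            if n not in self.components:
                self.sliding[n] = e
        return self


@dataclass
class ElasticSolution:
    """Nodal displacements and per-element stress state."""

    displacements: np.ndarray   # (N, 3)
    stresses: np.ndarray        # (M, 6): sx, sy, sz, txy, tyz, txz
    vm: np.ndarray              # (M,)
    residual: float             # relative equilibrium residual, free dofs


def von_mises(sx, sy, sz, txy, tyz, txz):
    """Standard Von Mises invariant of the symmetric stress tensor."""
    return np.sqrt(0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
                   + 3.0 * (np.asarray(txy) ** 2 + np.asarray(tyz) ** 2
                            + np.asarray(txz) ** 2))


def _element_matrices(mesh: TetMesh, D: np.ndarray):
    x = mesh.nodes[mesh.tets]                       # (M, 4, 3)
    ones = np.ones((len(x), 4, 1))
    M4 = np.concatenate([ones, x], axis=2)          # rows [1 x y z]
    vol = np.linalg.det(M4) / 6.0
    C = np.linalg.inv(M4)                           # (M, 4, 4)
    grads = C[:, 1:4, :]                            # dN_i = grads[:, :, i]
    M = len(x)
    B = np.zeros((M, 6, 12))
    bx, by, bz = grads[:, 0, :], grads[:, 1, :], grads[:, 2, :]
    for i in range(4):
        B[:, 0, 3 * i + 0] = bx[:, i]
        B[:, 1, 3 * i + 1] = by[:, i]
        B[:, 2, 3 * i + 2] = bz[:, i]
        B[:, 3, 3 * i + 0] = by[:, i]
        B[:, 3, 3 * i + 1] = bx[:, i]
        B[:, 4, 3 * i + 1] = bz[:, i]
        B[:, 4, 3 * i + 2] = by[:, i]
        B[:, 5, 3 * i + 0] = bz[:, i]
        B[:, 5, 3 * i + 2] = bx[:, i]
    Ke = np.einsum("mji,jk,mkl,m->mil", B, D, B, vol)
    return B, Ke, vol


def _assemble(mesh: TetMesh, D: np.ndarray):
    B, Ke, vol = _element_matrices(mesh, D)
    dof = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(len(mesh.tets), 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sparse.coo_matrix((Ke.ravel(), (rows, cols)),
                          shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes)).tocsr()
    return K, B


def _transformation(mesh: TetMesh, bcs: BCSet):
    """Sparse map u = T a + u_p eliminating ties and constraints."""
    n = mesh.n_nodes
    u_p = np.zeros(3 * n)
    slaves = {s for s, _, _, _ in mesh.ties}
    cols: list[tuple[int, int, float]] = []   # (dof row, reduced col, coeff)
    n_red = 0
    node_cols: dict[int, list[tuple[int, int, float]]] = {}
    for node in range(n):
        if node in slaves:
            continue
        if node in bcs.sliding:
            e = bcs.sliding[node]
            node_cols[node] = [(3 * node + ax, n_red, e[ax]) for ax in range(3)
                               if e[ax] != 0.0]
            n_red += 1
        elif node in bcs.components:
            mask, values = bcs.components[node]
            entries = []
            for ax in range(3):
                if mask[ax]:
                    u_p[3 * node + ax] = values[ax]
                else:
                    entries.append((3 * node + ax, n_red, 1.0))
                    n_red += 1
            node_cols[node] = entries
        else:
            node_cols[node] = [(3 * node + ax, n_red + ax, 1.0)
                               for ax in range(3)]
            n_red += 3
    for node, entries in node_cols.items():
        cols.extend(entries)
    for s, masters, w, e in mesh.ties:
        # two free transverse dofs spanning the plane normal to the
        # coupling direction, plus the dependent axial component
        t1 = np.cross([0.0, 0.0, 1.0], e)
        if np.linalg.norm(t1) < 1e-12:
            t1 = np.cross([1.0, 0.0, 0.0], e)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(e, t1)
        for vec in (t1, t2):
            for ax in range(3):
                if vec[ax] != 0.0:
                    cols.append((3 * s + ax, n_red, vec[ax]))
            n_red += 1
        for m, wm in zip(masters, w):
            m = int(m)
            if m in slaves:
                raise ValueError("tie master is itself a slave")
            axial_p = wm * float(e @ u_p[3 * m: 3 * m + 3])
            for ax in range(3):
                u_p[3 * s + ax] += axial_p * e[ax]
            for row, col, coeff in node_cols.get(m, []):
                proj = wm * e[row % 3] * coeff
                for ax in range(3):
                    if proj * e[ax] != 0.0:
                        cols.append((3 * s + ax, col, proj * e[ax]))
    rows = np.array([c[0] for c in cols])
    ccols = np.array([c[1] for c in cols])
    vals = np.array([c[2] for c in cols])
    T = sparse.coo_matrix((vals, (rows, ccols)),
                          shape=(3 * n, n_red)).tocsr()
    return T, u_p


def solve(mesh: TetMesh, material: Material, bcs: BCSet) -> ElasticSolution:
    """Solve the constrained quasi-static problem.

    Raises
    ------
    ValueError
        If the constraints leave the reduced system singular.
    """
    if not bcs.components:
        raise ValueError("insufficient constraints: no prescribed "
                         "displacements anywhere")
    D = material.D
    K, B = _assemble(mesh, D)
    T, u_p = _transformation(mesh, bcs)
    if T.shape[1] == 0:
        u = u_p
    else:
        A = (T.T @ K @ T).tocsc()
        rhs = -T.T @ (K @ u_p)
        try:
            a = sla.spsolve(A, rhs)
        except Exception as exc:  # pragma: no cover - scipy error path
            raise ValueError(f"singular constrained system: {exc}") from exc
        if not np.all(np.isfinite(a)):
            raise ValueError("singular constrained system "
                             "(insufficient constraints)")
        rhs_norm = float(np.linalg.norm(rhs))
        if rhs_norm > 0 and \
                float(np.linalg.norm(A @ a - rhs)) > 1e-6 * rhs_norm:
            raise ValueError("singular constrained system "
                             "(rank-deficient after elimination)")
        u = T @ a + u_p
    ue = u.reshape(-1, 3)[mesh.tets].reshape(len(mesh.tets), 12)
    stresses = np.einsum("ij,mjk,mk->mi", D, B, ue)
    vm = von_mises(*(stresses[:, i] for i in range(6)))
    f_int = K @ u
    scale = float(np.abs(f_int).max()) or 1.0
    residual = float(np.abs(T.T @ f_int).max() / scale) if T.shape[1] else 0.0
    return ElasticSolution(u.reshape(-1, 3), stresses, vm, residual)


def standard_bcs(mesh: TetMesh, geometry: ConeGeometry,
                 shortening: float | None = None) -> BCSet:
    """The growth-cone loading pattern.

    Filopodial tip ending lines fully fixed to the substrate; filopodial
    shafts and the cone bottom surface slide only along their longitudinal
    axes; the neurite contact area is shortened by ``shortening`` um along
    -x (default 5% of the cone radius; normalized outputs are insensitive
    to it by linearity).
    """
    delta = (0.05 * geometry.cone_radius if shortening is None
             else shortening)
    bcs = BCSet()
    for i in range(len(geometry.filopodia)):
        bcs.fix(mesh.node_sets[f"filo{i}_end_line"])
    bcs.prescribe(mesh.node_sets["contact_area"],
                  (True, False, False), (-delta, 0.0, 0.0))
    bcs.prescribe(mesh.node_sets["cone_bottom"],
                  (False, True, True), (0.0, 0.0, 0.0))
    for i in range(len(geometry.filopodia)):
        bcs.slide(mesh.node_sets[f"filo{i}_bottom"], mesh.filopodium_axes[i])
    return bcs


def interface_max_vm(solution: ElasticSolution, mesh: TetMesh,
                     filopodium: int, normalize_by: float | None = None
                     ) -> float:
    """Maximum Von Mises stress on a filopodium's interface ring.

    The maximum is taken over the filopodium's elements adjacent to its
    proximal interface with the growth cone; optionally normalized by a
    reference stress (e.g. the shortest filopodium's value).
    """
    key = f"filo{filopodium}_interface"
    if key not in mesh.node_sets:
        raise KeyError(f"unknown filopodium id {filopodium}")
    ring = set(mesh.node_sets[key].tolist())
    mask = (mesh.element_tags == filopodium + 1) & np.array(
        [bool(ring.intersection(t)) for t in mesh.tets.tolist()])
    if not mask.any():
        raise ValueError(f"filopodium {filopodium} has no interface elements")
    value = float(solution.vm[mask].max())
    return value / normalize_by if normalize_by else value


def sweep_surface(lengths_frac, orientations_deg,
                  material: Material | None = None,
                  cone_radius: float = 1.14,
                  shaft_radius: float = 0.1,
                  target_edge: float = 0.06,
                  shortening: float | None = None) -> pd.DataFrame:
    """Interface stress surface over filopodium length and orientation.

    One single-filopodium solve per grid point; values are normalized on
    the interface VM stress at orientation 0 deg and the smallest length in
    the grid, so that cell equals 1 exactly.  Returns a tidy frame with
    columns ``length_frac``, ``orientation_deg``, ``vm_normalized``.
    """
    lengths = sorted(float(x) for x in lengths_frac)
    orients = [float(x) for x in orientations_deg]
    if not lengths or not orients:
        raise ValueError("length and orientation grids must be non-empty")
    if 0.0 not in orients:
        raise ValueError("the orientation grid must contain 0 deg "
                         "(normalization cell)")
    material = material or Material()

    def one(length, orient):
        geo = ConeGeometry(cone_radius,
                           (FilopodiumSpec(length, orient, shaft_radius),))
        mesh = build_mesh(geo, target_edge)
        sol = solve(mesh, material, standard_bcs(mesh, geo, shortening))
        return interface_max_vm(sol, mesh, 0)

    ref = one(lengths[0], 0.0)
    rows = []
    for length in lengths:
        for orient in orients:
            vm = ref if (length == lengths[0] and orient == 0.0) \
                else one(length, orient)
            rows.append((length, orient, vm / ref))
    return pd.DataFrame(rows, columns=["length_frac", "orientation_deg",
                                       "vm_normalized"])


def write_vtk(mesh: TetMesh, solution: ElasticSolution, path) -> None:
    """Legacy-ASCII VTK export: point displacements and cell VM stress."""
    lines = ["# vtk DataFile Version 3.0", "filoguide growth-cone FE",
             "ASCII", "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.nodes]
    lines.append(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}")
    lines += [f"4 {a} {b} {c} {d}" for a, b, c, d in mesh.tets]
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines += ["10"] * mesh.n_elements
    lines.append(f"POINT_DATA {mesh.n_nodes}")
    lines.append("VECTORS displacement double")
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in solution.displacements]
    lines.append(f"CELL_DATA {mesh.n_elements}")
    lines.append("SCALARS von_mises double 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{v:.9g}" for v in solution.vm]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
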
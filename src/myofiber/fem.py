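"""Linear finite elements for Laplace-Dirichlet problems.

The fiber-generation rules only ever need harmonic potentials: solutions of
``-Δu = 0`` with Dirichlet values on labeled surface patches (or at single
snapped vertices, e.g. an apex) and homogeneous Neumann conditions on the
rest of the boundary.  This module assembles the P1 (tet4) / Q1 (hex8)
stiffness matrix, eliminates Dirichlet rows symmetrically and solves the
reduced SPD system with Jacobi-preconditioned conjugate gradients.

Only degree-1 elements are supported; they are exact for the globally
linear potentials arising on slab geometries, which several analytic
checks rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from .errors import ConfigurationError, IllPosedError, MeshError, NumericalError
from .mesh import HEX, TET, LabeledMesh

DEFAULT_TOL = 1e-12
DEFAULT_MAXITER = 10_000


@dataclass
class DirichletSpec:
    """Dirichlet data: per-surface-label values and per-point values.

    Point constraints are snapped to the nearest mesh vertex; they model
    point-like boundaries such as the apex or the sphere poles.
    """

    surface_values: dict = field(default_factory=dict)
    point_values: list = field(default_factory=list)  # [(xyz, value), ...]

    def resolve(self, mesh: LabeledMesh):
        """Return (dof indices, prescribed values) on the given mesh."""
        idx: list[int] = []
        val: list[float] = []
        labels = mesh.label_set
        for label, v in self.surface_values.items():
            if int(label) not in labels:
                raise ConfigurationError(
                    f"boundary label {label} not present in mesh (labels: {sorted(labels)})"
                )
            verts = mesh.vertices_on_labels(int(label))
            idx.extend(verts.tolist())
            val.extend([float(v)] * len(verts))
        snapped = set()
        for point, v in self.point_values:
            j = mesh.nearest_vertex(point)
            if j in snapped:
                raise ConfigurationError(
                    f"two point constraints snap to the same vertex {j}"
                )
            snapped.add(j)
            idx.append(j)
            val.append(float(v))
        if not idx:
            raise IllPosedError("no Dirichlet constraint given: Laplace problem is singular")
        idx_arr = np.asarray(idx, dtype=np.int64)
        val_arr = np.asarray(val, dtype=np.float64)
        # deduplicate, last assignment wins (point constraints override surfaces)
        order = np.arange(idx_arr.size)
        uniq: dict[int, float] = {}
        for o in order:
            uniq[int(idx_arr[o])] = float(val_arr[o])
        keys = np.fromiter(uniq.keys(), dtype=np.int64)
        vals = np.fromiter(uniq.values(), dtype=np.float64)
        return keys, vals


# ------------------------------------------------------------------ assembly

_GAUSS_1D = np.array([-1.0, 1.0]) / np.sqrt(3.0)


def _hex_shape_gradients():
    """Gradients of the 8 trilinear shape functions at the 2x2x2 Gauss points.

    Returns an (8 gp, 8 nodes, 3) array in the reference cell [-1, 1]^3.
    """
    signs = np.array(
        [
            [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
            [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
        ],
        dtype=np.float64,
    )
    gp = np.array([[x, y, z] for z in _GAUSS_1D for y in _GAUSS_1D for x in _GAUSS_1D])
    dN = np.empty((8, 8, 3))
    for g, xi in enumerate(gp):
        for a, s in enumerate(signs):
            # N_a = prod_i (1 + s_i xi_i) / 8 ; dN/dxi_i = s_i/8 prod_{j!=i}(...)
            prod = 1 + s * xi
            for i in range(3):
                dN[g, a, i] = s[i] * np.prod(np.delete(prod, i)) / 8.0
    return dN


_HEX_DN = _hex_shape_gradients()


def tet_gradients(mesh: LabeledMesh):
    """Per-cell P1 shape gradients G (m, 4, 3) and volumes (m,)."""
    x = mesh.vertices[mesh.cells]
    d = x[:, 1:] - x[:, :1]  # (m, 3, 3) rows e1,e2,e3
    det = np.linalg.det(d)
    if np.any(np.abs(det) < 1e-300):
        raise MeshError("degenerate (zero-volume) tetrahedron")
    dinv = np.linalg.inv(d)  # (m, 3, 3)
    g = np.empty((mesh.n_cells, 4, 3))
    g[:, 1:, :] = np.transpose(dinv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    vol = det / 6.0
    if np.any(vol <= 0):
        raise MeshError("negatively oriented tetrahedron")
    return g, vol


def hex_gauss_data(mesh: LabeledMesh):
    """Physical shape gradients (m, 8gp, 8nodes, 3) and w*detJ (m, 8gp)."""
    x = mesh.vertices[mesh.cells]  # (m, 8, 3)
    # J[m, g, k, l] = d x_l / d xi_k
    J = np.einsum("gnk,mnl->mgkl", _HEX_DN, x)
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        raise MeshError("non-positive Jacobian in hexahedral cell")
    Jinv = np.linalg.inv(J)
    # grad_x N = J^{-1} grad_xi N
    gx = np.einsum("mgkl,gnk->mgnl", Jinv, _HEX_DN)
    w = detJ  # all Gauss weights are 1
    return gx, w


def assemble_stiffness(mesh: LabeledMesh) -> sparse.csr_matrix:
    """Assemble the (symmetric) Laplace stiffness matrix."""
    n = mesh.n_vertices
    if mesh.element_type == TET:
        g, vol = tet_gradients(mesh)
        ke = np.einsum("mik,mjk,m->mij", g, g, vol)
        conn = mesh.cells
    else:
        gx, w = hex_gauss_data(mesh)
        ke = np.einsum("mgik,mgjk,mg->mij", gx, gx, w)
        conn = mesh.cells
    nv = conn.shape[1]
    rows = np.repeat(conn, nv, axis=1).ravel()
    cols = np.tile(conn, (1, nv)).ravel()
    K = sparse.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n))
    return K.tocsr()


def solve_laplace(
    mesh: LabeledMesh,
    bc: DirichletSpec,
    degree: int = 1,
    tol: float = DEFAULT_TOL,
    maxiter: int = DEFAULT_MAXITER,
) -> np.ndarray:
    """Solve -Δu = 0 with Dirichlet data `bc` and homogeneous Neumann elsewhere.

    Returns the nodal solution as an (n_vertices,) array.
    """
    if degree != 1:
        raise ConfigurationError(
            f"FE space degree {degree} not supported: only degree 1 is implemented"
        )
    K = assemble_stiffness(mesh)
    didx, dval = bc.resolve(mesh)
    n = mesh.n_vertices
    u = np.zeros(n)
    u[didx] = dval
    free = np.ones(n, dtype=bool)
    free[didx] = False
    if not free.any():
        return u
    Kff = K[free][:, free].tocsr()
    rhs = -K[free][:, ~free] @ u[~free]
    diag = Kff.diagonal()
    if np.any(diag <= 0):
        raise MeshError("non-positive stiffness diagonal (degenerate mesh)")
    M = sparse.diags(1.0 / diag)
    it = [0]

    def _count(_):
        it[0] += 1

    x, info = cg(Kff, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=M, callback=_count)
    if info > 0:
        raise NumericalError(
            f"conjugate gradients did not converge in {it[0]} iterations "
            f"(rtol={tol:g}, n={Kff.shape[0]})"
        )
    if info < 0:
        raise NumericalError(f"conjugate gradients failed (info={info})")
    u[free] = x
    return u


def cell_gradients(mesh: LabeledMesh, values: np.ndarray):
    """Per-cell (average) gradient of a nodal field and cell volumes."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (mesh.n_vertices,):
        raise MeshError("field not aligned with mesh")
    if mesh.element_type == TET:
        g, vol = tet_gradients(mesh)
        grad = np.einsum("mik,mi->mk", g, values[mesh.cells])
    else:
        gx, w = hex_gauss_data(mesh)
        gp_grad = np.einsum("mgik,mi->mgk", gx, values[mesh.cells])
        vol = w.sum(axis=1)
        grad = np.einsum("mgk,mg->mk", gp_grad, w) / vol[:, None]
    return grad, vol


def gradient(mesh: LabeledMesh, values: np.ndarray) -> np.ndarray:
    """Volume-weighted nodal recovery of the gradient of a nodal field.

    Per-cell gradients (constant on tets, quadrature-averaged on hexes) are
    averaged onto vertices with cell-volume weights; this recovery is exact
    for globally linear fields.
    """
    grad, vol = cell_gradients(mesh, values)
    n = mesh.n_vertices
    acc = np.zeros((n, 3))
    wgt = np.zeros(n)
    for a in range(mesh.cells.shape[1]):
        np.add.at(acc, mesh.cells[:, a], grad * vol[:, None])
        np.add.at(wgt, mesh.cells[:, a], vol)
    return acc / wgt[:, None]
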
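"""Angular-error metric and the mesh-sensitivity study protocol.

The fiber fields produced by the rules are unit vectors, so the difference
between two numerical solutions reduces to an orientation angle:
``delta_theta = |arccos(f_a . f_b)|``.  The sensitivity protocol runs the
fiber generation on a family of uniformly refined meshes of the same
labeled geometry, evaluates every coarse fiber field at the finest mesh's
vertices, and reports the average and maximum angular error per level; the
finest level is the reference and carries no error row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, OutOfDomainError
from .ldrbm import generate_fibers
from .mesh import HEX, TET, LabeledMesh


def angular_error(f_a: np.ndarray, f_b: np.ndarray) -> np.ndarray | float:
    """Angle in degrees between unit vectors, elementwise for (n, 3) input.

    The dot product is clamped to [-1, 1] before arccos, so numerically
    just-past-unit inputs do not raise.  Non-unit inputs violate the
    contract and raise ValueError.
    """
    a = np.atleast_2d(np.asarray(f_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(f_b, dtype=np.float64))
    for v, name in ((a, "f_a"), (b, "f_b")):
        if np.any(np.abs(np.linalg.norm(v, axis=1) - 1.0) > 1e-6):
            raise ValueError(f"{name} must be unit-norm")
    dots = np.clip(np.einsum("ij,ij->i", a, b), -1.0, 1.0)
    ang = np.degrees(np.abs(np.arccos(dots)))
    return float(ang[0]) if np.asarray(f_a).ndim == 1 else ang


# --------------------------------------------------------- field transfer


def _locate_tets(mesh, points, snap_tol):
    """(cell index, barycentric (4,)) for each point in a tet mesh."""
    x = mesh.vertices[mesh.cells]
    v0 = x[:, 0]
    d = np.transpose(x[:, 1:] - x[:, :1], (0, 2, 1))  # columns e1,e2,e3
    dinv = np.linalg.inv(d)
    centroids = x.mean(axis=1)
    tree = cKDTree(centroids)
    kmax = min(32, mesh.n_cells)
    _, cand = tree.query(points, k=kmax)
    cand = np.atleast_2d(cand)
    if cand.ndim == 1:
        cand = cand[:, None]
    npts = points.shape[0]
    cell_of = np.full(npts, -1, dtype=np.int64)
    bary = np.zeros((npts, 4))
    best_def = np.full(npts, -np.inf)
    best_cell = np.zeros(npts, dtype=np.int64)
    best_bary = np.zeros((npts, 4))
    todo = np.arange(npts)
    for j in range(cand.shape[1]):
        if todo.size == 0:
            break
        c = cand[todo, j]
        xi = np.einsum("nij,nj->ni", dinv[c], points[todo] - v0[c])
        lam = np.concatenate([(1 - xi.sum(axis=1))[:, None], xi], axis=1)
        mindef = lam.min(axis=1)
        upd = mindef > best_def[todo]
        best_def[todo[upd]] = mindef[upd]
        best_cell[todo[upd]] = c[upd]
        best_bary[todo[upd]] = lam[upd]
        inside = mindef >= -1e-9
        hit = todo[inside]
        cell_of[hit] = c[inside]
        bary[hit] = lam[inside]
        todo = todo[~inside]
    if todo.size:
        # accept slightly-outside points within the snap tolerance
        scale = np.cbrt(np.abs(np.linalg.det(d[best_cell[todo]])))
        ok = best_def[todo] * scale >= -snap_tol
        acc = todo[ok]
        lam = np.clip(best_bary[acc], 0.0, None)
        lam /= lam.sum(axis=1)[:, None]
        cell_of[acc] = best_cell[acc]
        bary[acc] = lam
        if np.any(~ok):
            i = todo[~ok][0]
            raise OutOfDomainError(
                f"point {points[i]} lies outside the source mesh "
                f"(deficit {best_def[i]:.3g})"
            )
    return cell_of, bary


def _locate_hexes(mesh, points, snap_tol):
    """(cell index, trilinear weights (8,)) via Newton inversion."""
    signs = np.array(
        [
            [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
            [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
        ],
        dtype=np.float64,
    )
    x = mesh.vertices[mesh.cells]
    centroids = x.mean(axis=1)
    tree = cKDTree(centroids)
    kmax = min(32, mesh.n_cells)
    _, cand = tree.query(points, k=kmax)
    cand = np.atleast_2d(cand)
    npts = points.shape[0]
    cell_of = np.full(npts, -1, dtype=np.int64)
    weights = np.zeros((npts, 8))
    best_over = np.full(npts, np.inf)
    best_cell = np.zeros(npts, dtype=np.int64)
    best_xi = np.zeros((npts, 3))
    todo = np.arange(npts)
    for j in range(cand.shape[1]):
        if todo.size == 0:
            break
        c = cand[todo, j]
        xc = x[c]
        xi = np.zeros((todo.size, 3))
        for _ in range(20):
            N = np.prod(1 + signs[None, :, :] * xi[:, None, :], axis=2) / 8.0
            r = np.einsum("pn,pnk->pk", N, xc) - points[todo]
            dN = np.empty((todo.size, 8, 3))
            for i in range(3):
                prod = np.ones((todo.size, 8))
                for k in range(3):
                    if k != i:
                        prod *= 1 + signs[None, :, k] * xi[:, None, k]
                dN[:, :, i] = signs[None, :, i] * prod / 8.0
            J = np.einsum("pni,pnk->pik", dN, xc)  # d x_k / d xi_i
            step = np.linalg.solve(np.transpose(J, (0, 2, 1)), r[:, :, None])[:, :, 0]
            xi = xi - step
            if np.abs(r).max() < 1e-14:
                break
        over = np.max(np.abs(xi), axis=1) - 1.0
        upd = over < best_over[todo]
        best_over[todo[upd]] = over[upd]
        best_cell[todo[upd]] = c[upd]
        best_xi[todo[upd]] = xi[upd]
        inside = over <= 1e-9
        hit = todo[inside]
        cell_of[hit] = c[inside]
        weights[hit] = np.prod(1 + signs[None, :, :] * xi[inside][:, None, :], axis=2) / 8.0
        todo = todo[~inside]
    if todo.size:
        scale = np.cbrt(np.abs(np.linalg.det(
            np.einsum("ni,pnk->pik", signs / 2.0, x[best_cell[todo]])
        )))
        ok = best_over[todo] * scale <= snap_tol
        acc = todo[ok]
        xi = np.clip(best_xi[acc], -1.0, 1.0)
        cell_of[acc] = best_cell[acc]
        weights[acc] = np.prod(1 + signs[None, :, :] * xi[:, None, :], axis=2) / 8.0
        if np.any(~ok):
            i = todo[~ok][0]
            raise OutOfDomainError(f"point {points[i]} lies outside the source mesh")
    return cell_of, weights


def transfer_field(
    source_mesh: LabeledMesh,
    field: np.ndarray,
    target_points: np.ndarray,
    snap_tol: float = 1e-6,
    unit: bool = True,
) -> np.ndarray:
    """Interpolate a nodal vector field at arbitrary points.

    Barycentric (tet) or trilinear (hex) interpolation inside the
    containing cell; points outside the mesh but within `snap_tol` (meters)
    are snapped to the nearest cell.  With ``unit=True`` the interpolated
    vectors are renormalized to unit length (the fiber-field convention).
    """
    points = np.atleast_2d(np.asarray(target_points, dtype=np.float64))
    field = np.asarray(field, dtype=np.float64)
    if source_mesh.element_type == TET:
        cell_of, w = _locate_tets(source_mesh, points, snap_tol)
    else:
        cell_of, w = _locate_hexes(source_mesh, points, snap_tol)
    vals = np.einsum("pn,pnk->pk", w, field[source_mesh.cells[cell_of]])
    if unit:
        norms = np.linalg.norm(vals, axis=1)
        if np.any(norms < 1e-14):
            raise OutOfDomainError("interpolated vector vanished; cannot renormalize")
        vals = vals / norms[:, None]
    return vals


# ------------------------------------------------------------------- study


@dataclass
class SensitivityRow:
    level: int
    h_mm: float
    dofs: int
    avg_deg: float | None
    max_deg: float | None


@dataclass
class SensitivityReport:
    rows: list

    def to_table(self) -> str:
        lines = ["i\th [mm]\t#dofs\tavg [deg]\tmax [deg]"]
        for r in self.rows:
            avg = f"{r.avg_deg:.6f}" if r.avg_deg is not None else "-"
            mx = f"{r.max_deg:.6f}" if r.max_deg is not None else "-"
            lines.append(f"{r.level}\t{r.h_mm:.4f}\t{r.dofs}\t{avg}\t{mx}")
        return "\n".join(lines)


def sensitivity_study(meshes, config, snap_tol: float = 1e-9) -> SensitivityReport:
    """Run the refinement-family protocol and report per-level errors.

    `meshes` is ordered coarse to fine (h strictly decreasing); all must
    share the geometry's label set.  The fiber field of every coarser mesh
    is evaluated at the finest mesh's vertices and compared with the
    reference field there.
    """
    if len(meshes) < 2:
        raise ConfigurationError("sensitivity study needs at least two meshes")
    labels = meshes[0].label_set
    for m in meshes[1:]:
        if m.label_set != labels:
            raise ConfigurationError("inconsistent label sets across the refinement family")
    hs = [m.average_edge_length() for m in meshes]
    if any(h2 >= h1 * (1 + 1e-12) for h1, h2 in zip(hs, hs[1:])):
        raise ConfigurationError("meshes must be ordered by strictly decreasing mesh size")
    bundles = [generate_fibers(m, config) for m in meshes]
    fine = meshes[-1]
    f_ref = bundles[-1].vectors["f"]
    rows = []
    for lvl, (m, b) in enumerate(zip(meshes[:-1], bundles[:-1]), start=1):
        f_i = transfer_field(m, b.vectors["f"], fine.vertices, snap_tol=snap_tol)
        err = angular_error(f_i, f_ref)
        rows.append(
            SensitivityRow(lvl, hs[lvl - 1] * 1e3, m.n_vertices, float(err.mean()), float(err.max()))
        )
    rows.append(SensitivityRow(len(meshes), hs[-1] * 1e3, fine.n_vertices, None, None))
    return SensitivityReport(rows)
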
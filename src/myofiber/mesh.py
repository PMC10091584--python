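"""In-memory mesh model: labeled volumetric meshes and nodal fields.

A :class:`LabeledMesh` holds the myocardial domain Omega as a homogeneous
tetrahedral (tet4) or hexahedral (hex8) mesh plus the partition of its
boundary into labeled surface patches (endocardium, epicardium, base, valve
and vein rings ...) used as Dirichlet boundaries by the fiber-generation
rules.  All coordinates are SI meters; connectivity is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MeshError

TET = "Tet"
HEX = "Hex"

# local vertex ordering of hex8 faces (Gmsh/VTK convention, outward for a
# hex with positive Jacobian)
_HEX_FACES = np.array(
    [
        [0, 3, 2, 1],  # bottom  (z-)
        [4, 5, 6, 7],  # top     (z+)
        [0, 1, 5, 4],  # front   (y-)
        [2, 3, 7, 6],  # back    (y+)
        [0, 4, 7, 3],  # left    (x-)
        [1, 2, 6, 5],  # right   (x+)
    ]
)

_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


@dataclass
class LabeledMesh:
    """Volumetric mesh with integer-labeled boundary facets.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in meters.
    cells : (m, 4) or (m, 8) int array
        tet4 or hex8 connectivity, 0-based.
    facets : (k, 3) or (k, 4) int array
        Boundary triangles (tet mesh) or quadrilaterals (hex mesh).
    facet_labels : (k,) int array
        One surface label per boundary facet.
    element_type : {"Tet", "Hex"}
    """

    vertices: np.ndarray
    cells: np.ndarray
    facets: np.ndarray
    facet_labels: np.ndarray
    element_type: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.cells = np.ascontiguousarray(self.cells, dtype=np.int64)
        self.facets = np.ascontiguousarray(self.facets, dtype=np.int64)
        self.facet_labels = np.ascontiguousarray(self.facet_labels, dtype=np.int64)
        if self.element_type not in (TET, HEX):
            raise MeshError(f"unknown element type {self.element_type!r}")
        nv = 4 if self.element_type == TET else 8
        if self.cells.ndim != 2 or self.cells.shape[1] != nv:
            raise MeshError(
                f"{self.element_type} mesh requires cells with {nv} vertices, "
                f"got shape {self.cells.shape}"
            )

    # ------------------------------------------------------------------ sizes
    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    @property
    def label_set(self) -> set[int]:
        return set(int(l) for l in np.unique(self.facet_labels))

    # -------------------------------------------------------------- geometry
    def cell_volumes(self) -> np.ndarray:
        """Signed-then-validated volume of every cell (m^3)."""
        x = self.vertices[self.cells]
        if self.element_type == TET:
            e = x[:, 1:] - x[:, :1]
            vol = np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2])) / 6.0
        else:
            # sum of the 6-tet Kuhn split; exact for tri-linear cells
            vol = np.zeros(self.n_cells)
            for t in _hex_kuhn_tets():
                e = x[:, t[1:]] - x[:, t[:1]]
                vol += np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2])) / 6.0
        return vol

    def validate(self) -> None:
        """Check the structural invariants; raise MeshError on violation."""
        if self.cells.min(initial=0) < 0 or self.cells.max(initial=-1) >= self.n_vertices:
            raise MeshError("cell connectivity index out of range")
        if self.facets.size and (
            self.facets.min() < 0 or self.facets.max() >= self.n_vertices
        ):
            raise MeshError("facet connectivity index out of range")
        vol = self.cell_volumes()
        if np.any(vol <= 0.0):
            bad = int(np.argmin(vol))
            raise MeshError(f"non-positive volume in cell {bad}: {vol[bad]:g}")
        if self.facets.shape[0] != self.facet_labels.shape[0]:
            raise MeshError("facet/label count mismatch")

    def facets_with_labels(self, labels) -> np.ndarray:
        """Connectivity of all boundary facets carrying any of `labels`."""
        labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
        mask = np.isin(self.facet_labels, labels)
        return self.facets[mask]

    def vertices_on_labels(self, labels) -> np.ndarray:
        """Sorted unique vertex indices lying on the given surface labels."""
        return np.unique(self.facets_with_labels(labels))

    def nearest_vertex(self, point) -> int:
        p = np.asarray(point, dtype=np.float64)
        d2 = np.einsum("ij,ij->i", self.vertices - p, self.vertices - p)
        return int(np.argmin(d2))

    def edges(self) -> np.ndarray:
        """Unique undirected cell edges as an (e, 2) index array."""
        if self.element_type == TET:
            pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        else:
            pairs = [
                (0, 1), (1, 2), (2, 3), (3, 0),
                (4, 5), (5, 6), (6, 7), (7, 4),
                (0, 4), (1, 5), (2, 6), (3, 7),
            ]
        e = np.concatenate([self.cells[:, p] for p in pairs])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def average_edge_length(self) -> float:
        e = self.edges()
        d = self.vertices[e[:, 0]] - self.vertices[e[:, 1]]
        return float(np.mean(np.linalg.norm(d, axis=1)))

    def vertex_adjacency(self):
        """Sparse boolean vertex-vertex adjacency (via cell edges)."""
        from scipy import sparse

        e = self.edges()
        n = self.n_vertices
        a = sparse.coo_matrix(
            (np.ones(2 * e.shape[0]), (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(n, n),
        )
        return a.tocsr()

    def scaled(self, factor: float) -> "LabeledMesh":
        return LabeledMesh(
            self.vertices * float(factor),
            self.cells.copy(),
            self.facets.copy(),
            self.facet_labels.copy(),
            self.element_type,
            dict(self.metadata),
        )


def _hex_kuhn_tets() -> np.ndarray:
    """Kuhn 6-tet decomposition of the hex8 reference cell.

    All tets share the main diagonal 0-6; using the same rule in every cell
    of a structured grid yields a globally conforming tetrahedralization.
    """
    return np.array(
        [
            [0, 1, 2, 6],
            [0, 2, 3, 6],
            [0, 3, 7, 6],
            [0, 7, 4, 6],
            [0, 4, 5, 6],
            [0, 5, 1, 6],
        ]
    )


def boundary_facets_of(cells: np.ndarray, element_type: str) -> np.ndarray:
    """Extract boundary facets (faces referenced by exactly one cell)."""
    faces = _TET_FACES if element_type == TET else _HEX_FACES
    f = cells[:, faces].reshape(-1, faces.shape[1])
    key = np.sort(f, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return f[counts[inv] == 1]


@dataclass
class FieldBundle:
    """Named per-vertex scalar and vector fields aligned with a mesh."""

    mesh: LabeledMesh
    scalars: dict = field(default_factory=dict)
    vectors: dict = field(default_factory=dict)
    unit_norm: set = field(default_factory=set)

    def add_scalar(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (self.mesh.n_vertices,):
            raise MeshError(f"scalar field {name!r} misaligned with mesh")
        self.scalars[name] = values

    def add_vector(self, name: str, values: np.ndarray, unit: bool = False) -> None:
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (self.mesh.n_vertices, 3):
            raise MeshError(f"vector field {name!r} misaligned with mesh")
        self.vectors[name] = values
        if unit:
            norms = np.linalg.norm(values, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-8):
                raise MeshError(f"vector field {name!r} flagged unit-norm is not")
            self.unit_norm.add(name)
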
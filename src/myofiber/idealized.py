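"""Programmatic labeled meshes of idealized cardiac geometries.

Four generators cover the geometry types the fiber rules support:

* :func:`make_slab` — a rectangular myocardial slab (hex or tet), with the
  endocardium and epicardium on the two lateral ``x`` walls and the top and
  bottom surfaces acting as base-up / base-down;
* :func:`make_shell` — a spherical shell (tet), optionally with circular
  holes whose rims model the mitral-valve and pulmonary-vein rings of an
  idealized left atrium (or the valve rings of a complete ventricle);
* :func:`make_lv` — a truncated-ellipsoid idealized left ventricle (tet)
  with endocardial/epicardial walls and a flat basal plane.

All generators are deterministic (no randomness, no external mesher) and
emit meshes that satisfy the :class:`~myofiber.mesh.LabeledMesh`
invariants: positive cell volumes, conforming facets, and boundary labels
that partition the whole boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .mesh import HEX, TET, LabeledMesh, _hex_kuhn_tets, boundary_facets_of

# default surface labels, shared with the parameter-file defaults
EPI = 10
ENDO = 20
BASE = 30
BASE_UP = 40
BASE_DOWN = 50
SIDE = 60
MV = 70
AV = 75
LPV = 80
RPV = 90


# ---------------------------------------------------------------------- slab


@dataclass
class SlabSpec:
    """Rectangular slab: extents in meters, subdivisions per axis."""

    Lx: float = 0.024
    Ly: float = 0.024
    Lz: float = 0.048
    nx: int = 4
    ny: int = 4
    nz: int = 8
    element_type: str = HEX

    def __post_init__(self):
        if min(self.Lx, self.Ly, self.Lz) <= 0:
            raise ConfigurationError("slab extents must be positive")
        if min(self.nx, self.ny, self.nz) < 1:
            raise ConfigurationError("slab subdivisions must be >= 1")
        if self.element_type not in (TET, HEX):
            raise ConfigurationError(f"unknown element type {self.element_type!r}")


def make_slab(spec: SlabSpec) -> LabeledMesh:
    """Structured slab mesh with Fig.-4a-style labels.

    ``x = 0`` -> endocardium, ``x = Lx`` -> epicardium, ``z = Lz`` -> base up,
    ``z = 0`` -> base down, the two ``y`` walls -> side (homogeneous Neumann).
    The tet variant splits every hex into 6 tets sharing the cell's main
    diagonal (Kuhn rule); identical local rules on the structured lattice
    make the split globally conforming.
    """
    nx, ny, nz = spec.nx, spec.ny, spec.nz
    xs = np.linspace(0.0, spec.Lx, nx + 1)
    ys = np.linspace(0.0, spec.Ly, ny + 1)
    zs = np.linspace(0.0, spec.Lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    # index (i, j, k) -> i*(ny+1)*(nz+1) + j*(nz+1) + k
    verts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    hexes = np.stack(
        [
            vid(I, J, K), vid(I + 1, J, K), vid(I + 1, J + 1, K), vid(I, J + 1, K),
            vid(I, J, K + 1), vid(I + 1, J, K + 1), vid(I + 1, J + 1, K + 1), vid(I, J + 1, K + 1),
        ],
        axis=1,
    )
    if spec.element_type == HEX:
        cells = hexes
    else:
        kuhn = _hex_kuhn_tets()
        cells = hexes[:, kuhn].reshape(-1, 4)
    facets = boundary_facets_of(cells, spec.element_type)
    labels = _classify_box_facets(verts, facets, spec)
    mesh = LabeledMesh(verts, cells, facets, labels, spec.element_type)
    mesh.metadata["spec"] = spec
    return mesh


def _classify_box_facets(verts, facets, spec):
    c = verts[facets].mean(axis=1)
    tol = 1e-12 * max(spec.Lx, spec.Ly, spec.Lz)
    labels = np.full(facets.shape[0], SIDE, dtype=np.int64)
    labels[np.abs(c[:, 0]) < tol] = ENDO
    labels[np.abs(c[:, 0] - spec.Lx) < tol] = EPI
    labels[np.abs(c[:, 2] - spec.Lz) < tol] = BASE_UP
    labels[np.abs(c[:, 2]) < tol] = BASE_DOWN
    return labels


# -------------------------------------------------- extruded triangulations


def _icosphere(level: int):
    """Triangulated unit sphere with vertices at the +-z poles.

    Starts from the icosahedron oriented pole-to-pole and applies `level`
    4-way subdivisions with midpoint projection.
    """
    t = np.arctan(0.5)  # latitude of the two pentagon rings
    verts = [(0.0, 0.0, 1.0)]
    for k in range(5):  # upper ring
        a = 2 * np.pi * k / 5
        verts.append((np.cos(t) * np.cos(a), np.cos(t) * np.sin(a), np.sin(t)))
    for k in range(5):  # lower ring, offset by 36 degrees
        a = 2 * np.pi * (k + 0.5) / 5
        verts.append((np.cos(t) * np.cos(a), np.cos(t) * np.sin(a), -np.sin(t)))
    verts.append((0.0, 0.0, -1.0))
    v = np.array(verts)
    faces = []
    for k in range(5):
        k1 = (k + 1) % 5
        faces.append((0, 1 + k, 1 + k1))                 # north cap
        faces.append((1 + k, 6 + k, 1 + k1))             # upper band
        faces.append((1 + k1, 6 + k, 6 + k1))            # upper band
        faces.append((6 + k, 11, 6 + k1))                # south cap
    f = np.array(faces, dtype=np.int64)
    for _ in range(level):
        v, f = _subdivide(v, f)
    return v, f


def _subdivide(v, f):
    cache: dict[tuple[int, int], int] = {}
    vlist = list(map(tuple, v))

    def mid(a, b):
        key = (min(a, b), max(a, b))
        if key not in cache:
            m = (np.asarray(vlist[a]) + np.asarray(vlist[b])) / 2.0
            m /= np.linalg.norm(m)
            cache[key] = len(vlist)
            vlist.append(tuple(m))
        return cache[key]

    out = []
    for a, b, c in f:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        out.extend([(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)])
    return np.array(vlist), np.array(out, dtype=np.int64)


def _split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split prisms (p, 6) into 3 tets each with globally consistent diagonals.

    Bottom triple (0,1,2) and top triple (3,4,5) must be oriented so the
    bottom normal points toward the top.  Each quad face's diagonal is
    determined by global vertex ids alone, so adjacent prisms agree.
    """
    out = np.empty((prisms.shape[0], 3, 4), dtype=np.int64)
    rot_cyc = [(0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3), (2, 0, 1, 5, 3, 4)]
    flip = (4, 3, 5, 1, 0, 2)  # 180-deg rotation through edge (0,1)/(3,4) midpoints
    for r, p in enumerate(prisms):
        best = None
        for base in (tuple(p), tuple(p[list(flip)])):
            for cyc in rot_cyc:
                cand = tuple(base[i] for i in cyc)
                if best is None or cand[0] < best[0]:
                    best = cand
        q = best
        if min(q[1], q[5]) < min(q[2], q[4]):
            tets = [(q[0], q[1], q[2], q[5]), (q[0], q[1], q[5], q[4]), (q[0], q[4], q[5], q[3])]
        else:
            tets = [(q[0], q[1], q[2], q[4]), (q[0], q[4], q[2], q[5]), (q[0], q[4], q[5], q[3])]
        out[r] = tets
    return out.reshape(-1, 4)


def _extrude_surface(layer_coords: np.ndarray, faces: np.ndarray):
    """Stack per-layer copies of a triangulated surface into a tet mesh.

    layer_coords: (n_layers+1, n_surf, 3) vertex coordinates per layer.
    faces: (f, 3) surface triangles oriented outward (toward the last layer).

    Returns (vertices, tets, layer_of_vertex).
    """
    n_lay = layer_coords.shape[0] - 1
    n_surf = layer_coords.shape[1]
    verts = layer_coords.reshape(-1, 3)
    layer_of = np.repeat(np.arange(n_lay + 1), n_surf)
    prisms = []
    for l in range(n_lay):
        lo = l * n_surf
        hi = (l + 1) * n_surf
        prisms.append(np.hstack([faces + lo, faces + hi]))
    tets = _split_prisms(np.vstack(prisms))
    return verts, tets, layer_of


def _fix_orientation(verts, tets):
    e = verts[tets[:, 1:]] - verts[tets[:, :1]]
    vol = np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2]))
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    return tets


# --------------------------------------------------------------------- shell


@dataclass
class HoleSpec:
    """Circular hole in a spherical shell: labeled ring for a valve/vein."""

    label: int
    direction: tuple = (0.0, 0.0, -1.0)
    angular_radius_deg: float = 30.0


@dataclass
class ShellSpec:
    """Spherical shell r_endo <= |x| <= r_epi, target edge length h (meters)."""

    r_endo: float = 0.02
    r_epi: float = 0.03
    h: float = 0.008
    holes: list = field(default_factory=list)

    def __post_init__(self):
        if not (0 < self.r_endo < self.r_epi):
            raise ConfigurationError("shell requires 0 < r_endo < r_epi")
        if self.h <= 0:
            raise ConfigurationError("target edge length must be positive")
        dirs = []
        for hole in self.holes:
            d = np.asarray(hole.direction, dtype=np.float64)
            n = np.linalg.norm(d)
            if n == 0:
                raise ConfigurationError("hole direction must be nonzero")
            dirs.append((d / n, np.radians(hole.angular_radius_deg)))
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                sep = np.arccos(np.clip(dirs[i][0] @ dirs[j][0], -1, 1))
                if sep < dirs[i][1] + dirs[j][1]:
                    raise ConfigurationError(
                        f"holes {self.holes[i].label} and {self.holes[j].label} overlap"
                    )


def make_shell(spec: ShellSpec) -> LabeledMesh:
    """Tet mesh of a spherical shell, optionally with labeled ring holes."""
    r_mid = 0.5 * (spec.r_endo + spec.r_epi)
    ico_edge = 1.0515 * r_mid  # icosahedron chord length at radius r_mid
    level = max(0, int(np.ceil(np.log2(ico_edge / spec.h))))
    n_r = max(1, int(round((spec.r_epi - spec.r_endo) / spec.h)))
    dirs, faces = _icosphere(level)
    # carve holes: drop surface triangles whose centroid is inside a cone
    keep = np.ones(faces.shape[0], dtype=bool)
    for hole in spec.holes:
        d = np.asarray(hole.direction, dtype=np.float64)
        d /= np.linalg.norm(d)
        cen = dirs[faces].mean(axis=1)
        cen /= np.linalg.norm(cen, axis=1)[:, None]
        keep &= cen @ d < np.cos(np.radians(hole.angular_radius_deg))
    faces = faces[keep]
    used = np.unique(faces)
    remap = -np.ones(dirs.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    faces = remap[faces]
    dirs = dirs[used]
    radii = np.linspace(spec.r_endo, spec.r_epi, n_r + 1)
    layers = dirs[None, :, :] * radii[:, None, None]
    verts, tets, layer_of = _extrude_surface(layers, faces)
    tets = _fix_orientation(verts, tets)
    facets = boundary_facets_of(tets, TET)
    labels = _classify_shell_facets(facets, layer_of, n_r, verts, spec)
    mesh = LabeledMesh(verts, tets, facets, labels, TET)
    mesh.metadata["spec"] = spec
    mesh.metadata["north_pole"] = np.array([0.0, 0.0, spec.r_epi])
    mesh.metadata["south_pole"] = np.array([0.0, 0.0, -spec.r_epi])
    return mesh


def _classify_shell_facets(facets, layer_of, n_r, verts, spec):
    labels = np.empty(facets.shape[0], dtype=np.int64)
    fl = layer_of[facets]
    inner = (fl == 0).all(axis=1)
    outer = (fl == n_r).all(axis=1)
    labels[inner] = ENDO
    labels[outer] = EPI
    rim = ~(inner | outer)
    if rim.any():
        if not spec.holes:
            raise ConfigurationError("unclassifiable boundary facet in hole-free shell")
        cen = verts[facets[rim]].mean(axis=1)
        cen /= np.linalg.norm(cen, axis=1)[:, None]
        hole_dirs = np.array(
            [np.asarray(h.direction) / np.linalg.norm(h.direction) for h in spec.holes]
        )
        hole_labels = np.array([h.label for h in spec.holes], dtype=np.int64)
        labels[rim] = hole_labels[np.argmax(cen @ hole_dirs.T, axis=1)]
    return labels


# ----------------------------------------------------------------------- LV


@dataclass
class EllipsoidLVSpec:
    """Truncated-ellipsoid idealized left ventricle.

    semi_endo / semi_epi: endocardial and epicardial semi-axes (a, b, c) in
    meters; the long axis is z with the apex at z = -c.  z_base is the
    height of the artificial basal (truncation) plane.
    """

    semi_endo: tuple = (0.020, 0.020, 0.050)
    semi_epi: tuple = (0.030, 0.030, 0.060)
    z_base: float = 0.020
    n_theta: int = 8
    n_phi: int = 12
    n_r: int = 2

    def __post_init__(self):
        endo = np.asarray(self.semi_endo, dtype=np.float64)
        epi = np.asarray(self.semi_epi, dtype=np.float64)
        if np.any(endo <= 0) or np.any(epi <= endo):
            raise ConfigurationError(
                "epicardial semi-axes must strictly exceed the (positive) endocardial ones"
            )
        if not (-endo[2] < self.z_base < endo[2]):
            raise ConfigurationError(
                "basal plane must cut both walls: -c_endo < z_base < c_endo"
            )
        if min(self.n_theta, self.n_phi, self.n_r) < 1 or self.n_phi < 3:
            raise ConfigurationError("invalid LV subdivision counts")


def make_lv(spec: EllipsoidLVSpec) -> LabeledMesh:
    """Tet mesh of a truncated ellipsoidal left ventricle.

    Labels: endocardium (inner wall), epicardium (outer wall), base
    (truncation plane, exactly planar).  The epicardial apex coordinate is
    reported in ``mesh.metadata["apex"]``.
    """
    endo = np.asarray(spec.semi_endo, dtype=np.float64)
    epi = np.asarray(spec.semi_epi, dtype=np.float64)
    n_t, n_p, n_r = spec.n_theta, spec.n_phi, spec.n_r
    # surface topology shared by all layers: apex vertex + n_t rings of n_p
    n_surf = 1 + n_t * n_p

    def ring(i, j):
        return 1 + (i - 1) * n_p + (j % n_p)

    faces = []
    for j in range(n_p):  # apex fan (outward orientation: seen from outside)
        faces.append((0, ring(1, j + 1), ring(1, j)))
    for i in range(1, n_t):
        for j in range(n_p):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j), ring(i + 1, j + 1)
            # quad (a,b,d,c) split along the (a,d) diagonal, same for all layers
            faces.append((a, b, d))
            faces.append((a, d, c))
    faces = np.array(faces, dtype=np.int64)
    # orientation: apex fan as built points inward; fix by checking one normal
    layers = np.empty((n_r + 1, n_surf, 3))
    for l in range(n_r + 1):
        s = endo + (epi - endo) * (l / n_r)
        theta_b = np.arccos(np.clip(spec.z_base / s[2], -1.0, 1.0))
        thetas = np.linspace(np.pi, theta_b, n_t + 1)[1:]  # rings (apex excluded)
        layers[l, 0] = (0.0, 0.0, -s[2])
        for i, th in enumerate(thetas, start=1):
            for j in range(n_p):
                ph = 2 * np.pi * j / n_p
                layers[l, ring(i, j)] = (
                    s[0] * np.sin(th) * np.cos(ph),
                    s[1] * np.sin(th) * np.sin(ph),
                    s[2] * np.cos(th),
                )
        # force the basal ring onto the plane exactly
        for j in range(n_p):
            layers[l, ring(n_t, j), 2] = spec.z_base
    verts, tets, layer_of = _extrude_surface(layers, faces)
    tets = _fix_orientation(verts, tets)
    facets = boundary_facets_of(tets, TET)
    labels = np.empty(facets.shape[0], dtype=np.int64)
    fl = layer_of[facets]
    inner = (fl == 0).all(axis=1)
    outer = (fl == n_r).all(axis=1)
    labels[inner] = ENDO
    labels[outer] = EPI
    rim = ~(inner | outer)
    zc = verts[facets].mean(axis=1)[:, 2]
    if np.any(rim & (np.abs(zc - spec.z_base) > 1e-10)):
        raise ConfigurationError("LV boundary facet neither wall nor basal plane")
    labels[rim] = BASE
    mesh = LabeledMesh(verts, tets, facets, labels, TET)
    mesh.metadata["spec"] = spec
    mesh.metadata["apex"] = np.array([0.0, 0.0, -epi[2]])
    return mesh


def make_la_shell(
    r_endo: float = 0.02,
    r_epi: float = 0.025,
    h: float = 0.006,
) -> LabeledMesh:
    """Hollow-sphere idealized left atrium: shell with MV and two PV rings."""
    holes = [
        HoleSpec(MV, (0.0, 0.0, -1.0), 35.0),
        HoleSpec(LPV, (np.sin(np.radians(50)), 0.0, np.cos(np.radians(50))), 18.0),
        HoleSpec(RPV, (-np.sin(np.radians(50)), 0.0, np.cos(np.radians(50))), 18.0),
    ]
    return make_shell(ShellSpec(r_endo, r_epi, h, holes))


def make_lv_complete_shell(
    r_endo: float = 0.02,
    r_epi: float = 0.03,
    h: float = 0.007,
) -> LabeledMesh:
    """Shell with mitral and aortic rings: a topological stand-in for a
    complete (unbased) left ventricle, used to exercise the outflow-tract
    rules without a patient geometry."""
    holes = [
        HoleSpec(MV, (np.sin(np.radians(25)), 0.0, np.cos(np.radians(25))), 16.0),
        HoleSpec(AV, (-np.sin(np.radians(25)), 0.0, np.cos(np.radians(25))), 16.0),
    ]
    return make_shell(ShellSpec(r_endo, r_epi, h, holes))
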
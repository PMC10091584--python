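"""Laplace-Dirichlet rule-based generation of myocardial fiber fields.

The pipeline, common to every geometry type:

1.  solve the transmural Laplace problem (epicardium = 1, endocardium = 0)
    and normalize its gradient into the unit transmural direction ``e_t``;
2.  build an apico-basal *normal* direction ``k`` by one of four rules —
    a constant basal normal (RL), the gradient of an apex-to-base potential
    (BT), a weighted blend of apico-basal and apico-outflow-tract
    gradients (Doste), or a per-bundle selection among several potentials
    (atrial);
3.  orthonormalize ``(e_l, e_n, e_t)`` with ``e_n`` the projection of ``k``
    off ``e_t`` and ``e_l = e_n x e_t``;
4.  rotate the frame by the transmurally interpolated helical angle alpha
    (about ``e_t``) and sheetlet angle beta (about the rotated longitudinal
    axis), producing the fiber ``f``, sheet-normal ``n`` and sheet ``s``
    directions.

Rotations follow the right-hand rule ("counter-clockwise" about the stated
axis) and are applied with the Rodrigues formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateFrameError
from .fem import DEFAULT_MAXITER, DEFAULT_TOL, DirichletSpec, gradient, solve_laplace
from .mesh import FieldBundle, LabeledMesh

GEOMETRY_SLAB = "Slab"
GEOMETRY_LV = "Left ventricle"
GEOMETRY_LV_COMPLETE = "Left ventricle complete"
GEOMETRY_LA = "Left atrium"


@dataclass
class AngleLaw:
    """Linear transmural interpolation of the helical/sheetlet angles.

    Angles are degrees; ``alpha(phi) = alpha_endo (1 - phi) + alpha_epi phi``
    and likewise for beta.  Optional outflow-tract (OT) variants are blended
    by the Doste interpolation function ``w`` in the complete-LV rule.
    """

    alpha_endo: float = -60.0
    alpha_epi: float = 60.0
    beta_endo: float = 0.0
    beta_epi: float = 0.0
    alpha_endo_ot: float | None = None
    alpha_epi_ot: float | None = None
    beta_endo_ot: float | None = None
    beta_epi_ot: float | None = None

    def angles(self, phi: np.ndarray, w: np.ndarray | None = None):
        """Per-vertex (alpha, beta) in radians.

        With ``w`` given (complete LV), effective endo/epi angles are
        ``w * standard + (1 - w) * OT`` before the transmural interpolation.
        """
        phi = np.asarray(phi, dtype=np.float64)
        a_en, a_ep = self.alpha_endo, self.alpha_epi
        b_en, b_ep = self.beta_endo, self.beta_epi
        if w is not None:
            w = np.asarray(w, dtype=np.float64)
            a_en = w * a_en + (1 - w) * (self.alpha_endo_ot if self.alpha_endo_ot is not None else a_en)
            a_ep = w * a_ep + (1 - w) * (self.alpha_epi_ot if self.alpha_epi_ot is not None else a_ep)
            b_en = w * b_en + (1 - w) * (self.beta_endo_ot if self.beta_endo_ot is not None else b_en)
            b_ep = w * b_ep + (1 - w) * (self.beta_epi_ot if self.beta_epi_ot is not None else b_ep)
        alpha = np.radians(a_en * (1 - phi) + a_ep * phi)
        beta = np.radians(b_en * (1 - phi) + b_ep * phi)
        return alpha, beta


@dataclass
class FrameField:
    """Per-vertex orthonormal triads before and after the angle rotation."""

    e_l: np.ndarray
    e_n: np.ndarray
    e_t: np.ndarray
    f: np.ndarray | None = None
    n: np.ndarray | None = None
    s: np.ndarray | None = None
    degenerate: np.ndarray | None = None  # mask of vertices fixed by averaging


@dataclass
class NormalDirectionResult:
    """Normal direction ``k`` plus the auxiliary potentials that built it."""

    k: np.ndarray
    potentials: dict = field(default_factory=dict)
    bundle_id: np.ndarray | None = None


def _normalize(v: np.ndarray, what: str, tol: float = 1e-14) -> np.ndarray:
    norms = np.linalg.norm(v, axis=1)
    bad = norms < tol
    if bad.any():
        raise DegenerateFrameError(
            f"degenerate {what} (norm < {tol:g}) at vertex {int(np.argmax(bad))}"
        )
    return v / norms[:, None]


# ------------------------------------------------------------------- step 2


def transmural_direction(
    mesh: LabeledMesh,
    endo_tags,
    epi_tags,
    tol: float = DEFAULT_TOL,
    maxiter: int = DEFAULT_MAXITER,
):
    """Transmural potential phi (endo = 0, epi = 1) and unit direction e_t."""
    bc = DirichletSpec(
        {**{int(t): 0.0 for t in np.atleast_1d(endo_tags)},
         **{int(t): 1.0 for t in np.atleast_1d(epi_tags)}}
    )
    phi = solve_laplace(mesh, bc, tol=tol, maxiter=maxiter)
    e_t = _normalize(gradient(mesh, phi), "transmural gradient")
    return phi, e_t


# ------------------------------------------------------------------- step 3


def normal_rl(mesh: LabeledMesh, n_base) -> NormalDirectionResult:
    """Constant normal direction: the outward normal to the basal plane."""
    n_base = np.asarray(n_base, dtype=np.float64)
    if np.linalg.norm(n_base) == 0:
        raise ConfigurationError("Normal to base must be a nonzero vector")
    k = np.broadcast_to(n_base, (mesh.n_vertices, 3)).copy()
    return NormalDirectionResult(k)


def normal_bt(
    mesh: LabeledMesh,
    base_tags=None,
    apex_point=None,
    apex_tags=None,
    base_point=None,
    tol: float = DEFAULT_TOL,
    maxiter: int = DEFAULT_MAXITER,
) -> NormalDirectionResult:
    """Apex-to-base potential psi (base = 1, apex = 0); ``k`` is its gradient.

    The base and apex may each be surface labels or a point snapped to the
    nearest vertex (slab: two surfaces; sphere: the two pole points;
    ventricle: basal surface + apex point).
    """
    surface = {}
    points = []
    if base_tags is not None:
        surface.update({int(t): 1.0 for t in np.atleast_1d(base_tags)})
    if base_point is not None:
        points.append((base_point, 1.0))
    if apex_tags is not None:
        surface.update({int(t): 0.0 for t in np.atleast_1d(apex_tags)})
    if apex_point is not None:
        j = mesh.nearest_vertex(apex_point)
        if base_tags is not None and j in set(mesh.vertices_on_labels(list(np.atleast_1d(base_tags))).tolist()):
            raise ConfigurationError("apex point snaps to a vertex on the basal surface")
        points.append((apex_point, 0.0))
    psi = solve_laplace(mesh, DirichletSpec(surface, points), tol=tol, maxiter=maxiter)
    k = gradient(mesh, psi)
    return NormalDirectionResult(k, {"psi": psi})


def normal_doste(
    mesh: LabeledMesh,
    mv_tags,
    av_tags,
    apex_point,
    tol: float = DEFAULT_TOL,
    maxiter: int = DEFAULT_MAXITER,
) -> NormalDirectionResult:
    """Blend of apico-basal and apico-outflow-tract directions.

    ``psi_ab`` uses the mitral ring as base, ``psi_ot`` the aortic ring; the
    interpolation function ``w`` is harmonic with w = 1 on the mitral ring
    and apex and w = 0 on the aortic ring; ``k = w grad(psi_ab) +
    (1 - w) grad(psi_ot)``.
    """
    mv = [int(t) for t in np.atleast_1d(mv_tags)]
    av = [int(t) for t in np.atleast_1d(av_tags)]
    if set(mv) & set(av):
        raise ConfigurationError("mitral and aortic ring labels overlap")
    psi_ab = solve_laplace(
        mesh, DirichletSpec({t: 1.0 for t in mv}, [(apex_point, 0.0)]), tol=tol, maxiter=maxiter
    )
    psi_ot = solve_laplace(
        mesh, DirichletSpec({t: 1.0 for t in av}, [(apex_point, 0.0)]), tol=tol, maxiter=maxiter
    )
    w = solve_laplace(
        mesh,
        DirichletSpec({**{t: 1.0 for t in mv}, **{t: 0.0 for t in av}}, [(apex_point, 1.0)]),
        tol=tol,
        maxiter=maxiter,
    )
    k = w[:, None] * gradient(mesh, psi_ab) + (1 - w)[:, None] * gradient(mesh, psi_ot)
    return NormalDirectionResult(k, {"psi_ab": psi_ab, "psi_ot": psi_ot, "w": w})


# bundle ids for the atrial rule
BUNDLE_DEFAULT = 0
BUNDLE_MV = 1
BUNDLE_LPV = 2
BUNDLE_RPV = 3


def normal_atrial(
    mesh: LabeledMesh,
    mv_tags,
    lpv_tags,
    rpv_tags,
    taus,
    apex_point=None,
    tol: float = DEFAULT_TOL,
    maxiter: int = DEFAULT_MAXITER,
) -> NormalDirectionResult:
    """Per-bundle normal direction for the left atrium.

    Three harmonic potentials are solved: ``psi_ab`` (mitral ring = 1,
    against the appendage apex when given, else the pulmonary rings),
    ``psi_v`` (left PV ring = 1, right PV ring = 0) and ``psi_r`` (mitral
    ring = 1, both PV rings = 0).  Each vertex is assigned exactly one
    bundle by threshold tests, in fixed order:

    * mitral bundle if ``psi_r >= 1 - tau_mv``        (k = grad psi_r),
    * else left-PV bundle if ``psi_v >= 1 - tau_lpv`` (k = grad psi_v),
    * else right-PV bundle if ``psi_v <= tau_rpv``    (k = grad psi_v),
    * else the default apico-basal bundle             (k = grad psi_ab).
    """
    tau_mv, tau_lpv, tau_rpv = (float(t) for t in taus)
    for name, t in (("MV", tau_mv), ("LPV", tau_lpv), ("RPV", tau_rpv)):
        if not 0.0 <= t <= 1.0:
            raise ConfigurationError(f"Tau bundle {name} = {t} outside [0, 1]")
    mv = [int(t) for t in np.atleast_1d(mv_tags)]
    lpv = [int(t) for t in np.atleast_1d(lpv_tags)]
    rpv = [int(t) for t in np.atleast_1d(rpv_tags)]
    if apex_point is not None:
        ab_spec = DirichletSpec({t: 1.0 for t in mv}, [(apex_point, 0.0)])
    else:
        ab_spec = DirichletSpec({**{t: 1.0 for t in mv}, **{t: 0.0 for t in lpv + rpv}})
    psi_ab = solve_laplace(mesh, ab_spec, tol=tol, maxiter=maxiter)
    psi_v = solve_laplace(
        mesh, DirichletSpec({**{t: 1.0 for t in lpv}, **{t: 0.0 for t in rpv}}),
        tol=tol, maxiter=maxiter,
    )
    psi_r = solve_laplace(
        mesh, DirichletSpec({**{t: 1.0 for t in mv}, **{t: 0.0 for t in lpv + rpv}}),
        tol=tol, maxiter=maxiter,
    )
    g_ab = gradient(mesh, psi_ab)
    g_v = gradient(mesh, psi_v)
    g_r = gradient(mesh, psi_r)
    bundle = np.full(mesh.n_vertices, BUNDLE_DEFAULT, dtype=np.int64)
    unassigned = np.ones(mesh.n_vertices, dtype=bool)
    m = unassigned & (psi_r >= 1.0 - tau_mv)
    bundle[m] = BUNDLE_MV
    unassigned &= ~m
    m = unassigned & (psi_v >= 1.0 - tau_lpv)
    bundle[m] = BUNDLE_LPV
    unassigned &= ~m
    m = unassigned & (psi_v <= tau_rpv)
    bundle[m] = BUNDLE_RPV
    k = g_ab.copy()
    k[bundle == BUNDLE_MV] = g_r[bundle == BUNDLE_MV]
    k[(bundle == BUNDLE_LPV) | (bundle == BUNDLE_RPV)] = g_v[
        (bundle == BUNDLE_LPV) | (bundle == BUNDLE_RPV)
    ]
    return NormalDirectionResult(
        k, {"psi_ab": psi_ab, "psi_v": psi_v, "psi_r": psi_r}, bundle
    )


# ------------------------------------------------------------------- step 4


def build_frame(
    e_t: np.ndarray,
    k: np.ndarray,
    mesh: LabeledMesh | None = None,
    degeneracy_tol: float = 1e-10,
) -> FrameField:
    """Orthonormal right-handed triad (e_l, e_n, e_t) from e_t and k.

    ``e_n`` is ``k`` with its component along ``e_t`` removed, normalized;
    ``e_l = e_n x e_t``.  At vertices where ``k`` is (numerically) parallel
    to ``e_t`` the local ``k`` is replaced by the average of ``k`` over
    adjacent non-degenerate vertices (requires `mesh`); vertices repaired
    this way are flagged in the returned mask.
    """
    e_t = np.asarray(e_t, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64).copy()
    proj = k - np.einsum("ij,ij->i", k, e_t)[:, None] * e_t
    knorm = np.linalg.norm(k, axis=1)
    pnorm = np.linalg.norm(proj, axis=1)
    degenerate = pnorm < degeneracy_tol * np.maximum(knorm, 1e-300)
    if degenerate.all():
        raise DegenerateFrameError("k is parallel to e_t at every vertex")
    if degenerate.any():
        if mesh is None:
            raise DegenerateFrameError(
                f"k parallel to e_t at vertex {int(np.argmax(degenerate))} "
                "and no mesh given for neighbor averaging"
            )
        adj = mesh.vertex_adjacency()
        good = (~degenerate).astype(np.float64)
        k_avg = adj @ (k * good[:, None])
        w_avg = adj @ good
        still = degenerate & (w_avg == 0)
        if still.any():
            raise DegenerateFrameError(
                f"vertex {int(np.argmax(still))}: k parallel to e_t and no "
                "non-degenerate neighbor to average from"
            )
        k[degenerate] = k_avg[degenerate] / w_avg[degenerate, None]
        proj = k - np.einsum("ij,ij->i", k, e_t)[:, None] * e_t
        pnorm = np.linalg.norm(proj, axis=1)
        bad = degenerate & (pnorm < degeneracy_tol * np.maximum(np.linalg.norm(k, axis=1), 1e-300))
        if bad.any():
            raise DegenerateFrameError(
                f"vertex {int(np.argmax(bad))}: neighbor-averaged k still parallel to e_t"
            )
    e_n = proj / pnorm[:, None]
    e_l = np.cross(e_n, e_t)
    return FrameField(e_l=e_l, e_n=e_n, e_t=e_t, degenerate=degenerate)


# ------------------------------------------------------------------- step 5


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rotate vectors v about per-vertex unit axes by per-vertex angles."""
    c = np.cos(angle)[:, None]
    s = np.sin(angle)[:, None]
    dot = np.einsum("ij,ij->i", axis, v)[:, None]
    return v * c + np.cross(axis, v) * s + axis * dot * (1 - c)


def rotate_frame(
    frame: FrameField,
    phi: np.ndarray,
    law: AngleLaw,
    w: np.ndarray | None = None,
) -> FrameField:
    """Apply the alpha/beta rotations, filling f, n, s on the frame.

    The whole triad is first rotated about ``e_t`` by the helical angle
    alpha (yielding the fiber direction ``f``), then about the rotated
    longitudinal axis ``f`` by the sheetlet angle beta (tilting the
    transmural axis into the sheet direction ``s``).  Both are proper
    rotations, so (f, n, s) stays orthonormal and right-handed.
    """
    alpha, beta = law.angles(phi, w)
    f = _rodrigues(frame.e_l, frame.e_t, alpha)
    n1 = _rodrigues(frame.e_n, frame.e_t, alpha)
    n = _rodrigues(n1, f, beta)
    s = _rodrigues(frame.e_t, f, beta)
    return FrameField(
        e_l=frame.e_l, e_n=frame.e_n, e_t=frame.e_t,
        f=f, n=n, s=s, degenerate=frame.degenerate,
    )


# --------------------------------------------------------------- dispatcher


def generate_fibers(mesh: LabeledMesh, config) -> FieldBundle:
    """Run the full rule for the configured geometry type.

    `config` is an :class:`~myofiber.config.LDRBMConfig`.  Returns a
    :class:`~myofiber.mesh.FieldBundle` with the transmural potential, the
    auxiliary potentials of the chosen normal rule and the unit fields
    ``f``, ``s``, ``n``.
    """
    geo = config.geometry_type
    if config.element_type != mesh.element_type:
        raise ConfigurationError(
            f"Element type = {config.element_type} but the mesh is {mesh.element_type}"
        )
    if config.fe_degree != 1:
        raise ConfigurationError(
            f"FE space degree {config.fe_degree} not supported: only degree 1 is implemented"
        )
    tol, maxiter = config.solver_tolerance, config.solver_max_iterations
    law = AngleLaw(
        alpha_endo=config.geo("alpha endo"), alpha_epi=config.geo("alpha epi"),
        beta_endo=config.geo("beta endo"), beta_epi=config.geo("beta epi"),
    ) if geo != GEOMETRY_LA else AngleLaw(0.0, 0.0, 0.0, 0.0)

    phi, e_t = transmural_direction(
        mesh, config.geo("Tags endo"), config.geo("Tags epi"), tol=tol, maxiter=maxiter
    )
    w = None
    if geo == GEOMETRY_SLAB:
        if config.geo("Sphere slab"):
            nd = normal_bt(
                mesh,
                base_point=config.geo("North pole"),
                apex_point=config.geo("South pole"),
                tol=tol, maxiter=maxiter,
            )
        else:
            nd = normal_bt(
                mesh,
                base_tags=config.geo("Tags base up"),
                apex_tags=config.geo("Tags base down"),
                tol=tol, maxiter=maxiter,
            )
    elif geo == GEOMETRY_LV:
        algo = config.geo("Algorithm type")
        if algo == "RL":
            nd = normal_rl(mesh, config.geo("Normal to base"))
        elif algo == "BT":
            nd = normal_bt(
                mesh, base_tags=config.geo("Tags base"),
                apex_point=config.geo("Apex"), tol=tol, maxiter=maxiter,
            )
        else:  # pragma: no cover - pattern validation rejects earlier
            raise ConfigurationError(f"unknown Algorithm type {algo!r}")
    elif geo == GEOMETRY_LV_COMPLETE:
        nd = normal_doste(
            mesh, config.geo("Tags MV"), config.geo("Tags AV"),
            config.geo("Apex"), tol=tol, maxiter=maxiter,
        )
        w = nd.potentials["w"]
        law.alpha_endo_ot = config.geo("alpha endo OT")
        law.alpha_epi_ot = config.geo("alpha epi OT")
        law.beta_endo_ot = config.geo("beta endo OT")
        law.beta_epi_ot = config.geo("beta epi OT")
    elif geo == GEOMETRY_LA:
        nd = normal_atrial(
            mesh, config.geo("Tags MV"), config.geo("Tags LPV"), config.geo("Tags RPV"),
            (config.geo("Tau bundle MV"), config.geo("Tau bundle LPV"), config.geo("Tau bundle RPV")),
            apex_point=config.geo("Apex") if config.geo("Appendage") else None,
            tol=tol, maxiter=maxiter,
        )
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown Geometry type {geo!r}")

    frame = build_frame(e_t, nd.k, mesh)
    if geo == GEOMETRY_LA:
        # no transmural rotation: [e_l, e_n, e_t] = [f, n, s]
        frame.f, frame.n, frame.s = frame.e_l.copy(), frame.e_n.copy(), frame.e_t.copy()
    else:
        frame = rotate_frame(frame, phi, law, w)
    f, s, n = frame.f, frame.s, frame.n
    if geo == GEOMETRY_SLAB and config.geo("Sphere slab") and config.geo("Sphere with radial fibers"):
        # radial fibers: exchange f with s; the sign keeps (f, n, s) a
        # proper (det = +1) right-handed triad
        f, s = s, -f

    out = FieldBundle(mesh)
    out.add_scalar("phi", phi)
    for name, p in nd.potentials.items():
        out.add_scalar(name, p)
    out.add_vector("f", f, unit=True)
    out.add_vector("s", s, unit=True)
    out.add_vector("n", n, unit=True)
    if nd.bundle_id is not None:
        out.add_scalar("bundle", nd.bundle_id.astype(np.float64))
    out.scalars["_degenerate"] = frame.degenerate.astype(np.float64)
    return out
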
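# Methods

This note records the model implemented by `myofiber`, the choices made
where the method family leaves room, and what the test geometries do and do
not establish about realistic anatomies.

## Model and assumptions

All rules share one structure: harmonic potentials on the myocardial domain
Ω with Dirichlet data on labeled anatomical surfaces, a gradient-built
orthonormal frame, and transmural rotation laws.

- **Transmural potential φ**: −Δφ = 0, φ = 0 on the endocardium, φ = 1 on
  the epicardium, homogeneous Neumann elsewhere. φ is used both for the
  transmural direction ê_t = ∇φ/‖∇φ‖ and as the abscissa of the angle laws.
  The laws are written directly in φ; no arc-length rescaling of wall depth
  is applied (the two coincide for a flat wall and differ mildly for curved
  walls).
- **Normal direction k** (apex → base), by geometry:
  - slab: gradient of an apex-to-base harmonic potential ψ between the two
    base surfaces (ventricular slab) or between the epicardial pole points
    (spherical slab);
  - based left ventricle: either the constant basal-plane normal (`RL`) or
    ∇ψ with ψ = 1 on the basal surface and ψ = 0 at the apex point (`BT`);
  - complete left ventricle: k = w∇ψ_ab + (1−w)∇ψ_ot, where ψ_ab and ψ_ot
    anchor to the mitral and aortic rings respectively and w is harmonic
    with w = 1 on the mitral ring and at the apex, w = 0 on the aortic ring;
  - left atrium: a per-vertex selection among ∇ψ_ab, ∇ψ_v, ∇ψ_r (below).
- **Frame**: ê_n is k orthogonalized against ê_t and normalized;
  ê_l = ê_n × ê_t. The triad [ê_l, ê_n, ê_t] is orthonormal and
  right-handed by construction.
- **Rotation**: "counter-clockwise" is the right-hand rule about the stated
  axis, implemented with the Rodrigues formula. The helical rotation by
  α(φ) is applied to the whole triad about ê_t (ê_l ↦ f). The sheetlet
  rotation by β(φ) is applied about the *rotated* longitudinal axis f —
  rotating about the original ê_l would not keep the result a pure rotation
  of the triad; both conventions coincide when α = 0, and for β = 0 the
  choice is immaterial. Angles interpolate linearly in φ between their
  endo/epi values.
- **Atria** get no transmural rotation: [f, n, s] = [ê_l, ê_n, ê_t].
- **Spherical slab with radial fibers**: f and s are exchanged; the new
  sheet direction takes a sign flip (f, s ← s, −f) so the output triad
  remains right-handed (det +1). Only the axis identification changes.

### Atrial bundle scheme

The atrial rule requires auxiliary potentials and a bundle-selection
procedure whose details vary between implementations; the scheme here is
this package's documented convention:

- ψ_ab: 1 on the mitral ring; 0 at the appendage apex point when an
  appendage is declared (`Appendage = true`), otherwise 0 on both
  pulmonary-vein rings (the idealized hollow-sphere atrium exposes no apex
  parameter, so an apex anchor is not available there);
- ψ_v: 1 on the left pulmonary ring, 0 on the right;
- ψ_r: 1 on the mitral ring, 0 on both pulmonary rings.

Each vertex is assigned exactly one bundle, tested in fixed order: mitral
if ψ_r ≥ 1 − τ_MV (k = ∇ψ_r); else left-PV if ψ_v ≥ 1 − τ_LPV (k = ∇ψ_v);
else right-PV if ψ_v ≤ τ_RPV (k = ∇ψ_v); else the default apico-basal
bundle (k = ∇ψ_ab). Larger τ means a larger bundle.

### Outflow-tract angles (complete left ventricle)

Separate helical/sheetlet angles may be set for the outflow-tract region.
They are blended with the standard angles through the Doste interpolation
function: effective endo/epi angles are w·(standard) + (1−w)·(OT), so the
OT values take over smoothly toward the aortic ring (w = 0) and the
standard values hold toward the mitral ring and apex (w = 1). The spatial
blending function is a design choice of this package; defaults make the OT
angles equal to the standard ones, i.e. a no-op unless configured.

## Discretization and numerics

- **Elements**: P1 on tet4, Q1 (trilinear, 2×2×2 Gauss) on hex8. Only
  degree 1 is implemented; higher `FE space degree` values are declared in
  the parameter schema but rejected at solve time. Degree 1 reproduces the
  globally linear potentials of rectangular slabs exactly, which the
  analytic tests exploit.
- **Solver**: conjugate gradients with Jacobi preconditioning on the
  symmetrically reduced SPD system; relative tolerance 1e-12 (parameter
  `Linear solver / Tolerance`), at most 10⁴ iterations. The tight default
  keeps solver error well below the 0.01° resolution at which angular
  results are reported.
- **Point constraints** (apex, sphere poles) snap the given coordinate to
  the nearest mesh vertex and constrain that single degree of freedom.
- **Gradient recovery**: per-cell gradients (constant on tets,
  quadrature-averaged on hexes) averaged to vertices with cell-volume
  weights — exact for linear fields.
- **Degenerate frames**: where k is numerically parallel to ê_t
  (‖k − (k·ê_t)ê_t‖ < 1e-10 ‖k‖), k is replaced by the average of k over
  adjacent non-degenerate vertices and the vertex is flagged; if the
  average is still parallel, the run fails with the vertex index. This is
  deliberate: the `RL` rule with an axial basal normal on a geometry with
  an exactly pole-symmetric apex vertex has a genuine frame singularity
  there (every neighbor contributes the same constant k), and emitting an
  arbitrary frame silently would corrupt downstream simulations. `BT` does
  not suffer from this because the recovered apex gradient tilts with the
  wall.
- **Cross-mesh transfer** (sensitivity protocol): coarse fields are
  evaluated at the fine mesh's vertices — the reference field is defined
  pointwise there — by locating the containing cell (KD-tree on centroids
  plus barycentric test or trilinear Newton inversion) and interpolating,
  then renormalizing to unit length. Points outside the mesh within a snap
  tolerance are clipped to the nearest cell. The angular error uses
  arccos of the clamped dot product; note arccos(1 − ε_mach) ≈ 1.2e-6
  degrees, which is the resolution floor of the metric in double precision.

## Generated test geometries

`myofiber.idealized` builds every geometry deterministically, with the
boundary labels the rules expect (defaults shared with the parameter file:
epi 10, endo 20, base 30, base-up 40, base-down 50, side 60, MV 70, AV 75,
LPV 80, RPV 90):

- **Slab**: structured box; endo/epi on the x-walls, base-up/-down on the
  z-walls, Neumann side walls. Default 24×24×48 mm with 6 mm edges — the
  dimensions are this package's choice of a ventricular-wall-like block
  (wall thickness ≈ 24 mm across four coarse elements). The tet variant
  splits each hex into 6 tets sharing the cell's main diagonal (Kuhn rule),
  which conforms globally on the structured lattice and preserves volume.
- **Spherical shell**: icosphere (pole-oriented, subdivided to a target
  edge h) extruded radially; prisms are split into 3 tets with quad-face
  diagonals chosen by smallest-global-vertex-id, so adjacent prisms agree.
  Optional conical holes carve labeled rings: mitral + two pulmonary-vein
  rings for the idealized atrium, mitral + aortic rings as a topological
  stand-in for a complete left ventricle. Defaults r_endo 20 mm, r_epi
  30 mm (atrium 25 mm).
- **Truncated-ellipsoid left ventricle**: latitude-longitude cap surface
  (apex vertex + rings, basal ring forced exactly onto the truncation
  plane) extruded through the wall; endo semi-axes (20, 20, 50) mm, epi
  (30, 30, 60) mm, basal plane at z = 20 mm, apex at (0, 0, −60 mm).

What these fixtures establish — and what they do not: the rectangular slab
makes both potentials linear, so it isolates the frame/rotation algebra
from discretization error (exact to machine precision); the shell has the
closed-form concentric-sphere potential, so it measures discretization
convergence; the LV/LA fixtures exercise the full dispatch, point
constraints, bundles and degeneracy handling. None of them has the
irregular surface labels, wall-thickness variation or mesh anisotropy of
patient geometries, so passing tests demonstrate correctness of the method
and its numerics, not anatomical fidelity of any particular patient run.

## Parameters

All parameters carry a pattern, default, doc string and verbosity class,
and are validated on parse. The ones that shape the physics:

| parameter | default | meaning |
|---|---|---|
| alpha endo / alpha epi | −60° / +60° | helical angle at the walls (ventricular physiological range) |
| beta endo / beta epi | 0° / 0° | sheetlet angle at the walls |
| alpha/beta … OT | = standard | outflow-tract variants (complete LV) |
| Tau bundle MV / LPV / RPV | 0.65 / 0.65 / 0.10 | atrial bundle sizes in [0, 1] |
| Normal to base | (0, 0, 1) | basal normal for `RL` |
| Scaling factor | 1 | coordinate scaling on read (1e-3 for mm meshes) |

The β defaults are zero because no single sheetlet range is canonical
across chambers; the τ defaults give a broad mitral collar, a broad left-PV
bundle and a narrow right-PV bundle on the hollow-sphere atrium.

## Study sizes

The refinement studies use a four-level slab family with 6 mm coarsest
edges halving per level (finest ≈ 7·10⁴ vertices, both element types) and
spherical shells at h = 10, 5, 2.5 mm; these sizes were chosen so the whole
suite and the acceptance script run in well under a minute each on one CPU
while leaving at least three refinement steps to exhibit convergence.

## Known limitations

- Serial only; no parallel assembly or partitioned I/O.
- FE degree 1 only; no adaptive refinement; Jacobi-CG only.
- Gmsh ASCII v2.2/v4.1 input only (binary `.msh` rejected); xml parameter
  files rejected (prm and json are the supported, interconvertible pair).
- The atrial bundle scheme and the OT blending function are this package's
  documented conventions; other implementations of the same method family
  differ in these details, so per-vertex bundle boundaries need not match
  across tools even when both are internally consistent.
- Bi-ventricular geometries are supported only through tag composition on
  the based-ventricle rule (endocardial labels excluding the right septum
  as `Tags endo`, epicardium plus right septum as `Tags epi`); there is no
  dedicated bi-ventricular geometry type, and no whole-heart composition.
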
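"""Laplace solver and gradient recovery: oracles, exactness, convergence."""

import numpy as np
import pytest

import myofiber as mf
from myofiber.errors import ConfigurationError, IllPosedError
from myofiber.fem import DirichletSpec, assemble_stiffness, gradient, solve_laplace
from myofiber.idealized import BASE_DOWN, BASE_UP, ENDO, EPI
from myofiber.mesh import LabeledMesh

# stiffness of the 2-tet mesh {(0,0,0),(1,0,0),(0,1,0),(0,0,1),(1,1,1)} with
# cells (0,1,2,3), (1,2,3,4): computed independently by symbolic integration
# of the P1 barycentric gradients (sympy), frozen here as exact rationals
_K_2TET = np.array(
    [
        [1 / 2, -1 / 6, -1 / 6, -1 / 6, 0],
        [-1 / 6, 5 / 12, -1 / 12, -1 / 12, -1 / 12],
        [-1 / 6, -1 / 12, 5 / 12, -1 / 12, -1 / 12],
        [-1 / 6, -1 / 12, -1 / 12, 5 / 12, -1 / 12],
        [0, -1 / 12, -1 / 12, -1 / 12, 1 / 4],
    ]
)

# stiffness of the unit-cube Q1 element (gmsh node order), from symbolic
# integration of the trilinear shape gradients: diag 1/3, edge neighbors 0,
# face/space diagonals -1/12
_K_CUBE = (
    12 * np.eye(8)
    - 3
    * np.array(
        [
            [0, 0, 1, 0, 0, 1, 1, 1],
            [0, 0, 0, 1, 1, 0, 1, 1],
            [1, 0, 0, 0, 1, 1, 0, 1],
            [0, 1, 0, 0, 1, 1, 1, 0],
            [0, 1, 1, 1, 0, 0, 1, 0],
            [1, 0, 1, 1, 0, 0, 0, 1],
            [1, 1, 0, 1, 1, 0, 0, 0],
            [1, 1, 1, 0, 0, 1, 0, 0],
        ]
    )
) / 36.0


def two_tet_mesh():
    verts = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], dtype=float
    )
    cells = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
    facets = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 4], [2, 3, 4], [1, 4, 3]])
    labels = np.arange(1, 7)
    return LabeledMesh(verts, cells, facets, labels, "Tet")


def unit_cube_hex():
    return mf.make_slab(mf.SlabSpec(1, 1, 1, 1, 1, 1, "Hex"))


class TestStiffnessOracles:
    def test_two_tet_matrix_matches_symbolic_integration(self):
        K = assemble_stiffness(two_tet_mesh()).toarray()
        assert np.abs(K - _K_2TET).max() <= 1e-12

    def test_unit_cube_matrix_matches_symbolic_integration(self):
        mesh = unit_cube_hex()
        K = assemble_stiffness(mesh).toarray()
        c = mesh.cells[0]  # map global vertex numbering to cell-local order
        assert np.abs(K[np.ix_(c, c)] - _K_CUBE).max() <= 1e-12

    @pytest.mark.parametrize("fixture", ["slab_hex", "slab_tet", "shell"])
    def test_operator_symmetric_positive_semidefinite(self, fixture, request):
        mesh = request.getfixturevalue(fixture)
        K = assemble_stiffness(mesh)
        asym = abs(K - K.T)
        assert asym.max() <= 1e-12
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=mesh.n_vertices)
            assert x @ (K @ x) >= -1e-12


class TestSolveLaplace:
    @pytest.mark.parametrize("fixture", ["slab_hex", "slab_tet"])
    def test_linear_solution_reproduced_exactly(self, fixture, request):
        mesh = request.getfixturevalue(fixture)
        Lx = mesh.metadata["spec"].Lx
        u = solve_laplace(mesh, DirichletSpec({ENDO: 0.0, EPI: 1.0}))
        assert np.abs(u - mesh.vertices[:, 0] / Lx).max() <= 1e-10

    def test_constant_dirichlet_gives_constant_field(self, slab_hex):
        bc = DirichletSpec({lab: 3.25 for lab in slab_hex.label_set})
        u = solve_laplace(slab_hex, bc)
        assert np.abs(u - 3.25).max() <= 1e-10

    def test_shell_matches_concentric_sphere_closed_form(self):
        # phi(r) = (1/r_endo - 1/r) / (1/r_endo - 1/r_epi), refined mesh
        sh = mf.make_shell(mf.ShellSpec(0.02, 0.03, 0.005))
        u = solve_laplace(sh, DirichletSpec({ENDO: 0.0, EPI: 1.0}))
        r = np.linalg.norm(sh.vertices, axis=1)
        exact = (1 / 0.02 - 1 / r) / (1 / 0.02 - 1 / 0.03)
        assert np.abs(u - exact).max() <= 5e-3

    def test_shell_error_decreases_under_refinement(self):
        errs = []
        for h in (0.005, 0.0025):
            sh = mf.make_shell(mf.ShellSpec(0.02, 0.03, h))
            u = solve_laplace(sh, DirichletSpec({ENDO: 0.0, EPI: 1.0}))
            r = np.linalg.norm(sh.vertices, axis=1)
            exact = (1 / 0.02 - 1 / r) / (1 / 0.02 - 1 / 0.03)
            errs.append(np.abs(u - exact).max())
        assert errs[1] < errs[0]

    @pytest.mark.parametrize("fixture", ["slab_tet", "shell", "lv"])
    def test_discrete_maximum_principle(self, fixture, request):
        mesh = request.getfixturevalue(fixture)
        labels = sorted(mesh.label_set)
        bc = DirichletSpec({labels[0]: 0.0, labels[1]: 1.0})
        u = solve_laplace(mesh, bc)
        assert u.min() >= -1e-8
        assert u.max() <= 1 + 1e-8

    def test_point_constraints_attained_at_snapped_vertices(self, shell):
        north = shell.metadata["north_pole"]
        south = shell.metadata["south_pole"]
        u = solve_laplace(shell, DirichletSpec(point_values=[(north, 1.0), (south, 0.0)]))
        assert u[shell.nearest_vertex(north)] == 1.0
        assert u[shell.nearest_vertex(south)] == 0.0
        assert u.min() >= -1e-8 and u.max() <= 1 + 1e-8

    def test_missing_label_names_the_label(self, slab_hex):
        with pytest.raises(ConfigurationError, match="999"):
            solve_laplace(slab_hex, DirichletSpec({999: 1.0}))

    def test_no_constraint_is_ill_posed(self, slab_hex):
        with pytest.raises(IllPosedError):
            solve_laplace(slab_hex, DirichletSpec())

    def test_higher_degree_rejected(self, slab_hex):
        with pytest.raises(ConfigurationError, match="degree"):
            solve_laplace(slab_hex, DirichletSpec({ENDO: 0.0, EPI: 1.0}), degree=2)


class TestGradient:
    @pytest.mark.parametrize("fixture", ["slab_hex", "slab_tet", "shell", "lv"])
    def test_exact_on_linear_fields(self, fixture, request):
        mesh = request.getfixturevalue(fixture)
        v = mesh.vertices
        g = gradient(mesh, 2 * v[:, 0] + 3 * v[:, 1] - v[:, 2])
        assert np.abs(g - np.array([2.0, 3.0, -1.0])).max() <= 1e-10

    def test_quadratic_field_volume_weighted_hand_value(self):
        # field x^2 on a unit hex slab with nx=2: cell gradients average 0.5
        # and 1.5 in x; the interior plane x=0.5 receives their equal-volume
        # mean (the tet split shares no such symmetry, so hex only)
        m = mf.make_slab(mf.SlabSpec(1, 1, 1, 2, 1, 1, "Hex"))
        g = gradient(m, m.vertices[:, 0] ** 2)
        mid = np.abs(m.vertices[:, 0] - 0.5) < 1e-12
        assert np.abs(g[mid, 0] - 1.0).max() <= 1e-10
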
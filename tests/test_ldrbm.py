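"""Rule-based fiber generation: frames, rotations, normal rules, dispatch."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import myofiber as mf
from myofiber.errors import ConfigurationError, DegenerateFrameError
from myofiber.idealized import AV, BASE_DOWN, BASE_UP, ENDO, EPI, LPV, MV, RPV
from myofiber.ldrbm import (
    AngleLaw,
    BUNDLE_DEFAULT,
    BUNDLE_LPV,
    BUNDLE_MV,
    BUNDLE_RPV,
    build_frame,
    normal_atrial,
    normal_bt,
    normal_doste,
    normal_rl,
    rotate_frame,
    transmural_direction,
)

from conftest import config_for


class TestTransmuralDirection:
    def test_slab_linear_potential_and_unit_direction(self, slab_hex):
        Lx = slab_hex.metadata["spec"].Lx
        phi, e_t = transmural_direction(slab_hex, ENDO, EPI)
        assert np.abs(phi - slab_hex.vertices[:, 0] / Lx).max() <= 1e-10
        assert np.abs(e_t - np.array([1.0, 0.0, 0.0])).max() <= 1e-10

    def test_swapped_tags_mirror_potential_and_flip_direction(self, slab_tet):
        phi, e_t = transmural_direction(slab_tet, ENDO, EPI)
        phi2, e_t2 = transmural_direction(slab_tet, EPI, ENDO)
        assert np.abs(phi2 - (1.0 - phi)).max() <= 1e-10
        assert np.abs(e_t2 + e_t).max() <= 1e-10

    def test_shell_direction_near_radial(self):
        sh = mf.make_shell(mf.ShellSpec(0.02, 0.03, 0.0025))
        _, e_t = transmural_direction(sh, ENDO, EPI)
        er = sh.vertices / np.linalg.norm(sh.vertices, axis=1)[:, None]
        ang = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", e_t, er), -1, 1)))
        assert ang.max() <= 2.0


class TestNormalRules:
    def test_rl_constant_field(self, slab_hex):
        nd = normal_rl(slab_hex, (0, 0, 1))
        assert np.array_equal(nd.k, np.tile([0.0, 0.0, 1.0], (slab_hex.n_vertices, 1)))
        nd2 = normal_rl(slab_hex, (0, 0, 2))  # normalization deferred to the frame
        assert np.array_equal(nd2.k, 2 * nd.k)

    def test_rl_zero_vector_rejected(self, slab_hex):
        with pytest.raises(ConfigurationError):
            normal_rl(slab_hex, (0, 0, 0))

    def test_bt_slab_linear_potential(self, slab_hex):
        Lz = slab_hex.metadata["spec"].Lz
        nd = normal_bt(slab_hex, base_tags=BASE_UP, apex_tags=BASE_DOWN)
        assert np.abs(nd.potentials["psi"] - slab_hex.vertices[:, 2] / Lz).max() <= 1e-10
        assert np.abs(nd.k - np.array([0.0, 0.0, 1.0 / Lz])).max() <= 1e-8

    def test_bt_and_rl_agree_on_slab(self, slab_hex):
        _, e_t = transmural_direction(slab_hex, ENDO, EPI)
        f_bt = build_frame(e_t, normal_bt(slab_hex, base_tags=BASE_UP, apex_tags=BASE_DOWN).k)
        f_rl = build_frame(e_t, normal_rl(slab_hex, (0, 0, 1)).k)
        assert np.abs(f_bt.e_n - f_rl.e_n).max() <= 1e-10
        assert np.abs(f_rl.e_n - np.array([0.0, 0.0, 1.0])).max() <= 1e-10

    def test_bt_pole_points_respect_bounds(self, shell):
        nd = normal_bt(
            shell,
            base_point=shell.metadata["north_pole"],
            apex_point=shell.metadata["south_pole"],
        )
        psi = nd.potentials["psi"]
        assert psi.min() >= -1e-8 and psi.max() <= 1 + 1e-8
        assert psi[shell.nearest_vertex(shell.metadata["north_pole"])] == 1.0
        assert psi[shell.nearest_vertex(shell.metadata["south_pole"])] == 0.0

    def test_bt_apex_on_base_rejected(self, slab_hex):
        spec = slab_hex.metadata["spec"]
        with pytest.raises(ConfigurationError, match="apex"):
            normal_bt(slab_hex, base_tags=BASE_UP, apex_point=(0, 0, spec.Lz))


class TestNormalDoste:
    def test_interpolation_function_within_bounds(self, lv_complete):
        apex = (0.0, 0.0, -lv_complete.metadata["spec"].r_epi)
        nd = normal_doste(lv_complete, MV, AV, apex)
        w = nd.potentials["w"]
        assert w.min() >= -1e-8 and w.max() <= 1 + 1e-8

    def test_k_equals_ab_gradient_where_w_is_one(self, lv_complete):
        apex = (0.0, 0.0, -lv_complete.metadata["spec"].r_epi)
        nd = normal_doste(lv_complete, MV, AV, apex)
        w = nd.potentials["w"]
        ones = w == 1.0
        assert ones.any()
        g_ab = mf.gradient(lv_complete, nd.potentials["psi_ab"])
        assert np.abs(nd.k[ones] - g_ab[ones]).max() <= 1e-12

    def test_coincident_rings_make_blend_independent_of_w(self, slab_hex):
        # duplicate the top facets under a second label: Gamma_mv and
        # Gamma_av become geometrically identical, so psi_ab == psi_ot and
        # k must equal the common gradient regardless of w
        m = mf.make_slab(mf.SlabSpec())
        top = m.facet_labels == BASE_UP
        m.facets = np.vstack([m.facets, m.facets[top]])
        m.facet_labels = np.concatenate([m.facet_labels, np.full(top.sum(), 41)])
        apex = (0.0, 0.0, 0.0)
        nd = normal_doste(m, BASE_UP, 41, apex)
        g_ab = mf.gradient(m, nd.potentials["psi_ab"])
        assert np.abs(nd.k - g_ab).max() <= 1e-9

    def test_overlapping_ring_labels_rejected(self, lv_complete):
        with pytest.raises(ConfigurationError, match="overlap"):
            normal_doste(lv_complete, MV, MV, (0, 0, -0.03))


class TestNormalAtrial:
    def test_bundle_assignment_is_total(self, la_shell):
        nd = normal_atrial(la_shell, MV, LPV, RPV, (0.65, 0.65, 0.10))
        assert nd.bundle_id.shape == (la_shell.n_vertices,)
        assert set(np.unique(nd.bundle_id)) <= {
            BUNDLE_DEFAULT, BUNDLE_MV, BUNDLE_LPV, BUNDLE_RPV,
        }
        assert np.all(np.isfinite(nd.k))

    def test_mv_threshold_selects_mv_bundle(self, la_shell):
        nd = normal_atrial(la_shell, MV, LPV, RPV, (0.65, 0.65, 0.10))
        psi_r = nd.potentials["psi_r"]
        assert np.all(nd.bundle_id[psi_r >= 1 - 0.65] == BUNDLE_MV)
        g_r = mf.gradient(la_shell, psi_r)
        mv_mask = nd.bundle_id == BUNDLE_MV
        assert np.abs(nd.k[mv_mask] - g_r[mv_mask]).max() <= 1e-12

    def test_degenerate_thresholds_leave_interior_in_default_bundle(self, la_shell):
        nd = normal_atrial(la_shell, MV, LPV, RPV, (0.0, 0.0, 0.0))
        rings = np.concatenate(
            [la_shell.vertices_on_labels(t) for t in (MV, LPV, RPV)]
        )
        interior = np.setdiff1d(np.arange(la_shell.n_vertices), rings)
        assert np.all(nd.bundle_id[interior] == BUNDLE_DEFAULT)
        g_ab = mf.gradient(la_shell, nd.potentials["psi_ab"])
        assert np.abs(nd.k[interior] - g_ab[interior]).max() <= 1e-12

    def test_thresholds_outside_unit_interval_rejected(self, la_shell):
        with pytest.raises(ConfigurationError, match="Tau"):
            normal_atrial(la_shell, MV, LPV, RPV, (1.2, 0.5, 0.1))


class TestBuildFrame:
    def test_known_projection(self):
        e_t = np.array([[1.0, 0.0, 0.0]])
        fr = build_frame(e_t, np.array([[0.0, 0.0, 1.0]]))
        assert np.allclose(fr.e_n, [[0, 0, 1]], atol=1e-14)
        assert np.allclose(fr.e_l, [[0, 1, 0]], atol=1e-14)
        # parallel component of k is discarded
        fr2 = build_frame(e_t, np.array([[1.0, 0.0, 1.0]]))
        assert np.allclose(fr2.e_n, [[0, 0, 1]], atol=1e-14)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_random_frames_orthonormal_right_handed(self, seed):
        rng = np.random.default_rng(seed)
        e_t = rng.normal(size=(16, 3))
        e_t /= np.linalg.norm(e_t, axis=1)[:, None]
        k = rng.normal(size=(16, 3))
        # reject near-parallel draws: the degenerate path is tested separately
        proj = k - np.einsum("ij,ij->i", k, e_t)[:, None] * e_t
        keep = np.linalg.norm(proj, axis=1) > 1e-3 * np.linalg.norm(k, axis=1)
        fr = build_frame(e_t[keep], k[keep])
        Q = np.stack([fr.e_l, fr.e_n, fr.e_t], axis=2)
        eye = np.einsum("nij,nik->njk", Q, Q)
        assert np.abs(eye - np.eye(3)).max() <= 1e-12
        assert np.abs(np.linalg.det(Q) - 1.0).max() <= 1e-12

    def test_isolated_degeneracy_repaired_by_neighbor_average(self, slab_hex):
        n = slab_hex.n_vertices
        e_t = np.tile([1.0, 0.0, 0.0], (n, 1))
        k = np.tile([0.0, 0.0, 1.0], (n, 1))
        k[0] = [1.0, 0.0, 0.0]  # parallel to e_t at one vertex
        fr = build_frame(e_t, k, slab_hex)
        assert fr.degenerate[0] and fr.degenerate.sum() == 1
        assert np.allclose(fr.e_n[0], [0, 0, 1], atol=1e-12)

    def test_globally_parallel_k_fails(self, slab_hex):
        n = slab_hex.n_vertices
        e_t = np.tile([1.0, 0.0, 0.0], (n, 1))
        with pytest.raises(DegenerateFrameError):
            build_frame(e_t, e_t.copy(), slab_hex)


class TestRotateFrame:
    def frame(self, n=1):
        e_l = np.tile([0.0, 1.0, 0.0], (n, 1))
        e_n = np.tile([0.0, 0.0, 1.0], (n, 1))
        e_t = np.tile([1.0, 0.0, 0.0], (n, 1))
        return mf.FrameField(e_l=e_l, e_n=e_n, e_t=e_t)

    def test_zero_angles_are_identity(self):
        fr = rotate_frame(self.frame(), np.array([0.3]), AngleLaw(0, 0, 0, 0))
        assert np.array_equal(fr.f, fr.e_l)
        assert np.array_equal(fr.n, fr.e_n)
        assert np.array_equal(fr.s, fr.e_t)

    def test_right_hand_quarter_turn(self):
        # alpha=90 deg about e_t=(1,0,0) takes e_l=(0,1,0) to (0,0,1)
        fr = rotate_frame(self.frame(), np.array([0.0]), AngleLaw(90, 90, 0, 0))
        assert np.allclose(fr.f, [[0, 0, 1]], atol=1e-14)

    def test_midwall_angle_vanishes_for_symmetric_law(self):
        fr = rotate_frame(self.frame(), np.array([0.5]), AngleLaw(-60, 60, 0, 0))
        assert np.abs(np.degrees(np.arccos(np.clip(fr.f[0] @ fr.e_l[0], -1, 1)))) <= 1e-8

    def test_beta_rotation_preserves_orthonormality(self):
        fr = rotate_frame(self.frame(), np.array([0.25]), AngleLaw(-60, 60, 25, -65))
        Q = np.stack([fr.f, fr.n, fr.s], axis=2)
        assert np.abs(np.einsum("nij,nik->njk", Q, Q) - np.eye(3)).max() <= 1e-12
        assert np.abs(np.linalg.det(Q) - 1.0).max() <= 1e-12


class TestGenerateFibers:
    def test_slab_angle_matches_closed_form(self, slab_hex):
        Lx = slab_hex.metadata["spec"].Lx
        cfg = config_for("Slab", "Hex")
        fb = mf.generate_fibers(slab_hex, cfg)
        alpha = -60 * (1 - slab_hex.vertices[:, 0] / Lx) + 60 * slab_hex.vertices[:, 0] / Lx
        f = fb.vectors["f"]
        # signed angle via atan2 is numerically stable near zero, unlike
        # arccos of the dot product which floors at ~1e-6 deg in double
        signed = np.degrees(np.arctan2(f[:, 2], f[:, 1]))
        assert np.abs(signed - alpha).max() <= 1e-8

    def test_sphere_tangential_versus_radial_fibers(self, shell):
        er = shell.vertices / np.linalg.norm(shell.vertices, axis=1)[:, None]
        cfg = config_for("Slab", "Tet", **{"Sphere slab": True})
        fb = mf.generate_fibers(shell, cfg)
        assert np.abs(np.einsum("ij,ij->i", fb.vectors["s"], fb.vectors["s"]) - 1).max() <= 1e-12
        # beta = 0: s = e_t, so f.e_t == 0 identically
        assert np.abs(np.einsum("ij,ij->i", fb.vectors["f"], fb.vectors["s"])).max() <= 1e-8
        cfg_r = config_for(
            "Slab", "Tet", **{"Sphere slab": True, "Sphere with radial fibers": True}
        )
        fb_r = mf.generate_fibers(shell, cfg_r)
        dots = np.einsum("ij,ij->i", fb_r.vectors["f"], fb.vectors["s"])
        assert np.abs(np.abs(dots) - 1.0).max() <= 1e-8

    def test_left_atrium_frame_is_unrotated(self, la_shell):
        cfg = config_for("Left atrium", "Tet")
        fb = mf.generate_fibers(la_shell, cfg)
        phi, e_t = transmural_direction(la_shell, ENDO, EPI)
        assert np.abs(fb.vectors["s"] - e_t).max() <= 1e-12

    def test_lv_bt_algorithm_runs(self, lv):
        cfg = config_for("Left ventricle", "Tet", **{"Algorithm type": "BT"})
        fb = mf.generate_fibers(lv, cfg)
        for name in ("f", "s", "n"):
            assert np.abs(np.linalg.norm(fb.vectors[name], axis=1) - 1).max() <= 1e-8

    def test_lv_rl_algorithm_runs_when_k_avoids_transmural_axis(self, lv):
        # with the basal normal tilted off the pole axis, no vertex has k
        # parallel to e_t, so the RL rule completes
        cfg = config_for(
            "Left ventricle", "Tet",
            **{"Algorithm type": "RL", "Normal to base": (0.3, 0.1, 1.0)},
        )
        fb = mf.generate_fibers(lv, cfg)
        for name in ("f", "s", "n"):
            assert np.abs(np.linalg.norm(fb.vectors[name], axis=1) - 1).max() <= 1e-8

    def test_lv_rl_apex_singularity_reported_with_location(self, lv):
        # a constant axial k is exactly parallel to e_t at the symmetric
        # apex column and neighbor averaging cannot resolve it: the rule
        # must fail with a located error rather than emit a garbage frame
        cfg = config_for(
            "Left ventricle", "Tet",
            **{"Algorithm type": "RL", "Normal to base": (0.0, 0.0, 1.0)},
        )
        with pytest.raises(DegenerateFrameError, match="vertex"):
            mf.generate_fibers(lv, cfg)

    def test_lv_complete_ot_blend_runs(self, lv_complete):
        cfg = config_for(
            "Left ventricle complete", "Tet",
            Apex=(0.0, 0.0, -lv_complete.metadata["spec"].r_epi),
            **{"alpha endo OT": -30.0, "alpha epi OT": 30.0},
        )
        fb = mf.generate_fibers(lv_complete, cfg)
        assert {"phi", "psi_ab", "psi_ot", "w"} <= set(fb.scalars)

    def test_element_type_mismatch_rejected(self, slab_tet):
        with pytest.raises(ConfigurationError, match="Element type"):
            mf.generate_fibers(slab_tet, config_for("Slab", "Hex"))

    def test_missing_tag_names_the_label(self, slab_hex):
        cfg = config_for("Slab", "Hex", **{"Tags endo": (123,)})
        with pytest.raises(ConfigurationError, match="123"):
            mf.generate_fibers(slab_hex, cfg)

    def test_angle_law_endpoints_attained_exactly(self, slab_hex):
        cfg = config_for("Slab", "Hex")
        fb = mf.generate_fibers(slab_hex, cfg)
        phi = fb.scalars["phi"]
        f = fb.vectors["f"]
        # signed angle of f from e_l=(0,1,0) about e_t=(1,0,0)
        signed = np.degrees(np.arctan2(f[:, 2], f[:, 1]))
        assert np.abs(signed[phi == 0.0] + 60.0).max() <= 1e-8
        assert np.abs(signed[phi == 1.0] - 60.0).max() <= 1e-8
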
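"""Finite-element core tests: assembly consistency, loads, contact, strains."""

import numpy as np
import pytest

from airwaymech import (OgdenMaterial, TissueLibrary, TracheaConfig,
                        build_trachea_mesh, element_strains,
                        uniaxial_cauchy_stress)
from airwaymech.fem import TracheaModel
from airwaymech.geometry import HexMesh, lumen_surface_area
from airwaymech.ogden import CMH2O_TO_MPA
from airwaymech.solver import SolverConfig, newton_solve
from airwaymech.synthetic import (make_ring_fixture,
                                  make_single_element_fixture,
                                  solve_single_element)


@pytest.fixture(scope="module")
def small_model(library):
    mesh = build_trachea_mesh(TracheaConfig.coarse(diameter=6.0))
    return TracheaModel(mesh, library, contact=False)


def _uniform_library(material):
    return TissueLibrary({r: material for r in
                          ("cartilage", "fibrous", "smooth_muscle", "mucosa")})


class TestAssembly:
    def test_zero_displacement_zero_residual(self, small_model):
        f, _ = small_model.internal_force(np.zeros(small_model.ndof),
                                          want_tangent=False)
        assert np.abs(f).max() < 1e-12

    def test_residual_is_gradient_of_energy(self, small_model):
        rng = np.random.default_rng(3)
        u = 0.01 * rng.standard_normal(small_model.ndof)
        f, _ = small_model.internal_force(u, want_tangent=False)
        h = 1e-7
        for i in rng.choice(small_model.ndof, 8, replace=False):
            up, um = u.copy(), u.copy()
            up[i] += h
            um[i] -= h
            fd = (small_model.total_energy(up) -
                  small_model.total_energy(um)) / (2 * h)
            assert fd == pytest.approx(f[i], rel=2e-4, abs=1e-10)

    def test_tangent_matches_residual_finite_difference(self, small_model):
        rng = np.random.default_rng(4)
        u = 0.01 * rng.standard_normal(small_model.ndof)
        _, K = small_model.internal_force(u)
        h = 1e-7
        for i in rng.choice(small_model.ndof, 4, replace=False):
            up, um = u.copy(), u.copy()
            up[i] += h
            um[i] -= h
            fp, _ = small_model.internal_force(up, want_tangent=False)
            fm, _ = small_model.internal_force(um, want_tangent=False)
            col = (fp - fm) / (2 * h)
            Kc = np.asarray(K[:, i].todense()).ravel()
            assert np.abs(col - Kc).max() / np.abs(col).max() < 1e-4

    def test_internal_tangent_symmetric(self, small_model):
        rng = np.random.default_rng(5)
        u = 0.005 * rng.standard_normal(small_model.ndof)
        _, K = small_model.internal_force(u)
        asym = (K - K.T)
        assert abs(asym).max() < 1e-9 * abs(K).max()

    def test_inverted_element_signals_step_cut(self, small_model):
        from airwaymech.fem import _InvertedElement

        u = np.zeros(small_model.ndof)
        # crush one element's nodes through its opposite face
        conn = small_model.mesh.elems[0]
        u = u.reshape(-1, 3)
        u[conn[:4]] = small_model.mesh.nodes[conn[4:]] - \
            small_model.mesh.nodes[conn[:4]] + 0.1
        with pytest.raises(_InvertedElement):
            small_model.internal_force(u.ravel(), want_tangent=False)


class TestSingleElement:
    @pytest.mark.parametrize("a,b,stretch,tol", [
        (0.1, 3.4, 1.5, 0.01),        # mucosa at 50% strain
        (0.109, 16.63, 1.1, 0.02),    # cartilage (stiffer -> more kappa bias)
    ])
    def test_reaction_matches_closed_form(self, a, b, stretch, tol):
        mat = OgdenMaterial.single(a, b)
        fx = make_single_element_fixture(mat, stretch)
        stress, _, _ = solve_single_element(fx)
        assert stress == pytest.approx(fx.reference, rel=tol)


class TestPressureLoad:
    def test_zero_pressure_zero_force(self, small_model):
        f, _ = small_model.pressure_force(np.zeros(small_model.ndof), 0.0)
        assert np.abs(f).max() == 0.0

    def test_resultants_are_pressure_times_projected_area(self, library):
        """Chord and arc loads each integrate to p x projected area D x L,
        and the closed cross-section's net resultant cancels."""
        import dataclasses

        mesh = build_trachea_mesh(TracheaConfig.coarse(diameter=10.0))
        p = 40.0 * CMH2O_TO_MPA
        y = mesh.nodes[:, 1]
        chord = np.array([np.all(np.abs(y[f]) < 1e-9)
                          for f in mesh.lumen_facets])
        expected = p * 10.0 * 50.0
        for sel, sign in ((chord, +1.0), (~chord, -1.0)):
            sub = dataclasses.replace(mesh,
                                      lumen_facets=mesh.lumen_facets[sel])
            model = TracheaModel(sub, library, contact=False)
            f, _ = model.pressure_force(np.zeros(model.ndof), 40.0,
                                        want_tangent=False)
            assert f.reshape(-1, 3)[:, 1].sum() == \
                pytest.approx(sign * expected, rel=1e-6)
        model = TracheaModel(mesh, library, contact=False)
        f, _ = model.pressure_force(np.zeros(model.ndof), 40.0,
                                    want_tangent=False)
        assert np.abs(f.reshape(-1, 3).sum(axis=0)).max() < 1e-6 * expected
        # ~5 N equivalent total force at 40 cm H2O on the 10 mm model
        assert 40.0 * CMH2O_TO_MPA * lumen_surface_area(mesh) == \
            pytest.approx(5.04, rel=0.02)

    def test_load_stiffness_matches_finite_difference(self, small_model):
        rng = np.random.default_rng(6)
        u = 0.01 * rng.standard_normal(small_model.ndof)
        f, Kp = small_model.pressure_force(u, 10.0)
        h = 1e-7
        for i in rng.choice(np.unique(3 * small_model.mesh.lumen_facets), 4,
                            replace=False):
            up, um = u.copy(), u.copy()
            up[i] += h
            um[i] -= h
            fp, _ = small_model.pressure_force(up, 10.0, want_tangent=False)
            fm, _ = small_model.pressure_force(um, 10.0, want_tangent=False)
            col = (fp - fm) / (2 * h)
            Kc = np.asarray(Kp[:, i].todense()).ravel()
            assert np.abs(col - Kc).max() <= 1e-6 + 1e-4 * np.abs(col).max()

    def test_follower_force_rotates_with_configuration(self, library):
        """Rigid rotation of the whole mesh rotates the load vector."""
        from scipy.spatial.transform import Rotation

        mesh = build_trachea_mesh(TracheaConfig.coarse(diameter=6.0))
        model = TracheaModel(mesh, library, contact=False)
        R = Rotation.from_rotvec([0.0, 0.0, 0.7]).as_matrix()
        u_rot = (mesh.nodes @ R.T - mesh.nodes)
        f0, _ = model.pressure_force(np.zeros(model.ndof), 8.0,
                                     want_tangent=False)
        f1, _ = model.pressure_force(u_rot.ravel(), 8.0, want_tangent=False)
        np.testing.assert_allclose(f1.reshape(-1, 3),
                                   f0.reshape(-1, 3) @ R.T, atol=1e-10)


class TestContact:
    @staticmethod
    def _two_plate_model(gap=0.5):
        """Two single-element plates with facing 'luminal' surfaces."""
        def plate(z0):
            return np.array([[x, y, z0 + dz] for dz in (0.0, 0.5)
                             for y in (0.0, 1.0) for x in (0.0, 1.0)])

        nodes = np.vstack([plate(0.0), plate(0.5 + gap)])
        elems = np.array([[0, 1, 3, 2, 4, 5, 7, 6],
                          [8, 9, 11, 10, 12, 13, 15, 14]])
        # facing facets: top of lower plate (+z), bottom of upper (-z)
        facets = np.array([[4, 5, 7, 6], [9, 8, 10, 11]])
        mesh = HexMesh(nodes=nodes, elems=elems,
                       region=np.array(["mucosa", "mucosa"]),
                       node_sets={"fixed_dofs": np.arange(3 * 16)},
                       lumen_facets=facets,
                       mid_loop_nodes=np.zeros(0, np.int64), config=None)
        lib = _uniform_library(OgdenMaterial.single(0.1, 3.4))
        return TracheaModel(mesh, lib, contact=True, contact_penalty=10.0)

    def test_no_penetration_no_force(self):
        model = self._two_plate_model(gap=0.5)
        f, _, pen = model.contact_force(np.zeros(model.ndof))
        assert np.abs(f).max() == 0.0 and pen == 0.0

    def test_overlap_force_is_penalty_times_area_times_depth(self):
        model = self._two_plate_model(gap=0.5)
        delta = 0.1
        u = np.zeros((16, 3))
        u[8:, 2] = -(0.5 + delta)     # push upper plate into the lower
        f, K, pen = model.contact_force(u.ravel())
        assert pen == pytest.approx(delta, rel=1e-9)
        upper_fz = f.reshape(-1, 3)[8:, 2].sum()
        # penalty * depth * unit contact area (both passes combined)
        assert upper_fz == pytest.approx(10.0 * delta * 1.0, rel=0.05)
        lower_fz = f.reshape(-1, 3)[:8, 2].sum()
        assert lower_fz == pytest.approx(-upper_fz, rel=1e-9)

    def test_forces_push_surfaces_apart(self):
        model = self._two_plate_model(gap=0.5)
        u = np.zeros((16, 3))
        u[8:, 2] = -0.55
        f, _, _ = model.contact_force(u.ravel())
        fz = f.reshape(-1, 3)[:, 2]
        assert fz[8:].sum() > 0       # upper pushed up
        assert fz[:8].sum() < 0       # lower pushed down


class TestElementStrains:
    def test_zero_displacement_zero_strain(self, coarse_mesh_10):
        E = element_strains(coarse_mesh_10,
                            np.zeros((coarse_mesh_10.n_nodes, 3)))
        assert np.abs(E).max() < 1e-12

    def test_uniaxial_stretch_green_lagrange(self, coarse_mesh_10):
        u = np.zeros((coarse_mesh_10.n_nodes, 3))
        u[:, 2] = 0.2 * coarse_mesh_10.nodes[:, 2]   # lambda_z = 1.2
        E = element_strains(coarse_mesh_10, u)
        assert E[:, 2].max() == pytest.approx(0.22, rel=1e-9)

    def test_rigid_rotation_gives_zero_strain(self, coarse_mesh_10):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec([0.2, 0.1, -0.4]).as_matrix()
        u = coarse_mesh_10.nodes @ R.T - coarse_mesh_10.nodes
        E = element_strains(coarse_mesh_10, u)
        assert np.abs(E).max() < 1e-9


class TestRingBenchmark:
    def test_small_strain_matches_lame(self):
        fx = make_ring_fixture()
        lib = _uniform_library(fx.meta["material"])
        model = TracheaModel(fx.mesh, lib, contact=False)
        u, ok, _ = newton_solve(model, np.zeros(model.n_free),
                                fx.meta["pressure"], SolverConfig())
        assert ok
        uu = model.expand(u).reshape(-1, 3)
        X = fx.mesh.nodes
        r = np.linalg.norm(X[:, :2], axis=1)
        outer = np.abs(r - fx.meta["outer_radius"]) < 1e-9
        ur = (np.sum(uu[:, :2] * X[:, :2], axis=1) / r)[outer].mean()
        assert ur == pytest.approx(fx.reference, rel=fx.tolerance)

    def test_linearity_of_small_pressure_response(self):
        fx = make_ring_fixture()
        lib = _uniform_library(fx.meta["material"])
        model = TracheaModel(fx.mesh, lib, contact=False)
        cfg = SolverConfig()
        sols = []
        for p in (0.05, 0.10):
            u, ok, _ = newton_solve(model, np.zeros(model.n_free), p, cfg)
            assert ok
            sols.append(model.expand(u))
        ratio = np.linalg.norm(sols[1]) / np.linalg.norm(sols[0])
        assert ratio == pytest.approx(2.0, rel=0.01)
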
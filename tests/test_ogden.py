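"""Constitutive-model tests: energy, stresses, tangents, fitting, malacia."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airwaymech import (OgdenMaterial, OgdenModel, StressStrainCurve,
                        TissueLibrary, apply_malacia, cauchy_stress_tensor,
                        fit_ogden, material_tangent, strain_energy,
                        uniaxial_cauchy_stress)
from airwaymech.ogden import pk1_stress_and_tangent

ALL_TISSUES = [(0.109, 16.63), (0.01, 11.05), (0.08, 6.29), (0.1, 3.4)]


class TestStrainEnergy:
    def test_zero_at_identity(self, mucosa):
        assert strain_energy(mucosa, (1.0, 1.0, 1.0)) == 0.0

    def test_permutation_invariance(self, mucosa):
        lams = (1.3, 0.9, 0.86)
        vals = {round(strain_energy(mucosa, p), 12)
                for p in [(lams[i], lams[j], lams[k])
                          for i, j, k in ((0, 1, 2), (1, 2, 0), (2, 0, 1),
                                          (0, 2, 1), (1, 0, 2), (2, 1, 0))]}
        assert len(vals) == 1

    def test_incompressible_uniaxial_value(self, mucosa):
        # (0.1/3.4)(1.5^3.4 + 2*1.5^-1.7 - 3) evaluated directly
        lam = (1.5, 1.5 ** -0.5, 1.5 ** -0.5)
        assert strain_energy(mucosa, lam) == pytest.approx(0.0580, abs=2e-4)

    def test_rejects_nonpositive_stretch(self, mucosa):
        with pytest.raises(ValueError):
            strain_energy(mucosa, (1.0, -0.2, 1.0))

    @given(st.floats(0.7, 1.4), st.floats(0.7, 1.4), st.floats(0.7, 1.4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_energy_nonnegative_and_zero_only_at_identity(self, l1, l2, l3):
        mat = OgdenMaterial.single(0.1, 3.4)
        w = strain_energy(mat, (l1, l2, l3))
        assert w >= -1e-12
        if max(abs(l1 - 1), abs(l2 - 1), abs(l3 - 1)) > 1e-3:
            assert w > 0


class TestUniaxialStress:
    def test_zero_at_unit_stretch(self, cartilage):
        assert uniaxial_cauchy_stress(cartilage, 1.0) == 0.0

    @pytest.mark.parametrize("a,b,lam,expected", [
        (0.1, 3.4, 1.5, 0.3467),     # mucosa at 50% strain
        (0.109, 16.63, 1.1, 0.4825),  # cartilage at 10% strain
    ])
    def test_closed_form_values(self, a, b, lam, expected):
        mat = OgdenMaterial.single(a, b)
        assert uniaxial_cauchy_stress(mat, lam) == pytest.approx(expected,
                                                                 abs=1e-4)

    def test_mucosa_under_one_mpa_at_fifty_percent(self, mucosa):
        assert uniaxial_cauchy_stress(mucosa, 1.5) < 1.0

    def test_sign_matches_strain_direction(self, mucosa):
        assert uniaxial_cauchy_stress(mucosa, 1.2) > 0
        assert uniaxial_cauchy_stress(mucosa, 0.8) < 0

    @pytest.mark.parametrize("a,b", ALL_TISSUES)
    def test_strictly_increasing_on_physiologic_range(self, a, b):
        lam = np.linspace(0.5, 2.0, 400)
        sig = uniaxial_cauchy_stress(OgdenMaterial.single(a, b), lam)
        assert np.all(np.diff(sig) > 0)

    def test_rejects_nonpositive_stretch(self, mucosa):
        with pytest.raises(ValueError):
            uniaxial_cauchy_stress(mucosa, 0.0)


class TestTensorStress:
    def test_identity_gives_zero(self, mucosa):
        assert np.allclose(cauchy_stress_tensor(mucosa, np.eye(3)), 0.0)

    def test_objectivity_under_rotation(self, mucosa):
        from scipy.spatial.transform import Rotation

        U = np.diag([1.3, 0.95, 0.85])
        R = Rotation.from_rotvec([0.3, -0.5, 0.8]).as_matrix()
        s_U = cauchy_stress_tensor(mucosa, U)
        s_RU = cauchy_stress_tensor(mucosa, R @ U)
        assert np.allclose(s_RU, R @ s_U @ R.T, atol=1e-10)

    def test_near_incompressible_uniaxial_limit(self, mucosa):
        """Lateral-equilibrium uniaxial state reproduces the closed form."""
        from scipy.optimize import brentq

        def lateral_stress(q):
            F = np.diag([1.5, q, q])
            return cauchy_stress_tensor(mucosa, F)[1, 1]

        q = brentq(lateral_stress, 0.5, 1.0, xtol=1e-12)
        s11 = cauchy_stress_tensor(mucosa, np.diag([1.5, q, q]))[0, 0]
        assert s11 == pytest.approx(uniaxial_cauchy_stress(mucosa, 1.5),
                                    rel=0.02)

    def test_rejects_inverted_gradient(self, mucosa):
        with pytest.raises(ValueError):
            cauchy_stress_tensor(mucosa, -np.eye(3))


class TestTangent:
    def test_pk1_tangent_matches_finite_difference(self, mucosa):
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(3):
            F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
            if np.linalg.det(F) < 0.8 or np.linalg.det(F) > 1.2:
                continue
            P, A = pk1_stress_and_tangent(mucosa, F)
            fd = np.zeros((3, 3, 3, 3))
            for k in range(3):
                for l in range(3):
                    dF = np.zeros((3, 3))
                    dF[k, l] = h
                    Pp, _ = pk1_stress_and_tangent(mucosa, F + dF, False)
                    Pm, _ = pk1_stress_and_tangent(mucosa, F - dF, False)
                    fd[:, :, k, l] = (Pp - Pm) / (2 * h)
            assert np.abs(A - fd).max() / np.abs(fd).max() < 1e-4

    def test_cauchy_tangent_predicts_stress_increment(self, mucosa):
        rng = np.random.default_rng(1)
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        C = material_tangent(mucosa, F)
        dF = 1e-6 * rng.standard_normal((3, 3))
        ds_pred = np.einsum('ijkb,kb->ij', C, dF)
        ds = cauchy_stress_tensor(mucosa, F + dF) - cauchy_stress_tensor(mucosa, F)
        assert np.abs(ds_pred - ds).max() / np.abs(ds).max() < 1e-4

    @pytest.mark.parametrize("a,b", ALL_TISSUES)
    def test_positive_shear_stiffness_at_identity(self, a, b):
        mat = OgdenMaterial.single(a, b)
        _, A = pk1_stress_and_tangent(mat, np.eye(3))
        # small-strain shear modulus from the spectral tangent
        assert A[0, 1, 0, 1] == pytest.approx(mat.shear_modulus, rel=1e-6)
        assert A[0, 1, 0, 1] > 0

    def test_minor_symmetry_of_cauchy_tangent(self, mucosa):
        C = material_tangent(mucosa, np.diag([1.2, 0.95, 0.9]))
        assert np.allclose(C, np.swapaxes(C, 0, 1))


class TestFitting:
    @pytest.mark.parametrize("a,b", [(0.109, 16.63), (0.1, 3.4)])
    def test_noise_free_recovery(self, a, b):
        mat = OgdenMaterial.single(a, b)
        eps = np.arange(0, 0.501, 0.01)
        curve = StressStrainCurve(eps, uniaxial_cauchy_stress(mat, 1 + eps))
        res = fit_ogden(curve)
        assert res.converged
        fa, fb = res.material.terms[0]
        assert fa == pytest.approx(a, rel=1e-3)
        assert fb == pytest.approx(b, rel=1e-3)
        assert res.r_squared > 0.99999

    @given(st.floats(0.01, 1.0), st.floats(1.0, 20.0))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_recovery_across_parameter_space(self, a, b):
        mat = OgdenMaterial.single(a, b)
        eps = np.arange(0, 0.501, 0.01)
        curve = StressStrainCurve(eps, uniaxial_cauchy_stress(mat, 1 + eps))
        res = fit_ogden(curve)
        fa, fb = res.material.terms[0]
        assert fa == pytest.approx(a, rel=1e-3)
        assert fb == pytest.approx(b, rel=1e-3)

    def test_noisy_fit_stays_close(self):
        from airwaymech.synthetic import CurveGenSpec, generate_stress_strain

        mat = OgdenMaterial.single(0.109, 16.63, "cartilage")
        curve = generate_stress_strain(CurveGenSpec(
            mat, noise="multiplicative", noise_sd=0.05, seed=42))
        res = fit_ogden(curve)
        fa, fb = res.material.terms[0]
        assert res.r_squared > 0.95
        assert fa == pytest.approx(0.109, rel=0.10)
        assert fb == pytest.approx(16.63, rel=0.10)

    def test_statsmodels_style_interface(self, mucosa):
        import pandas as pd

        eps = np.arange(0, 0.5, 0.02)
        df = pd.DataFrame({"strain": eps,
                           "stress_mpa": uniaxial_cauchy_stress(mucosa, 1 + eps)})
        res = OgdenModel.from_dataframe(df, label="mucosa").fit()
        assert "R^2" in res.summary()
        assert res.material.a == pytest.approx(0.1, rel=1e-3)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            OgdenModel(StressStrainCurve(np.array([0, 0.1, 0.2]),
                                         np.zeros(3)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            OgdenModel(StressStrainCurve(np.array([0, 0.1]),
                                         np.array([0.0, 0.1])))


class TestMalacia:
    def test_soft_replaces_cartilage_with_fibrous(self, library):
        out = apply_malacia(library, "soft")
        assert out["cartilage"].terms == library["fibrous"].terms
        assert out["cartilage"].terms[0] == (0.01, 11.05)
        assert out["fibrous"].terms == library["fibrous"].terms
        assert out["smooth_muscle"].terms == library["smooth_muscle"].terms

    def test_mucosa_replaces_both_anterior_tissues(self, library):
        out = apply_malacia(library, "mucosa")
        assert out["cartilage"].terms[0] == (0.1, 3.4)
        assert out["fibrous"].terms[0] == (0.1, 3.4)
        assert out["mucosa"].terms == library["mucosa"].terms

    def test_posterior_replaces_muscle_only(self, library):
        out = apply_malacia(library, "posterior", posterior_coeffs=(1.0, 1.0))
        assert out["smooth_muscle"].terms[0] == (1.0, 1.0)
        assert out["cartilage"].terms == library["cartilage"].terms

    def test_unknown_severity_rejected(self, library):
        with pytest.raises(ValueError):
            apply_malacia(library, "bogus")


class TestLibraryIO:
    def test_yaml_roundtrip(self, library, tmp_path):
        p = tmp_path / "lib.yaml"
        library.to_yaml(p)
        back = TissueLibrary.from_yaml(p)
        for role in ("cartilage", "fibrous", "smooth_muscle", "mucosa"):
            assert back[role].terms == library[role].terms

    def test_curve_csv_roundtrip(self, mucosa, tmp_path):
        eps = np.arange(0, 0.5, 0.05)
        c = StressStrainCurve(eps, uniaxial_cauchy_stress(mucosa, 1 + eps), "m")
        p = tmp_path / "c.csv"
        c.to_csv(p)
        back = StressStrainCurve.from_csv(p, "m")
        assert np.allclose(back.stress, c.stress)

    def test_material_validation(self):
        with pytest.raises(ValueError):
            OgdenMaterial.single(-1.0, 2.0)
        with pytest.raises(ValueError):
            OgdenMaterial.single(1.0, 0.0)
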
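"""Ogden hyperelasticity for airway tissues.

The trachea's load-bearing tissues (cartilage rings, interposed fibrous
tissue, the posterior trachealis muscle and the mucosal lining) are modelled
as isotropic, nearly incompressible hyperelastic solids with an Ogden strain
energy expressed in principal stretches ``lambda_i``:

    W_iso = sum_k (a_k / b_k) * (lb1**b_k + lb2**b_k + lb3**b_k - 3)

where ``lb_i = J**(-1/3) * lambda_i`` are the volume-preserving (deviatoric)
stretches, ``J = lambda1*lambda2*lambda3``, ``a_k`` carries stress units
(MPa) and ``b_k`` is a dimensionless exponent.  Near-incompressibility is
enforced with a decoupled volumetric penalty ``U(J) = kappa/2 * ln(J)**2``.

Units are mm-MPa-N throughout the package.

The module provides closed-form uniaxial stress (what a tensile test
measures), full tensor stress and consistent tangent via the spectral
(principal-stretch) formulation needed by the finite-element solver, and a
least-squares fitting interface (`OgdenModel`) in the style of statsmodels:
the model is built from a measured stress-strain curve and ``fit()`` returns
an `OgdenFitResults` carrying coefficients, R^2 and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml
from scipy import optimize

__all__ = [
    "OgdenMaterial",
    "StressStrainCurve",
    "TissueLibrary",
    "OgdenModel",
    "OgdenFitResults",
    "strain_energy",
    "uniaxial_cauchy_stress",
    "cauchy_stress_tensor",
    "material_tangent",
    "fit_ogden",
    "apply_malacia",
    "pk1_stress_and_tangent",
    "CMH2O_TO_MPA",
]

#: 1 cm H2O in MPa (98.0665 Pa).
CMH2O_TO_MPA = 98.0665e-6

TISSUE_ROLES = ("cartilage", "fibrous", "smooth_muscle", "mucosa")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OgdenMaterial:
    """An N-term Ogden material (default one term).

    Parameters
    ----------
    terms
        Sequence of ``(a, b)`` coefficient pairs; ``a`` in MPa, ``b``
        dimensionless.  Every ``a`` must be positive and every ``b``
        nonzero.
    bulk_modulus
        Volumetric penalty stiffness ``kappa`` in MPa.  If omitted it
        defaults to ``1000 * sum(a)``, which makes the material effectively
        incompressible relative to its shear response.
    label
        Tissue name used in reports and serialized libraries.
    """

    terms: tuple[tuple[float, float], ...]
    bulk_modulus: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        terms = tuple((float(a), float(b)) for a, b in self.terms)
        if not terms:
            raise ValueError("OgdenMaterial requires at least one (a, b) term")
        for a, b in terms:
            if a <= 0:
                raise ValueError(f"Ogden coefficient a must be > 0, got {a}")
            if b == 0:
                raise ValueError("Ogden exponent b must be nonzero")
        object.__setattr__(self, "terms", terms)
        kappa = float(self.bulk_modulus)
        if kappa <= 0.0:
            kappa = 1000.0 * sum(a for a, _ in terms)
        object.__setattr__(self, "bulk_modulus", kappa)

    @classmethod
    def single(cls, a: float, b: float, label: str = "",
               bulk_modulus: float = 0.0) -> "OgdenMaterial":
        return cls(terms=((a, b),), bulk_modulus=bulk_modulus, label=label)

    @property
    def a(self) -> float:
        """Coefficient ``a`` of the first term (convenience for 1-term)."""
        return self.terms[0][0]

    @property
    def b(self) -> float:
        """Exponent ``b`` of the first term (convenience for 1-term)."""
        return self.terms[0][1]

    @property
    def shear_modulus(self) -> float:
        """Small-strain shear modulus ``mu = sum a_k b_k / 2`` (MPa)."""
        return 0.5 * sum(a * b for a, b in self.terms)


@dataclass
class StressStrainCurve:
    """Uniaxial Cauchy stress (MPa) versus engineering strain.

    Strains are dimensionless, non-negative and strictly increasing; stress
    and strain arrays have equal length.
    """

    strain: np.ndarray
    stress: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress must be equal-length 1-D arrays")
        if self.strain.size and self.strain[0] < 0:
            raise ValueError("strain must start at >= 0")
        if self.strain.size > 1 and not np.all(np.diff(self.strain) > 0):
            raise ValueError("strain must be strictly increasing")
        if not np.all(np.isfinite(self.stress)):
            raise ValueError("stress must be finite")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"strain": self.strain, "stress_mpa": self.stress}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "StressStrainCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["strain"].to_numpy(), df["stress_mpa"].to_numpy(), label)


@dataclass
class TissueLibrary:
    """Mapping from tissue role to its Ogden material.

    All four roles (cartilage, fibrous, smooth_muscle, mucosa) must be
    present; `default` returns the library fit to preterm-lamb tracheal
    tissue plus engineered oral mucosa.
    """

    materials: dict[str, OgdenMaterial]

    def __post_init__(self) -> None:
        missing = [r for r in TISSUE_ROLES if r not in self.materials]
        if missing:
            raise ValueError(f"TissueLibrary missing roles: {missing}")

    def __getitem__(self, role: str) -> OgdenMaterial:
        return self.materials[role]

    @classmethod
    def default(cls) -> "TissueLibrary":
        return cls({
            "cartilage": OgdenMaterial.single(0.109, 16.63, "cartilage"),
            "fibrous": OgdenMaterial.single(0.01, 11.05, "fibrous"),
            "smooth_muscle": OgdenMaterial.single(0.08, 6.29, "smooth_muscle"),
            "mucosa": OgdenMaterial.single(0.1, 3.4, "mucosa"),
        })

    def to_yaml(self, path) -> None:
        doc = {
            role: {"a": m.a, "b": m.b, "kappa": m.bulk_modulus}
            for role, m in self.materials.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TissueLibrary":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls({
            role: OgdenMaterial.single(v["a"], v["b"], role,
                                       bulk_modulus=v.get("kappa", 0.0))
            for role, v in doc.items()
        })


# ---------------------------------------------------------------------------
# energy / stress in principal stretches
# ---------------------------------------------------------------------------

def _check_stretches(lam: np.ndarray) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("principal stretches must be positive")
    return lam


def _iso_derivs(material: OgdenMaterial, lam: np.ndarray):
    """Deviatoric Ogden energy and its first/second stretch derivatives.

    ``lam`` has shape (..., 3).  Returns ``(W, Wi, Wij)`` with shapes
    (...,), (..., 3), (..., 3, 3): derivatives are with respect to the
    *total* stretches, the deviatoric scaling J**(-1/3) being applied
    internally.
    """
    J = lam[..., 0] * lam[..., 1] * lam[..., 2]
    lb = lam * J[..., None] ** (-1.0 / 3.0)
    W = np.zeros(lam.shape[:-1])
    Wi = np.zeros(lam.shape)
    Wij = np.zeros(lam.shape + (3,))
    eye = np.eye(3)
    for a, b in material.terms:
        f = lb ** b                       # (...,3)
        fsum = f.sum(axis=-1)
        W += (a / b) * (fsum - 3.0)
        dev = f - fsum[..., None] / 3.0   # f_j - mean-like deviator
        Wi += a * dev / lam
        # d/dlam_k of [a * dev_j / lam_j]
        inv = 1.0 / lam
        d_f_j = b * np.einsum('...j,jk->...jk', f, eye)  # b f_j delta_jk
        d_f_j = (d_f_j - b * f[..., :, None] / 3.0) * inv[..., None, :]
        d_fsum = b * (f - fsum[..., None] / 3.0) * inv    # (...,k)
        term = (d_f_j - d_fsum[..., None, :] / 3.0) * (a * inv[..., :, None])
        term -= np.einsum('...j,jk->...jk', a * dev * inv * inv, eye)
        Wij += term
    return W, Wi, Wij


def _vol_derivs(kappa: float, lam: np.ndarray):
    """Volumetric penalty U = kappa/2 ln(J)^2 and its stretch derivatives."""
    J = lam[..., 0] * lam[..., 1] * lam[..., 2]
    lnJ = np.log(J)
    U = 0.5 * kappa * lnJ ** 2
    inv = 1.0 / lam
    Ui = kappa * lnJ[..., None] * inv
    Uij = kappa * np.einsum('...j,...k->...jk', inv, inv)
    Uij -= kappa * lnJ[..., None, None] * np.einsum(
        '...j,jk->...jk', inv * inv, np.eye(3))
    return U, Ui, Uij


def strain_energy(material: OgdenMaterial, stretches: Sequence[float]) -> float:
    """Strain energy density (MPa) at the given principal stretches.

    The deviatoric Ogden sum is evaluated on unit-volume-scaled stretches;
    the volumetric penalty ``kappa/2 * ln(J)**2`` is added.  Zero exactly at
    the identity, and invariant under permutation of the stretches.
    """
    lam = _check_stretches(stretches)
    W, _, _ = _iso_derivs(material, lam)
    U, _, _ = _vol_derivs(material.bulk_modulus, lam)
    return float(W + U) if np.isscalar(W + U) or (W + U).ndim == 0 else W + U


def uniaxial_cauchy_stress(material: OgdenMaterial, stretch) -> float | np.ndarray:
    """Incompressible uniaxial Cauchy stress (MPa) at axial stretch lambda.

    Closed form ``sigma = sum_k a_k (lambda**b_k - lambda**(-b_k/2))``,
    obtained by eliminating the lateral stretches ``lambda**(-1/2)`` and the
    indeterminate pressure with the traction-free lateral condition.  Zero
    at lambda = 1; same sign as ``lambda - 1``.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    sigma = sum(a * (lam ** b - lam ** (-b / 2.0)) for a, b in material.terms)
    return float(sigma) if np.isscalar(stretch) or np.ndim(stretch) == 0 else sigma


# ---------------------------------------------------------------------------
# spectral tensor stress and tangent (used by the FE solver)
# ---------------------------------------------------------------------------

def _stretch_derivs(material: OgdenMaterial, lam: np.ndarray,
                    volumetric: bool = True, deviatoric: bool = True):
    Wi = np.zeros(lam.shape)
    Wij = np.zeros(lam.shape + (3,))
    if deviatoric:
        _, a, b = _iso_derivs(material, lam)
        Wi += a
        Wij += b
    if volumetric:
        _, a, b = _vol_derivs(material.bulk_modulus, lam)
        Wi += a
        Wij += b
    return Wi, Wij


def pk1_stress_and_tangent(material: OgdenMaterial, F: np.ndarray,
                           want_tangent: bool = True,
                           volumetric: bool = True,
                           deviatoric: bool = True):
    """First Piola-Kirchhoff stress and first elasticity tensor dP/dF.

    Spectral evaluation on the singular value decomposition
    ``F = sum_i lambda_i n_i (x) N_i``:

        P = sum_i (dW/dlambda_i) n_i (x) N_i

    with the standard principal-stretch tangent built from the second
    derivatives ``d2W/dlambda_i dlambda_j`` plus the two off-diagonal
    coefficient families with ``(lambda_i**2 - lambda_j**2)`` denominators;
    near-coincident stretches are handled with the analytic l'Hopital
    limits, so the tangent stays consistent at and near the identity.

    ``F`` may be batched, shape (..., 3, 3).  Returns ``(P, A)`` with
    shapes (..., 3, 3) and (..., 3, 3, 3, 3); ``A`` is None when
    ``want_tangent`` is False.  The deviatoric/volumetric flags let the
    solver apply selective (mean-dilatation style) integration.

    Raises ``ValueError`` on non-positive ``det F`` (inverted state).
    """
    F = np.asarray(F, dtype=float)
    detF = np.linalg.det(F)
    if np.any(detF <= 0):
        raise ValueError("deformation gradient has non-positive determinant")
    U, s, Vh = np.linalg.svd(F)
    # SVD of F with det F > 0 can still produce det(U) = det(V) = -1;
    # the dyads n_i (x) N_i are insensitive to that joint sign flip.
    lam = s  # (...,3) descending
    Wi, Wij = _stretch_derivs(material, lam, volumetric, deviatoric)

    n = U                       # columns n_i: n[..., :, i]
    N = np.swapaxes(Vh, -1, -2)  # columns N_i
    # dyads M_i = n_i (x) N_i
    M = np.einsum('...ki,...li->...ikl', n, N)  # (...,i,3,3)
    P = np.einsum('...i,...ikl->...kl', Wi, M)
    if not want_tangent:
        return P, None

    # Assemble the tangent in the principal (dyad) basis e_(pq) = n_p (x) N_q
    # as a 9x9 block, then rotate: A = R Ahat R^T with R[(kl),(pq)] =
    # n[k,p] N[l,q].  In that basis only three coefficient families are
    # nonzero: W_ij on the (pp, qq) block, and c1/c2 on the (pq, pq) /
    # (pq, qp) entries for p != q.
    shape = lam.shape[:-1]
    Ahat = np.zeros(shape + (9, 9))
    for p in range(3):
        for q in range(3):
            Ahat[..., 4 * p, 4 * q] = Wij[..., p, q]
    for p in range(3):
        for q in range(3):
            if p == q:
                continue
            lp, lq = lam[..., p], lam[..., q]
            wp, wq = Wi[..., p], Wi[..., q]
            den = lp ** 2 - lq ** 2
            close = np.abs(lp - lq) <= 1e-7 * (lp + lq)
            den_safe = np.where(close, 1.0, den)
            c1 = (wp * lp - wq * lq) / den_safe
            c2 = (wp * lq - wq * lp) / den_safe
            # l'Hopital limits as lambda_q -> lambda_p
            wpp = Wij[..., p, p]
            wpq = Wij[..., p, q]
            c1 = np.where(close, 0.5 * (wpp - wpq) + wp / (lp + lq), c1)
            c2 = np.where(close, 0.5 * (wpp - wpq) - wp / (lp + lq), c2)
            Ahat[..., 3 * p + q, 3 * p + q] = c1
            Ahat[..., 3 * p + q, 3 * q + p] = c2
    R = np.einsum('...kp,...lq->...klpq', n, N).reshape(shape + (9, 9))
    A = (R @ Ahat @ np.swapaxes(R, -1, -2)).reshape(shape + (3, 3, 3, 3))
    return P, A


def cauchy_stress_tensor(material: OgdenMaterial, deformation_gradient) -> np.ndarray:
    """Cauchy stress tensor (MPa) at a deformation gradient F.

    Evaluated spectrally as ``sigma = J**-1 P F^T`` from the first
    Piola-Kirchhoff stress; reduces to `uniaxial_cauchy_stress` in the
    incompressible uniaxial limit as the bulk modulus grows.
    """
    F = np.asarray(deformation_gradient, dtype=float)
    P, _ = pk1_stress_and_tangent(material, F, want_tangent=False)
    J = np.linalg.det(F)
    sigma = np.einsum('...ij,...kj->...ik', P, F) / J[..., None, None] \
        if F.ndim > 2 else P @ F.T / J
    # symmetrize away SVD round-off
    return 0.5 * (sigma + np.swapaxes(sigma, -1, -2))


def material_tangent(material: OgdenMaterial, deformation_gradient) -> np.ndarray:
    """Derivative of the Cauchy stress with respect to F (3x3x3x3).

    Consistent linearization of `cauchy_stress_tensor`:
    ``dsigma_ij = C_ijkB dF_kB``.  Possesses the minor symmetry in (i, j).
    """
    F = np.asarray(deformation_gradient, dtype=float)
    P, A = pk1_stress_and_tangent(material, F)
    J = np.linalg.det(F)
    Finv = np.linalg.inv(F)
    sigma = cauchy_stress_tensor(material, F)
    C = np.einsum('...iakb,...ja->...ijkb', A, F) / J
    C += np.einsum('...ib,jk->...ijkb', P, np.eye(3)) / J
    C -= np.einsum('...ij,...bk->...ijkb', sigma, Finv)
    # enforce the (i,j) minor symmetry lost to round-off
    return 0.5 * (C + np.swapaxes(C, -4, -3))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class OgdenFitResults:
    """Results of fitting an Ogden material to a uniaxial curve."""

    material: OgdenMaterial
    r_squared: float
    residual_norm: float
    converged: bool
    n_obs: int
    label: str = ""

    def summary(self) -> str:
        lines = [
            "Ogden uniaxial fit" + (f" ({self.label})" if self.label else ""),
            "=" * 40,
            f"{'observations':<20}{self.n_obs:>20d}",
            f"{'converged':<20}{str(self.converged):>20}",
            f"{'R^2':<20}{self.r_squared:>20.5f}",
            f"{'residual norm (MPa)':<20}{self.residual_norm:>20.4e}",
            "-" * 40,
        ]
        for k, (a, b) in enumerate(self.material.terms):
            lines.append(f"term {k}:  a = {a:.6g} MPa   b = {b:.6g}")
        return "\n".join(lines)


class OgdenModel:
    """Least-squares Ogden fit to a uniaxial stress-strain curve.

    The residual is defined on Cauchy stress under the incompressible
    uniaxial assumption with ``lambda = 1 + engineering strain``.  The
    objective ``sum (sigma_model - sigma_i)**2`` is minimized over
    ``(log a, log b)`` per term with BFGS from multiple starts
    (b log-spaced, a solved in closed form at each start since the model is
    linear in a), which makes the optimum deterministic and robust to the
    local minima a single unconstrained run can fall into.
    """

    def __init__(self, curve: StressStrainCurve, n_terms: int = 1):
        if np.unique(curve.strain).size < 3:
            raise ValueError("need at least 3 distinct strain points")
        if np.allclose(curve.stress, 0.0):
            raise ValueError("degenerate all-zero stress data")
        self.curve = curve
        self.n_terms = int(n_terms)
        self._lam = 1.0 + curve.strain

    @classmethod
    def from_dataframe(cls, df, strain_col: str = "strain",
                       stress_col: str = "stress_mpa", label: str = "",
                       n_terms: int = 1) -> "OgdenModel":
        curve = StressStrainCurve(df[strain_col].to_numpy(),
                                  df[stress_col].to_numpy(), label)
        return cls(curve, n_terms=n_terms)

    def _predict(self, params: np.ndarray) -> np.ndarray:
        terms = params.reshape(self.n_terms, 2)
        lam = self._lam
        return sum(a * (lam ** b - lam ** (-b / 2.0)) for a, b in terms)

    def _objective(self, x: np.ndarray) -> float:
        params = np.exp(x)
        r = self._predict(params) - self.curve.stress
        return float(r @ r)

    def _best_a_for_b(self, b: float) -> float:
        """Closed-form optimal single-term a at fixed b (linear problem)."""
        lam = self._lam
        g = lam ** b - lam ** (-b / 2.0)
        gg = float(g @ g)
        if gg == 0.0:
            return 1e-3
        return max(float(g @ self.curve.stress) / gg, 1e-8)

    def fit(self, initial_guess: tuple[float, float] | None = None,
            multistart_count: int = 8, seed: int = 0) -> OgdenFitResults:
        """Fit the coefficients; returns an `OgdenFitResults`.

        ``initial_guess`` optionally adds one more start at the given
        (a, b).  ``seed`` controls the small deterministic jitter applied
        to starts beyond the log-spaced b grid.
        """
        rng = np.random.default_rng(seed)
        b_grid = np.geomspace(1.0, 20.0, max(multistart_count, 2))
        starts = []
        for b0 in b_grid:
            jitter = 0.0 if len(starts) < 8 else 0.05 * rng.standard_normal()
            b0 = float(b0 * (1.0 + jitter))
            starts.append((self._best_a_for_b(b0), b0))
        if initial_guess is not None:
            starts.append((max(float(initial_guess[0]), 1e-8),
                           float(initial_guess[1])))

        best = None
        for a0, b0 in starts:
            x0 = np.log(np.tile([a0, b0], self.n_terms))
            try:
                res = optimize.minimize(self._objective, x0, method="BFGS",
                                        options={"maxiter": 500, "gtol": 1e-12})
            except (FloatingPointError, OverflowError):
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError("all optimizer starts failed")

        params = np.exp(best.x)
        terms = tuple((float(a), float(b))
                      for a, b in params.reshape(self.n_terms, 2))
        converged = bool(np.all(np.isfinite(params))) and best.fun < np.inf
        sigma_hat = self._predict(params)
        ss_res = float(np.sum((sigma_hat - self.curve.stress) ** 2))
        ss_tot = float(np.sum((self.curve.stress -
                               self.curve.stress.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        material = OgdenMaterial(terms=terms, label=self.curve.label)
        return OgdenFitResults(material=material, r_squared=r2,
                               residual_norm=np.sqrt(ss_res),
                               converged=converged, n_obs=self.curve.strain.size,
                               label=self.curve.label)


def fit_ogden(curve: StressStrainCurve,
              initial_guess: tuple[float, float] | None = None,
              multistart_count: int = 8, seed: int = 0,
              n_terms: int = 1) -> OgdenFitResults:
    """Functional wrapper around ``OgdenModel(curve).fit(...)``."""
    return OgdenModel(curve, n_terms=n_terms).fit(
        initial_guess=initial_guess, multistart_count=multistart_count,
        seed=seed)


# ---------------------------------------------------------------------------
# malacia transforms
# ---------------------------------------------------------------------------

def apply_malacia(library: TissueLibrary, severity: str,
                  posterior_coeffs: tuple[float, float] | None = None
                  ) -> TissueLibrary:
    """Return a library with malacic property reductions applied.

    severity:
      * ``"soft"``    — cartilage coefficients replaced by fibrous-tissue
        coefficients (cartilage rings degraded to the inter-ring tissue).
      * ``"mucosa"``  — cartilage AND fibrous coefficients replaced by
        mucosa coefficients (most severe anterior-wall reduction).
      * ``"posterior"`` — trachealis smooth-muscle coefficients replaced by
        ``posterior_coeffs`` (e.g. (1, 7) or (1, 1)).

    Non-targeted tissues are unchanged; labels are preserved.
    """
    mats = dict(library.materials)
    if severity == "soft":
        mats["cartilage"] = replace(mats["fibrous"], label="cartilage")
    elif severity == "mucosa":
        mats["cartilage"] = replace(mats["mucosa"], label="cartilage")
        mats["fibrous"] = replace(mats["mucosa"], label="fibrous")
    elif severity == "posterior":
        if posterior_coeffs is None:
            raise ValueError("posterior severity requires (a, b) coefficients")
        a, b = posterior_coeffs
        mats["smooth_muscle"] = OgdenMaterial.single(a, b, "smooth_muscle")
    else:
        raise ValueError(f"unknown malacia severity: {severity!r}")
    return TissueLibrary(mats)
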
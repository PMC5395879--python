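"""Synthetic inputs and benchmark fixtures with independent oracles.

The uniaxial stress-strain source data the tissue coefficients were fit to
is not deposited anywhere, so `generate_stress_strain` emulates it by
sampling the closed-form uniaxial Ogden response of a given material (with
optional seeded noise); refitting the noise-free curves must return the
generating coefficients, closing the loop with `fit_ogden`.

The benchmark fixtures each carry a reference quantity computable without
the finite-element solver:

* single-element uniaxial cube — closed-form Cauchy stress;
* thick-walled ring under small external pressure — Lamé (linear
  elasticity) radial displacement at matched small-strain moduli;
* shallow two-bar von Mises truss — the limit (snap-through) load from a
  dense scan of the analytic 1-DOF equilibrium path, the classic test for
  arc-length continuation and the mechanism proposed for abrupt airway
  collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import HexMesh
from .ogden import OgdenMaterial, StressStrainCurve, uniaxial_cauchy_stress

__all__ = [
    "CurveGenSpec",
    "generate_stress_strain",
    "BenchmarkFixture",
    "make_single_element_fixture",
    "solve_single_element",
    "make_ring_fixture",
    "ring_lame_reference",
    "TrussSystem",
    "make_snapthrough_truss",
    "truss_limit_load_scan",
]


# ---------------------------------------------------------------------------
# stress-strain curve generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveGenSpec:
    """Recipe for a synthetic uniaxial stress-strain curve.

    Default strain grid 0..0.50 in steps of 0.01 (the plotted range of the
    tissue data).  noise: "none", "additive" (sd in MPa) or
    "multiplicative" (sd as a fraction of the stress).
    """

    material: OgdenMaterial
    strain_start: float = 0.0
    strain_stop: float = 0.50
    strain_step: float = 0.01
    noise: str = "none"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (self.strain_stop > self.strain_start >= 0):
            raise ValueError("need stop > start >= 0")
        if self.noise not in ("none", "additive", "multiplicative"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def generate_stress_strain(spec: CurveGenSpec) -> StressStrainCurve:
    """Sample the closed-form uniaxial response, optionally with noise.

    Identical seeds give identical curves; zero sd reproduces the exact
    closed form under any noise model.
    """
    n = int(round((spec.strain_stop - spec.strain_start) / spec.strain_step))
    eps = spec.strain_start + spec.strain_step * np.arange(n + 1)
    sigma = uniaxial_cauchy_stress(spec.material, 1.0 + eps)
    sigma = np.asarray(sigma, dtype=float)
    if spec.noise != "none" and spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        g = rng.standard_normal(sigma.shape)
        if spec.noise == "additive":
            sigma = sigma + spec.noise_sd * g
        else:
            sigma = sigma * (1.0 + spec.noise_sd * g)
    return StressStrainCurve(eps, sigma, spec.material.label)


# ---------------------------------------------------------------------------
# benchmark fixtures
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkFixture:
    """A small validation problem with a solver-independent reference."""

    name: str
    reference: float
    tolerance: float
    mesh: HexMesh | None = None
    system: object | None = None
    meta: dict = field(default_factory=dict)


def _unit_cube_mesh() -> HexMesh:
    nodes = np.array([[x, y, z] for z in (0.0, 1.0) for y in (0.0, 1.0)
                      for x in (0.0, 1.0)], dtype=float)
    # VTK ordering: bottom CCW then top
    elems = np.array([[0, 1, 3, 2, 4, 5, 7, 6]], dtype=np.int64)
    return HexMesh(nodes=nodes, elems=elems, region=np.array(["mucosa"]),
                   node_sets={}, lumen_facets=np.zeros((0, 4), np.int64),
                   mid_loop_nodes=np.zeros(0, np.int64), config=None)


def make_single_element_fixture(material: OgdenMaterial,
                                stretch: float) -> BenchmarkFixture:
    """Unit-cube hexahedron stretched uniaxially along x.

    The x = 0 face is held in x, the x = 1 face is displaced to impose the
    stretch, and single faces are held in y and z so the cube contracts
    laterally as an unconstrained uniaxial specimen.  Reference: the
    closed-form incompressible uniaxial Cauchy stress.
    """
    if stretch <= 0:
        raise ValueError("stretch must be positive")
    mesh = _unit_cube_mesh()
    X = mesh.nodes
    fixed = []
    presc = {}
    for a in range(8):
        if X[a, 0] < 0.5:
            fixed.append(3 * a + 0)
        else:
            fixed.append(3 * a + 0)
            presc[3 * a + 0] = stretch - 1.0
        if X[a, 1] < 0.5:
            fixed.append(3 * a + 1)
        if X[a, 2] < 0.5:
            fixed.append(3 * a + 2)
    mesh.node_sets["fixed_dofs"] = np.array(fixed, dtype=np.int64)
    return BenchmarkFixture(
        name="single_element_uniaxial",
        reference=float(uniaxial_cauchy_stress(material, stretch)),
        tolerance=0.01, mesh=mesh,
        meta={"material": material, "stretch": stretch, "prescribed": presc})


def solve_single_element(fixture: BenchmarkFixture):
    """Solve the cube fixture; returns (cauchy_stress, model, u_full).

    The reported stress is the x-face reaction divided by the deformed
    cross-section area, the quantity the closed form predicts.
    """
    from .fem import TracheaModel
    from .ogden import TissueLibrary
    from .solver import SolverConfig, newton_solve

    mat = fixture.meta["material"]
    lib = TissueLibrary({r: mat for r in
                         ("cartilage", "fibrous", "smooth_muscle", "mucosa")})
    model = TracheaModel(fixture.mesh, lib, contact=False)
    for dof, val in fixture.meta["prescribed"].items():
        model.u_prescribed[dof] = val
    u_free, ok, _ = newton_solve(model, np.zeros(model.n_free), 0.0,
                                 SolverConfig())
    if not ok:
        raise RuntimeError("single-element solve did not converge")
    u = model.expand(u_free)
    f_int, _ = model.internal_force(u, want_tangent=False)
    X = fixture.mesh.nodes
    face = np.nonzero(X[:, 0] > 0.5)[0]
    reaction = float(f_int[3 * face + 0].sum())
    x = X + u.reshape(-1, 3)
    ly = x[:, 1].max() - x[:, 1].min()
    lz = x[:, 2].max() - x[:, 2].min()
    return reaction / (ly * lz), model, u


def make_ring_fixture(diameter: float = 10.0, thickness: float = 1.0,
                      pressure: float = 0.1,
                      material: OgdenMaterial | None = None,
                      n_circ: int = 32, n_r: int = 2) -> BenchmarkFixture:
    """Closed circular ring (plane-strain slice) under external pressure.

    ``diameter`` is the inner diameter (mm), ``pressure`` in cm H2O and
    small enough for strains below 1%.  Reference: outer-surface radial
    displacement from the Lamé thick-walled-cylinder solution at the
    material's small-strain shear and bulk moduli.
    """
    from .ogden import CMH2O_TO_MPA

    material = material or OgdenMaterial.single(0.109, 16.63, "cartilage")
    a = diameter / 2.0
    b = a + thickness
    zs = (0.0, 1.0)
    thetas = np.linspace(0.0, 2 * np.pi, n_circ + 1)[:-1]
    radii = np.linspace(a, b, n_r + 1)
    nid = {}
    nodes = []
    for iz, z in enumerate(zs):
        for ir, r in enumerate(radii):
            for it in range(n_circ):
                nid[(iz, ir, it)] = len(nodes)
                nodes.append((r * np.cos(thetas[it]), r * np.sin(thetas[it]), z))
    nodes = np.array(nodes)
    elems, facets = [], []
    for ir in range(n_r):
        for it in range(n_circ):
            jt = (it + 1) % n_circ
            q = [nid[(0, ir, it)], nid[(0, ir + 1, it)],
                 nid[(0, ir + 1, jt)], nid[(0, ir, jt)]]
            top = [nid[(1, ir, it)], nid[(1, ir + 1, it)],
                   nid[(1, ir + 1, jt)], nid[(1, ir, jt)]]
            elems.append(q + top)
    for it in range(n_circ):
        jt = (it + 1) % n_circ
        # outer surface facet, oriented so the normal points inward
        facets.append([nid[(0, n_r, jt)], nid[(0, n_r, it)],
                       nid[(1, n_r, it)], nid[(1, n_r, jt)]])
    elems = np.array(elems, dtype=np.int64)
    facets = np.array(facets, dtype=np.int64)

    fixed = list(3 * np.arange(len(nodes)) + 2)          # plane strain in z
    # pin the axisymmetric rigid modes: y at theta = 0 and pi, x at pi/2
    for it, comp in ((0, 1), (n_circ // 2, 1), (n_circ // 4, 0)):
        for iz in (0, 1):
            for ir in range(n_r + 1):
                fixed.append(3 * nid[(iz, ir, it)] + comp)
    mesh = HexMesh(nodes=nodes, elems=elems,
                   region=np.array([material.label or "cartilage"] * len(elems)),
                   node_sets={"fixed_dofs": np.array(sorted(set(fixed)),
                                                     dtype=np.int64)},
                   lumen_facets=facets, mid_loop_nodes=np.zeros(0, np.int64),
                   config=None)
    ref = ring_lame_reference(a, b, pressure * CMH2O_TO_MPA, material)
    return BenchmarkFixture(name="ring_external_pressure", reference=ref,
                            tolerance=0.05, mesh=mesh,
                            meta={"material": material, "pressure": pressure,
                                  "inner_radius": a, "outer_radius": b})


def ring_lame_reference(a: float, b: float, p_mpa: float,
                        material: OgdenMaterial) -> float:
    """Outer-radius radial displacement (mm, inward negative) of a
    plane-strain thick-walled cylinder with free inner and pressure p on
    the outer surface, from the Lamé solution at matched small-strain
    moduli (mu from the Ogden terms, bulk modulus = penalty kappa)."""
    mu = material.shear_modulus
    kappa = material.bulk_modulus
    E = 9 * kappa * mu / (3 * kappa + mu)
    nu = (3 * kappa - 2 * mu) / (2 * (3 * kappa + mu))
    A = -p_mpa * b ** 2 / (b ** 2 - a ** 2)
    B = A * a ** 2
    return (1 + nu) / E * ((1 - 2 * nu) * A * b + B / b)


# ---------------------------------------------------------------------------
# shallow two-bar (von Mises) truss
# ---------------------------------------------------------------------------

class TrussSystem:
    """1-DOF von Mises truss: two hyperelastic bars, one free apex.

    Bars of reference length ``L0 = sqrt(half_span**2 + rise**2)`` connect
    pinned supports to an apex that can only move vertically; a downward
    load P is applied there.  The unknown is the apex drop ``delta``; the
    bar law is the incompressible uniaxial Ogden nominal force
    ``N(lambda) = A0 * sigma(lambda) / lambda``.  Exposes the same
    interface as the FE model so the Newton/arc-length drivers run
    unchanged on it.
    """

    def __init__(self, rise: float, half_span: float, area: float,
                 material: OgdenMaterial):
        self.h = float(rise)
        self.w = float(half_span)
        self.A0 = float(area)
        self.material = material
        self.L0 = np.hypot(self.w, self.h)
        self.n_free = 1

    # -- bar law ----------------------------------------------------------
    def _N(self, lam: float) -> float:
        return self.A0 * float(uniaxial_cauchy_stress(self.material, lam)) / lam

    def _dN(self, lam: float) -> float:
        sig = float(uniaxial_cauchy_stress(self.material, lam))
        dsig = sum(a * (b * lam ** (b - 1) + (b / 2.0) * lam ** (-b / 2.0 - 1))
                   for a, b in self.material.terms)
        return self.A0 * (dsig * lam - sig) / lam ** 2

    def equilibrium_load(self, delta: float) -> float:
        """Analytic P(delta): the downward load equilibrating an apex drop.

        For 0 < delta < rise the bars are compressed (N < 0) and push the
        apex up against the load, hence the minus sign.
        """
        y = self.h - delta
        ell = np.hypot(self.w, y)
        lam = ell / self.L0
        return -2.0 * self._N(lam) * y / ell

    # -- solver interface --------------------------------------------------
    def residual(self, u: np.ndarray, lam_load: float) -> np.ndarray:
        return np.array([self.equilibrium_load(float(u[0])) - lam_load])

    def residual_and_tangent(self, u: np.ndarray, lam_load: float):
        d = float(u[0])
        y = self.h - d
        ell = np.hypot(self.w, y)
        lam = ell / self.L0
        s = y / ell
        dr = -2.0 * (self._dN(lam) * (-s) / self.L0 * s +
                     self._N(lam) * (s * s - 1.0) / ell)
        return self.residual(u, lam_load), np.array([[dr]])

    def load_vector(self, u: np.ndarray) -> np.ndarray:
        return np.array([1.0])


def make_snapthrough_truss(rise: float = 1.0, half_span: float = 10.0,
                           axial_stiffness: float = 100.0,
                           material: OgdenMaterial | None = None
                           ) -> BenchmarkFixture:
    """Shallow truss fixture; reference = scanned limit load (N).

    ``axial_stiffness`` is EA in N; the bar area is chosen so the
    material's small-strain uniaxial modulus (3 mu for an incompressible
    Ogden solid) times the area equals it.  Warns (in meta) when the
    geometry is not shallow; the scan oracle stays valid regardless.
    """
    material = material or OgdenMaterial.single(0.1, 3.4, "bar")
    area = axial_stiffness / (3.0 * material.shear_modulus)
    system = TrussSystem(rise, half_span, area, material)
    ref = truss_limit_load_scan(system)
    return BenchmarkFixture(name="snapthrough_truss", reference=ref,
                            tolerance=0.01, system=system,
                            meta={"shallow": rise < 0.3 * half_span,
                                  "material": material, "area": area})


def truss_limit_load_scan(system: TrussSystem, n: int = 200001) -> float:
    """Limit load by dense scan of the analytic path P(delta).

    Pure function of the bar law and geometry — independent of the
    Newton/arc-length machinery it validates.  Returns the first local
    maximum of P on the primary branch.
    """
    deltas = np.linspace(0.0, 2.0 * system.h, n)
    P = np.array([system.equilibrium_load(d) for d in deltas])
    dP = np.diff(P)
    turning = np.nonzero((dP[:-1] > 0) & (dP[1:] <= 0))[0]
    if len(turning) == 0:
        return float(P.max())
    return float(P[turning[0] + 1])
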
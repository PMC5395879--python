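"""Total-Lagrangian hyperelastic finite elements for the trachea model.

Implements 8-node hexahedra with Ogden materials evaluated spectrally
(`airwaymech.ogden`), selective reduced integration of the volumetric
penalty (deviatoric part at the 2x2x2 Gauss points, volumetric part at the
element centroid) to avoid locking at near-incompressibility, a follower
pressure load on the luminal surface with its consistent load stiffness,
and a frictionless node-to-facet penalty treatment of luminal self-contact.

`TracheaModel` bundles a `HexMesh`, a `TissueLibrary` and an optional
`MalaciaSpec` into a nonlinear system exposing ``residual``/``tangent``
for the drivers in `airwaymech.solver`.  The residual is the exact
gradient of the total strain energy (checked by finite differences in the
test-suite), which is what makes Newton and arc-length continuation
reliable through the snap-through events the collapse study targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .geometry import HexMesh, MalaciaSpec, TracheaConfig, select_malacic_elements
from .ogden import (CMH2O_TO_MPA, OgdenMaterial, TissueLibrary,
                    pk1_stress_and_tangent, _iso_derivs, _vol_derivs)

__all__ = [
    "hex_shape_gradients",
    "TracheaModel",
    "element_deformation_gradients",
    "element_strains",
]

# natural coordinates of the VTK hexahedron nodes
_XI = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float)

_G = 1.0 / np.sqrt(3.0)
_GAUSS8 = np.array([[sx * _G, sy * _G, sz * _G]
                    for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)])
_CENTER = np.zeros((1, 3))


def _shape(natural: np.ndarray):
    """Hex8 shape values and natural-coordinate gradients at given points."""
    p = np.atleast_2d(natural)
    one = 1.0 + p[:, None, :] * _XI[None, :, :]          # (q, 8, 3)
    N = 0.125 * one[:, :, 0] * one[:, :, 1] * one[:, :, 2]
    dN = np.empty((p.shape[0], 8, 3))
    dN[:, :, 0] = 0.125 * _XI[None, :, 0] * one[:, :, 1] * one[:, :, 2]
    dN[:, :, 1] = 0.125 * _XI[None, :, 1] * one[:, :, 0] * one[:, :, 2]
    dN[:, :, 2] = 0.125 * _XI[None, :, 2] * one[:, :, 0] * one[:, :, 1]
    return N, dN


_N8, _DN8 = _shape(_GAUSS8)
_NC, _DNC = _shape(_CENTER)


def hex_shape_gradients(nodes: np.ndarray, elems: np.ndarray,
                        scheme: str = "gauss8"):
    """Physical shape-function gradients and weighted Jacobians.

    Returns ``(gradN, wdetJ, detJ)`` with shapes (E, q, 8, 3), (E, q),
    (E, q); ``wdetJ`` already includes the quadrature weights (1 for the
    2x2x2 rule, 8 for the centroid rule).
    """
    dN = _DN8 if scheme == "gauss8" else _DNC
    w = 1.0 if scheme == "gauss8" else 8.0
    X = nodes[elems]                                     # (E, 8, 3)
    J = np.einsum('eaj,qak->eqjk', X, dN)                # dx_j/dxi_k
    detJ = np.linalg.det(J)
    Jinv = np.linalg.inv(J)                              # dxi_k/dx_j
    gradN = np.einsum('qak,eqkj->eqaj', dN, Jinv)
    return gradN, w * detJ, detJ


def element_deformation_gradients(gradN: np.ndarray, u_elem: np.ndarray):
    """F = I + sum_a u_a (x) gradN_a at each quadrature point."""
    F = np.einsum('eai,eqaj->eqij', u_elem, gradN)
    F[..., 0, 0] += 1.0
    F[..., 1, 1] += 1.0
    F[..., 2, 2] += 1.0
    return F


def element_strains(mesh: HexMesh, displacements: np.ndarray) -> np.ndarray:
    """Principal Green-Lagrange strains at element centroids, (E, 3).

    ``E = (F^T F - I)/2``; eigenvalues sorted ascending, so ``[:, 2]`` is
    the maximum principal strain reported as wall strain.  Zero for rigid
    motions (objectivity).
    """
    gradN, _, _ = hex_shape_gradients(mesh.nodes, mesh.elems, "center")
    u = np.asarray(displacements).reshape(mesh.n_nodes, 3)
    F = element_deformation_gradients(gradN, u[mesh.elems])[:, 0]
    C = np.einsum('eki,ekj->eij', F, F)
    E = 0.5 * (C - np.eye(3))
    return np.linalg.eigvalsh(E)


class _InvertedElement(Exception):
    """Raised during assembly when an element inverts; signals a step cut."""


def _element_stiffness(A: np.ndarray, w: np.ndarray, gradN: np.ndarray):
    """K_e[a,i,b,j] = sum_q w_q A[i,A,j,B] gradN[a,A] gradN[b,B].

    Contracted with batched matmuls (BLAS) rather than a six-index einsum;
    the weighted material tensor is folded in first.
    """
    E, q = w.shape
    n = E * q
    Aw = (A * w[..., None, None, None, None]).reshape(n, 3, 3, 3, 3)
    G = gradN.reshape(n, 8, 3)
    # T[(i,A,j), b] = A[i,A,j,B] G[b,B]
    T = Aw.reshape(n, 27, 3) @ G.transpose(0, 2, 1)           # (n, 27, 8)
    # K[a, (i,j,b)] = G[a,A] T[A, (i,j,b)]
    T = T.reshape(n, 3, 3, 3, 8).transpose(0, 2, 1, 3, 4).reshape(n, 3, 72)
    K = G @ T                                                  # (n, 8, 72)
    K = K.reshape(E, q, 8, 3, 3, 8).sum(axis=1)                # (E,8,i,j,b)
    return K.transpose(0, 1, 2, 4, 3)                          # (E,a,i,b,j)


# quad facet shape functions (2x2 Gauss)
_QXI = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
_QGP = np.array([[sx * _G, sy * _G] for sy in (-1, 1) for sx in (-1, 1)])


def _quad_shape(points):
    p = np.atleast_2d(points)
    one = 1.0 + p[:, None, :] * _QXI[None, :, :]
    N = 0.25 * one[:, :, 0] * one[:, :, 1]
    dN = np.empty((p.shape[0], 4, 2))
    dN[:, :, 0] = 0.25 * _QXI[None, :, 0] * one[:, :, 1]
    dN[:, :, 1] = 0.25 * _QXI[None, :, 1] * one[:, :, 0]
    return N, dN


_QN, _QDN = _quad_shape(_QGP)
_QNC, _QDNC = _quad_shape(np.zeros((1, 2)))
_EPS3 = np.zeros((3, 3, 3))
for _i, _j, _k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
    _EPS3[_i, _j, _k] = 1.0
    _EPS3[_i, _k, _j] = -1.0


class TracheaModel:
    """Nonlinear FE system for one trachea (or benchmark) configuration.

    Parameters
    ----------
    mesh
        Hexahedral mesh from `build_trachea_mesh` (or a fixture).
    library
        Tissue library mapping region labels to Ogden materials.
    malacia
        Optional malacic degradation; the affected elements get the
        reduced material per the severity semantics of `apply_malacia`.
    contact
        Enable luminal self-contact (on by default when the mesh carries
        luminal facets).
    contact_penalty
        Penalty stiffness in MPa/mm; default ``100 * max a / mucosa
        thickness``.

    The system works on free degrees of freedom after applying the
    boundary conditions: both end cross-sections held axially (z) and the
    muscle midline held laterally (x), plus the midline end nodes held
    vertically (y) to remove the remaining rigid mode.  The load is the
    luminal follower pressure; ``lam`` below is the pressure in cm H2O.
    """

    def __init__(self, mesh: HexMesh, library: TissueLibrary,
                 malacia: MalaciaSpec | None = None,
                 contact: bool | None = None,
                 contact_penalty: float | None = None,
                 follower: bool = True):
        self.mesh = mesh
        self.library = library
        self.malacia = malacia
        self.follower = follower
        self._setup_materials()
        self._setup_quadrature()
        self._setup_bcs()
        self._setup_pressure()
        if contact is None:
            contact = mesh.lumen_facets is not None and len(mesh.lumen_facets) > 0
        self.contact_enabled = bool(contact)
        if contact_penalty is None:
            amax = max(m.a for m in self.materials)
            t = mesh.config.mucosa_thickness if mesh.config else 0.2
            contact_penalty = 100.0 * amax / t
        self.contact_penalty = float(contact_penalty)
        # C1 smoothing window: pairs engage at this standoff with zero
        # force/stiffness, removing the activation kink Newton chatters on;
        # half the mucosa thickness keeps engagement resolvable by the
        # load-stepping increments
        t_muc = mesh.config.mucosa_thickness if mesh.config else 0.2
        self.contact_smoothing = 0.5 * t_muc
        if self.contact_enabled:
            self._setup_contact()
        self.last_max_penetration = 0.0
        self.last_contact_active = False

    # -- setup -------------------------------------------------------------

    def _setup_materials(self) -> None:
        mesh, lib = self.mesh, self.library
        roles_present = [r for r in ("cartilage", "fibrous",
                                     "smooth_muscle", "mucosa")
                         if r in lib.materials]
        role_index = {r: i for i, r in enumerate(roles_present)}
        mat_of_elem = np.array([role_index[r] for r in mesh.region],
                               dtype=np.int64)
        materials = [lib[r] for r in roles_present]
        if self.malacia is not None and self.malacia.extent:
            from .ogden import apply_malacia

            degraded = apply_malacia(lib, self.malacia.severity,
                                     self.malacia.posterior_coeffs)
            sel = select_malacic_elements(mesh, self.malacia)
            roles = ("cartilage", "fibrous") if self.malacia.target == "anterior" \
                else ("smooth_muscle",)
            for role in roles:
                mat = degraded[role]
                materials.append(mat)
                idx = len(materials) - 1
                mask = np.zeros(mesh.n_elems, dtype=bool)
                mask[sel] = True
                mask &= mesh.region == role
                mat_of_elem[mask] = idx
        self.materials = materials
        self.mat_of_elem = mat_of_elem
        self._mat_groups = [np.nonzero(mat_of_elem == i)[0]
                            for i in range(len(materials))]

    def _setup_quadrature(self) -> None:
        mesh = self.mesh
        self.gradN8, self.w8, _ = hex_shape_gradients(mesh.nodes, mesh.elems)
        self.gradNc, self.wc, _ = hex_shape_gradients(mesh.nodes, mesh.elems,
                                                      "center")
        if np.any(self.w8 <= 0):
            raise ValueError("mesh contains elements with non-positive Jacobian")
        # scatter pattern for element stiffness blocks
        edof = (3 * mesh.elems[:, :, None] + np.arange(3)).reshape(-1, 24)
        self._Krow = np.repeat(edof, 24, axis=1).ravel()
        self._Kcol = np.tile(edof, (1, 24)).ravel()
        self._edof = edof

    def _setup_bcs(self) -> None:
        mesh = self.mesh
        ndof = 3 * mesh.n_nodes
        fixed = np.zeros(ndof, dtype=bool)
        sets = mesh.node_sets
        if "end_z0" in sets:
            fixed[3 * sets["end_z0"] + 2] = True
        if "end_zL" in sets:
            fixed[3 * sets["end_zL"] + 2] = True
        mid = sets.get("muscle_midline")
        if mid is not None and len(mid):
            fixed[3 * mid + 0] = True
            ends = np.concatenate([sets["end_z0"], sets["end_zL"]])
            mid_ends = np.intersect1d(mid, ends)
            fixed[3 * mid_ends + 1] = True
        # benchmark fixtures list explicit DOF indices instead
        extra = sets.get("fixed_dofs")
        if extra is not None:
            fixed[np.asarray(extra, dtype=np.int64)] = True
        self.ndof = ndof
        self.fixed = fixed
        self.free = np.nonzero(~fixed)[0]
        self.u_prescribed = np.zeros(ndof)

    def _setup_pressure(self) -> None:
        facets = self.mesh.lumen_facets
        self._pf = facets if facets is not None else np.zeros((0, 4), np.int64)
        pf = self._pf
        self._pf_dof = (3 * pf[:, :, None] + np.arange(3)).reshape(-1, 12)

    def _setup_contact(self) -> None:
        mesh = self.mesh
        facets = self._pf
        self.slave_nodes = np.unique(facets)
        # tributary reference area and averaged into-lumen normal per node
        X = mesh.nodes
        fx = X[facets]
        # facet reference normals/areas at centers
        dN = _QDNC[0]                      # (4, 2)
        t1 = np.einsum('a,fad->fd', dN[:, 0], fx)
        t2 = np.einsum('a,fad->fd', dN[:, 1], fx)
        nvec = np.cross(t1, t2)
        area = np.linalg.norm(nvec, axis=1) * 4.0   # full-facet weight
        nunit = nvec / np.linalg.norm(nvec, axis=1)[:, None]
        node_area = np.zeros(mesh.n_nodes)
        node_nrm = np.zeros((mesh.n_nodes, 3))
        for a in range(4):
            np.add.at(node_area, facets[:, a], 0.25 * area)
            np.add.at(node_nrm, facets[:, a], nvec)
        nn = np.linalg.norm(node_nrm, axis=1)
        node_nrm[nn > 0] /= nn[nn > 0, None]
        self.slave_area = node_area[self.slave_nodes]
        self.slave_normal = node_nrm[self.slave_nodes]
        # facets adjacent (sharing a node) to each node, for self-exclusion
        from collections import defaultdict

        node_facets = defaultdict(set)
        for fi, f in enumerate(facets):
            for a in f:
                node_facets[a].add(fi)
        excl = {}
        for s in self.slave_nodes:
            near = set(node_facets[s])
            ring = {a for fi in near for a in facets[fi]}
            for a in ring:
                near |= node_facets[a]
            excl[s] = near
        self._contact_excl = excl
        diag = np.linalg.norm(fx[:, 2] - fx[:, 0], axis=1)
        self._contact_radius = float(diag.max()) * 1.5

    # -- assembly ----------------------------------------------------------

    def _group_pk1(self, F8, Fc, want_tangent):
        """Per-material spectral stress/tangent at both quadrature sets."""
        E = self.mesh.n_elems
        P8 = np.zeros_like(F8)
        Pc = np.zeros_like(Fc)
        A8 = np.zeros(F8.shape + (3, 3)) if want_tangent else None
        Ac = np.zeros(Fc.shape + (3, 3)) if want_tangent else None
        for mat, idx in zip(self.materials, self._mat_groups):
            if len(idx) == 0:
                continue
            p, a = pk1_stress_and_tangent(mat, F8[idx], want_tangent,
                                          volumetric=False, deviatoric=True)
            P8[idx] = p
            if want_tangent:
                A8[idx] = a
            p, a = pk1_stress_and_tangent(mat, Fc[idx], want_tangent,
                                          volumetric=True, deviatoric=False)
            Pc[idx] = p
            if want_tangent:
                Ac[idx] = a
        return P8, A8, Pc, Ac

    def internal_force(self, u: np.ndarray, want_tangent: bool = True):
        """Internal nodal force vector (and sparse tangent) at displacement u.

        Raises `_InvertedElement` if any quadrature point has det F <= 0;
        the load-stepping drivers catch this and cut the step.
        """
        mesh = self.mesh
        ue = u.reshape(-1, 3)[mesh.elems]
        F8 = element_deformation_gradients(self.gradN8, ue)
        Fc = element_deformation_gradients(self.gradNc, ue)
        if np.any(np.linalg.det(F8) <= 0) or np.any(np.linalg.det(Fc) <= 0):
            raise _InvertedElement
        P8, A8, Pc, Ac = self._group_pk1(F8, Fc, want_tangent)

        fe = np.einsum('eqij,eq,eqaj->eai', P8, self.w8, self.gradN8)
        fe += np.einsum('eqij,eq,eqaj->eai', Pc, self.wc, self.gradNc)
        f = np.zeros(self.ndof)
        np.add.at(f, self._edof.reshape(-1, 8, 3), fe)

        if not want_tangent:
            return f, None
        Ke = _element_stiffness(A8, self.w8, self.gradN8)
        Ke += _element_stiffness(Ac, self.wc, self.gradNc)
        K = sparse.coo_matrix(
            (Ke.reshape(-1, 24 * 24).ravel(), (self._Krow, self._Kcol)),
            shape=(self.ndof, self.ndof)).tocsr()
        return f, K

    def total_energy(self, u: np.ndarray) -> float:
        """Total strain energy (mJ = N mm); the residual is its gradient."""
        mesh = self.mesh
        ue = u.reshape(-1, 3)[mesh.elems]
        F8 = element_deformation_gradients(self.gradN8, ue)
        Fc = element_deformation_gradients(self.gradNc, ue)
        total = 0.0
        for mat, idx in zip(self.materials, self._mat_groups):
            if len(idx) == 0:
                continue
            lam8 = np.linalg.svd(F8[idx], compute_uv=False)
            W, _, _ = _iso_derivs(mat, lam8)
            total += float((W * self.w8[idx]).sum())
            lamc = np.linalg.svd(Fc[idx], compute_uv=False)
            U, _, _ = _vol_derivs(mat.bulk_modulus, lamc)
            total += float((U * self.wc[idx]).sum())
        return total

    def pressure_force(self, u: np.ndarray, pressure_cmh2o: float,
                       want_tangent: bool = True):
        """Follower pressure load vector (and load stiffness) on the lumen.

        The traction acts along the (deformed, if follower) inward facet
        normal; its magnitude integrates to pressure x luminal area.
        """
        p = pressure_cmh2o * CMH2O_TO_MPA
        if len(self._pf) == 0 or p == 0.0:
            z = np.zeros(self.ndof)
            return (z, None) if want_tangent else (z, None)
        x = self.mesh.nodes.reshape(-1, 3) + \
            (u.reshape(-1, 3) if self.follower else 0.0)
        fx = x[self._pf]                                   # (Fc,4,3)
        t1 = np.einsum('qa,fad->fqd', _QDN[:, :, 0], fx)
        t2 = np.einsum('qa,fad->fqd', _QDN[:, :, 1], fx)
        nvec = np.cross(t1, t2)                            # (Fc,4,3) area-weighted
        fe = p * np.einsum('qa,fqi->fai', _QN, nvec)
        f = np.zeros(self.ndof)
        np.add.at(f, self._pf_dof.reshape(-1, 4, 3), fe)
        if not want_tangent or not self.follower:
            return f, None
        E1 = np.einsum('ijr,fqr->fqij', _EPS3, t2)         # (e_j x t2)_i
        E2 = np.einsum('irj,fqr->fqij', _EPS3, t1)         # (t1 x e_j)_i
        Kp = p * (np.einsum('qa,qb,fqij->faibj', _QN, _QDN[:, :, 0], E1) +
                  np.einsum('qa,qb,fqij->faibj', _QN, _QDN[:, :, 1], E2))
        rows = np.repeat(self._pf_dof, 12, axis=1).ravel()
        cols = np.tile(self._pf_dof, (1, 12)).ravel()
        K = sparse.coo_matrix((Kp.reshape(-1, 144).ravel(), (rows, cols)),
                              shape=(self.ndof, self.ndof)).tocsr()
        return f, K

    # -- contact -----------------------------------------------------------

    def contact_force(self, u: np.ndarray, want_tangent: bool = True):
        """Frictionless node-to-facet penalty forces on the luminal surface.

        Zero when the airway is patent; when a luminal node passes through
        an opposing luminal facet the penalty pushes the surfaces apart
        along the facet normal.  Returns ``(force, stiffness, max_pen)``.
        """
        z = np.zeros(self.ndof)
        if not self.contact_enabled:
            return z, None, 0.0
        x = self.mesh.nodes + u.reshape(-1, 3)
        facets = self._pf
        fx = x[facets]
        dN = _QDNC[0]
        t1 = np.einsum('a,fad->fd', dN[:, 0], fx)
        t2 = np.einsum('a,fad->fd', dN[:, 1], fx)
        nvec = np.cross(t1, t2)
        nn = np.linalg.norm(nvec, axis=1)
        nunit = nvec / nn[:, None]
        centers = fx.mean(axis=1)
        tree = cKDTree(centers)
        xs = x[self.slave_nodes]
        cand = tree.query_ball_point(xs, self._contact_radius)

        rows, cols, vals = [], [], []
        fvec = np.zeros(self.ndof)
        max_pen = 0.0
        k = self.contact_penalty
        eps = self.contact_smoothing
        any_active = False
        for si, (s, flist) in enumerate(zip(self.slave_nodes, cand)):
            if not flist:
                continue
            ns = self.slave_normal[si]
            excl = self._contact_excl[s]
            best = None
            for fi in flist:
                if fi in excl:
                    continue
                if np.dot(ns, nunit[fi]) > -0.05:
                    continue
                d = xs[si] - centers[fi]
                g = float(np.dot(d, nunit[fi]))
                if g >= eps or g < -self._contact_radius:
                    continue
                # in-plane location via the center tangent basis
                a11 = np.dot(t1[fi], t1[fi]); a12 = np.dot(t1[fi], t2[fi])
                a22 = np.dot(t2[fi], t2[fi])
                b1 = np.dot(d, t1[fi]); b2 = np.dot(d, t2[fi])
                det = a11 * a22 - a12 * a12
                if det <= 0:
                    continue
                xi = (a22 * b1 - a12 * b2) / det
                eta = (a11 * b2 - a12 * b1) / det
                if abs(xi) > 1.1 or abs(eta) > 1.1:
                    continue
                if best is None or g > best[0]:   # least-deep valid facet
                    best = (g, fi, xi, eta)
            if best is None:
                continue
            g, fi, xi, eta = best
            any_active = g < 0.0 or any_active
            max_pen = max(max_pen, -g, 0.0)
            n = nunit[fi]
            Nw, _ = _quad_shape(np.array([[np.clip(xi, -1, 1),
                                           np.clip(eta, -1, 1)]]))
            Nw = Nw[0]
            # the search runs both ways across the gap (every luminal node is
            # also a facet node), so each pass carries half the penalty
            A = 0.5 * self.slave_area[si]
            # C1-regularized penalty: quadratic ramp over the smoothing
            # window, then the plain linear law k*A*(-g) for deep overlap
            xi_pen = eps - g            # > 0 inside the activation window
            if xi_pen <= 2.0 * eps:
                fmag = k * A * xi_pen * xi_pen / (4.0 * eps)
                kfac = xi_pen / (2.0 * eps)
            else:
                fmag = k * A * (xi_pen - eps)
                kfac = 1.0
            fvec[3 * s:3 * s + 3] += fmag * n
            for a in range(4):
                fvec[3 * facets[fi, a]:3 * facets[fi, a] + 3] -= fmag * Nw[a] * n
            if want_tangent:
                # constant-normal penalty stiffness k A (n x n) on [s; -N_a]
                nodes = [s] + list(facets[fi])
                wts = [1.0] + [-w for w in Nw]
                nn_blk = kfac * k * A * np.outer(n, n)
                for (na, wa) in zip(nodes, wts):
                    for (nb, wb) in zip(nodes, wts):
                        blk = wa * wb * nn_blk
                        for i in range(3):
                            for j in range(3):
                                rows.append(3 * na + i)
                                cols.append(3 * nb + j)
                                vals.append(blk[i, j])
        K = None
        if want_tangent and vals:
            K = sparse.coo_matrix((vals, (rows, cols)),
                                  shape=(self.ndof, self.ndof)).tocsr()
        self.last_max_penetration = max_pen
        self.last_contact_active = any_active
        return fvec, K, max_pen

    # -- nonlinear-system interface (free DOFs) -----------------------------

    def expand(self, u_free: np.ndarray) -> np.ndarray:
        u = self.u_prescribed.copy()
        u[self.free] = u_free
        return u

    def residual(self, u_free: np.ndarray, pressure_cmh2o: float) -> np.ndarray:
        u = self.expand(u_free)
        f_int, _ = self.internal_force(u, want_tangent=False)
        f_p, _ = self.pressure_force(u, pressure_cmh2o, want_tangent=False)
        r = f_int - f_p
        if self.contact_enabled:
            f_c, _, _ = self.contact_force(u, want_tangent=False)
            r += f_c
        return r[self.free]

    def residual_and_tangent(self, u_free: np.ndarray, pressure_cmh2o: float):
        u = self.expand(u_free)
        f_int, K = self.internal_force(u)
        f_p, Kp = self.pressure_force(u, pressure_cmh2o)
        r = f_int - f_p
        if Kp is not None:
            K = K - Kp
        if self.contact_enabled:
            f_c, Kc, _ = self.contact_force(u)
            r += f_c
            if Kc is not None:
                K = K + Kc
        return r[self.free], K[self.free][:, self.free]

    def load_vector(self, u_free: np.ndarray,
                    reference_pressure: float = 1.0) -> np.ndarray:
        """External load at the reference pressure (for arc-length)."""
        u = self.expand(u_free)
        f_p, _ = self.pressure_force(u, reference_pressure, want_tangent=False)
        return f_p[self.free]

    @property
    def n_free(self) -> int:
        return len(self.free)

    def reference_force_scale(self) -> float:
        """|total force| per cm H2O on the undeformed lumen (N)."""
        from .geometry import lumen_surface_area

        return CMH2O_TO_MPA * lumen_surface_area(self.mesh)
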
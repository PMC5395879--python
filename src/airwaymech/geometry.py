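"""Idealized pediatric trachea geometry and hexahedral meshing.

The model is the classic idealization used for infant airways: a 50 mm long
tube whose anterior wall is a semicircular arc of alternating cartilage
rings (2 mm wide) and fibrous inter-ring tissue (1 mm wide), closed
posteriorly by the flat trachealis muscle, with a thin mucosal layer lining
the semicircular lumen.  Coordinates: z is the airway axis (0..L), y points
toward the anterior apex, and the flat muscle lies below the y = 0 chord
plane.  The lumen is the open semicircle of the quoted diameter; the
anterior wall stacks outward (0.2 mm mucosa, then cartilage/fibrous up to
the total wall thickness), and the bare muscle slab extends downward.

The mesh is structured: a 2-D cross-section (half-annulus patch bonded to a
rectangular slab patch by shared nodes) extruded along z through the
ring/gap band pattern.  A node plane is always inserted at mid-length so
the mid cross-section lumen polygon is directly available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "TracheaConfig",
    "MalaciaSpec",
    "HexMesh",
    "malacic_length",
    "build_trachea_mesh",
    "select_malacic_elements",
    "lumen_surface_area",
    "mid_cross_section_loop",
    "write_vtk",
]


@dataclass(frozen=True)
class TracheaConfig:
    """Geometry and mesh-density parameters (all lengths in mm).

    ``diameter`` is the inner (lumen) semicircular diameter; the study
    covers 6, 8 and 10 mm.  Defaults follow the idealized newborn trachea:
    50 mm length, 2 mm cartilage rings / 1 mm fibrous gaps, 0.8 mm wall
    and muscle thickness, 0.2 mm mucosa.  ``wall_thickness`` is the total
    anterior wall INCLUDING the mucosal lining (the convention of clinical
    wall-thickness measurements): 0.2 mm mucosa + 0.6 mm cartilage or
    fibrous tissue.  The mucosa lines the semicircular lumen only; the
    flat posterior slab is bare trachealis muscle of ``muscle_thickness``.
    """

    diameter: float = 10.0
    length: float = 50.0
    ring_width: float = 2.0
    gap_width: float = 1.0
    wall_thickness: float = 0.8
    mucosa_thickness: float = 0.2
    muscle_thickness: float = 0.8
    n_circ: int = 16           # circumferential divisions over the semicircle
    n_chord: int = 10          # divisions of the open chord (between wall ends)
    n_wall: int = 2            # through-thickness divisions of the hard wall
    n_mucosa: int = 1          # through-thickness divisions of the mucosa
    n_muscle: int = 1          # through-thickness divisions of the muscle
    elems_per_ring: int = 1    # axial elements per cartilage ring band
    elems_per_gap: int = 1     # axial elements per fibrous gap band

    def __post_init__(self):
        for name in ("diameter", "length", "ring_width", "gap_width",
                     "wall_thickness", "mucosa_thickness", "muscle_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_circ", "n_chord", "n_wall", "n_mucosa", "n_muscle",
                     "elems_per_ring", "elems_per_gap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.wall_thickness <= self.mucosa_thickness:
            raise ValueError("wall_thickness is the total anterior wall "
                             "(incl. the mucosa lining) and must exceed "
                             "mucosa_thickness")

    @classmethod
    def coarse(cls, diameter: float = 10.0, **kw) -> "TracheaConfig":
        """Coarse-mesh preset used for sweep and acceptance simulations."""
        kw.setdefault("n_circ", 8)
        kw.setdefault("n_chord", 6)
        kw.setdefault("n_wall", 1)
        return cls(diameter=diameter, **kw)

    @property
    def n_rings(self) -> int:
        """Number of cartilage rings tiling the length (rings at both ends)."""
        pitch = self.ring_width + self.gap_width
        n = (self.length + self.gap_width) / pitch
        n_int = int(round(n))
        if abs(n - n_int) > 1e-9 or n_int < 1:
            raise ValueError(
                f"length {self.length} not decomposable into "
                f"{self.ring_width} mm rings + {self.gap_width} mm gaps")
        return n_int

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: getattr(self, k) for k in self.__dataclass_fields__}, fh)

    @classmethod
    def from_yaml(cls, path) -> "TracheaConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class MalaciaSpec:
    """Which part of the wall is malacic, how severe, and over what extent.

    target "anterior": ``extent`` is an odd ring count (0, 1, 3, 5, 7) and
    severity is "soft" or "mucosa".  target "posterior": ``extent`` is an
    axial length in mm and severity is "posterior" with explicit
    ``posterior_coeffs`` (a, b).  Malacic spans are centered at mid-length.
    """

    target: str = "anterior"            # anterior | posterior
    severity: str = "soft"              # soft | mucosa | posterior
    extent: float = 0                    # ring count (anterior) or mm (posterior)
    posterior_coeffs: tuple[float, float] | None = None

    def __post_init__(self):
        if self.target not in ("anterior", "posterior"):
            raise ValueError(f"unknown malacia target {self.target!r}")
        if self.target == "anterior":
            n = int(self.extent)
            if n != self.extent or n < 0 or (n > 0 and n % 2 == 0):
                raise ValueError("anterior extent must be an odd ring count or 0")
            if self.severity not in ("soft", "mucosa"):
                raise ValueError("anterior severity must be 'soft' or 'mucosa'")
        else:
            if self.extent < 0:
                raise ValueError("posterior extent must be >= 0 mm")
            if self.posterior_coeffs is None:
                raise ValueError("posterior malacia requires (a, b) coefficients")


def malacic_length(n_rings: int, ring_width: float, gap_width: float) -> float:
    """Axial span (mm) of an n-ring malacic segment including interior gaps.

    ``n * ring_width + max(n - 1, 0) * gap_width`` — e.g. a 7-ring segment
    with 2 mm rings and 1 mm gaps spans 20 mm.
    """
    n = int(n_rings)
    if n != n_rings or n < 0:
        raise ValueError("ring count must be a non-negative integer")
    return n * ring_width + max(n - 1, 0) * gap_width


@dataclass
class HexMesh:
    """8-node hexahedral mesh with tissue labels and named sets.

    nodes: (N, 3) coordinates in mm.  elems: (E, 8) connectivity in the
    usual VTK hexahedron ordering (bottom quad counterclockwise, then top).
    region: length-E array of tissue labels.  node_sets include
    ``end_z0``, ``end_zL``, ``muscle_midline``.  lumen_facets: (F, 4)
    quad facets on the luminal surface, oriented so the right-hand-rule
    normal points into the lumen.  mid_loop_nodes: node ids at z = L/2 on
    the lumen surface, ordered into a simple polygon (chord then arc).
    """

    nodes: np.ndarray
    elems: np.ndarray
    region: np.ndarray
    node_sets: dict[str, np.ndarray]
    lumen_facets: np.ndarray
    mid_loop_nodes: np.ndarray
    config: TracheaConfig | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elems].mean(axis=1)

    def element_volumes(self) -> np.ndarray:
        """Exact volumes by 2x2x2 Gauss integration of the Jacobian."""
        from .fem import hex_shape_gradients

        _, detJ, _ = hex_shape_gradients(self.nodes, self.elems)
        return detJ.sum(axis=1)


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def _z_grid(cfg: TracheaConfig):
    """Axial node planes and per-interval band labels; mid-plane inserted."""
    zs = [0.0]
    labels = []
    z = 0.0
    for i in range(cfg.n_rings):
        for k in range(cfg.elems_per_ring):
            z += cfg.ring_width / cfg.elems_per_ring
            zs.append(z)
            labels.append("cartilage")
        if i < cfg.n_rings - 1:
            for k in range(cfg.elems_per_gap):
                z += cfg.gap_width / cfg.elems_per_gap
                zs.append(z)
                labels.append("fibrous")
    zs = np.array(zs)
    if abs(zs[-1] - cfg.length) > 1e-9:
        raise ValueError("band pattern does not tile the length")
    zmid = cfg.length / 2.0
    if not np.any(np.isclose(zs, zmid, atol=1e-9)):
        idx = int(np.searchsorted(zs, zmid))
        zs = np.insert(zs, idx, zmid)
        labels.insert(idx - 1, labels[idx - 1])
    return zs, labels


def build_trachea_mesh(config: TracheaConfig) -> HexMesh:
    """Build the idealized trachea hexahedral mesh.

    The cross-section is a half-annulus (inner radius D/2; mucosa then
    cartilage/fibrous layers) bonded at its two y = 0 end faces to a flat
    trachealis-muscle slab spanning the full outer width.  The
    section is extruded through the cartilage/fibrous band pattern; the
    default 50 mm length yields 17 rings and 16 gaps.
    """
    cfg = config
    R = cfg.diameter / 2.0
    t_m, t_w, t_s = cfg.mucosa_thickness, cfg.wall_thickness, cfg.muscle_thickness

    # --- 2-D cross-section: nodes keyed for deduplication -----------------
    key_of = {}
    pts2d = []

    def node2d(x, y):
        key = (round(float(x), 9), round(float(y), 9))
        if key not in key_of:
            key_of[key] = len(pts2d)
            pts2d.append((key[0], key[1]))
        return key_of[key]

    # radial node positions of the annulus (lumen outward); the structural
    # cartilage/fibrous band occupies the wall thickness beyond the mucosa
    t_hard = t_w - t_m
    radii = [R + t_m * j / cfg.n_mucosa for j in range(cfg.n_mucosa + 1)]
    radii += [R + t_m + t_hard * j / cfg.n_wall
              for j in range(1, cfg.n_wall + 1)]
    radii = np.array(radii)
    thetas = np.linspace(0.0, np.pi, cfg.n_circ + 1)

    quads = []      # (4 node ids CCW, patch, layer_index)
    for j in range(len(radii) - 1):
        layer = "mucosa" if j < cfg.n_mucosa else "wall"
        for k in range(cfg.n_circ):
            t0, t1 = thetas[k], thetas[k + 1]
            r0, r1 = radii[j], radii[j + 1]
            q = (node2d(r0 * np.cos(t0), r0 * np.sin(t0)),
                 node2d(r1 * np.cos(t0), r1 * np.sin(t0)),
                 node2d(r1 * np.cos(t1), r1 * np.sin(t1)),
                 node2d(r0 * np.cos(t1), r0 * np.sin(t1)))
            quads.append((q, "annulus", layer))

    # slab x-grid: interior chord plus the mirrored annulus radial stations
    xg = sorted(set(
        [round(float(x), 9) for x in np.linspace(-R, R, cfg.n_chord + 1)]
        + [round(float(r), 9) for r in radii]
        + [round(float(-r), 9) for r in radii]))
    yg = [-t_s * j / cfg.n_muscle for j in range(cfg.n_muscle + 1)]
    for j in range(len(yg) - 1):
        layer = "muscle"
        y_hi, y_lo = yg[j], yg[j + 1]
        for i in range(len(xg) - 1):
            q = (node2d(xg[i], y_lo), node2d(xg[i + 1], y_lo),
                 node2d(xg[i + 1], y_hi), node2d(xg[i], y_hi))
            quads.append((q, "slab", layer))

    pts2d = np.array(pts2d)
    n2d = len(pts2d)

    # --- extrude along z ---------------------------------------------------
    zs, band = _z_grid(cfg)
    nz = len(zs)
    nodes = np.empty((n2d * nz, 3))
    for iz, z in enumerate(zs):
        nodes[iz * n2d:(iz + 1) * n2d, :2] = pts2d
        nodes[iz * n2d:(iz + 1) * n2d, 2] = z

    elems, region = [], []
    for iz in range(nz - 1):
        lo, hi = iz * n2d, (iz + 1) * n2d
        for q, patch, layer in quads:
            elems.append([lo + q[0], lo + q[1], lo + q[2], lo + q[3],
                          hi + q[0], hi + q[1], hi + q[2], hi + q[3]])
            if layer == "mucosa":
                region.append("mucosa")
            elif layer == "muscle":
                region.append("smooth_muscle")
            else:
                region.append(band[iz])
    elems = np.array(elems, dtype=np.int64)
    region = np.array(region)

    # --- named node sets ---------------------------------------------------
    slab_ids2d = np.array(sorted({i for q, p, _ in quads if p == "slab"
                                  for i in q}))
    midline2d = slab_ids2d[np.abs(pts2d[slab_ids2d, 0]) < 1e-8]
    node_sets = {
        "end_z0": np.arange(n2d),
        "end_zL": np.arange(n2d) + (nz - 1) * n2d,
        "muscle_midline": np.concatenate(
            [midline2d + iz * n2d for iz in range(nz)]),
    }

    # --- luminal surface facets (normals into the lumen) -------------------
    arc_edges = []   # inner annulus edges at r = R, theta increasing
    for k in range(cfg.n_circ):
        t0, t1 = thetas[k], thetas[k + 1]
        arc_edges.append((key_of[(round(R * np.cos(t0), 9), round(R * np.sin(t0), 9))],
                          key_of[(round(R * np.cos(t1), 9), round(R * np.sin(t1), 9))]))
    chord_x = [x for x in xg if -R - 1e-9 <= x <= R + 1e-9]
    chord_edges = [(key_of[(chord_x[i], 0.0)], key_of[(chord_x[i + 1], 0.0)])
                   for i in range(len(chord_x) - 1)]

    facets = []
    for iz in range(nz - 1):
        lo, hi = iz * n2d, (iz + 1) * n2d
        for p0, p1 in arc_edges:
            # reversed so the normal points toward the axis (into the lumen)
            facets.append([lo + p1, lo + p0, hi + p0, hi + p1])
        for p0, p1 in chord_edges:
            # reversed so the normal points up (+y, into the lumen)
            facets.append([lo + p1, lo + p0, hi + p0, hi + p1])
    lumen_facets = np.array(facets, dtype=np.int64)

    # --- ordered mid-plane lumen loop --------------------------------------
    iz_mid = int(np.argmin(np.abs(zs - cfg.length / 2.0)))
    if abs(zs[iz_mid] - cfg.length / 2.0) > 1e-9:
        raise RuntimeError("mid-plane node ring missing")
    off = iz_mid * n2d
    chord_ids = [key_of[(x, 0.0)] for x in chord_x]          # x = -R .. R
    arc_ids = [key_of[(round(R * np.cos(t), 9), round(R * np.sin(t), 9))]
               for t in thetas]                               # theta = 0 .. pi
    loop = chord_ids[:-1] + arc_ids[:-1]   # ends coincide with starts
    mid_loop = np.array([off + i for i in loop], dtype=np.int64)

    mesh = HexMesh(nodes=nodes, elems=elems, region=region,
                   node_sets=node_sets, lumen_facets=lumen_facets,
                   mid_loop_nodes=mid_loop, config=cfg)
    _check_jacobians(mesh)
    return mesh


def _check_jacobians(mesh: HexMesh) -> None:
    from .fem import hex_shape_gradients

    _, detJ, _ = hex_shape_gradients(mesh.nodes, mesh.elems)
    if np.any(detJ <= 0):
        raise ValueError("mesh contains degenerate elements (detJ <= 0)")


# ---------------------------------------------------------------------------
# malacic selection and lumen measurement
# ---------------------------------------------------------------------------

def select_malacic_elements(mesh: HexMesh, spec: MalaciaSpec) -> np.ndarray:
    """Element ids whose properties the malacia spec degrades.

    Anterior: the n centermost cartilage rings plus the fibrous gaps
    interposed within the span.  Posterior: muscle elements whose axial
    centroid lies in the centered span.  Empty iff extent is 0.
    """
    cfg = mesh.config
    if cfg is None:
        raise ValueError("mesh has no geometry config attached")
    L = cfg.length
    if spec.target == "anterior":
        span = malacic_length(int(spec.extent), cfg.ring_width, cfg.gap_width)
        targets = ("cartilage", "fibrous")
    else:
        span = float(spec.extent)
        targets = ("smooth_muscle",)
    if span > L + 1e-9:
        raise ValueError("malacic extent exceeds mesh length")
    if span <= 0:
        return np.array([], dtype=np.int64)
    z0, z1 = (L - span) / 2.0, (L + span) / 2.0
    zc = mesh.element_centroids()[:, 2]
    in_span = (zc > z0 - 1e-9) & (zc < z1 + 1e-9)
    in_region = np.isin(mesh.region, targets)
    return np.nonzero(in_span & in_region)[0]


def _facet_areas(coords: np.ndarray) -> np.ndarray:
    """Areas of bilinear quad facets, coords (..., 4, 3), by triangulation."""
    a, b, c, d = (coords[..., i, :] for i in range(4))
    t1 = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=-1)
    t2 = 0.5 * np.linalg.norm(np.cross(c - a, d - a), axis=-1)
    return t1 + t2


def lumen_surface_area(mesh: HexMesh, displacements: np.ndarray | None = None) -> float:
    """Total luminal surface area (mm^2), optionally in a deformed state.

    For the intact semicircular lumen this approaches
    ``pi * (D/2) * L + D * L`` with circumferential refinement.
    """
    x = mesh.nodes if displacements is None else mesh.nodes + displacements
    return float(_facet_areas(x[mesh.lumen_facets]).sum())


def mid_cross_section_loop(mesh: HexMesh,
                           displacements: np.ndarray | None = None) -> np.ndarray:
    """Deformed mid-length lumen polygon, (n, 2) array in the x-y plane.

    Vertices are the luminal nodes at z = L/2 in boundary order (posterior
    chord left to right, then the anterior arc back); with zero
    displacement the polygon approximates the semicircle-plus-chord lumen.
    """
    x = mesh.nodes if displacements is None else mesh.nodes + displacements
    return x[mesh.mid_loop_nodes][:, :2].copy()


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

_REGION_IDS = {"cartilage": 1, "fibrous": 2, "smooth_muscle": 3, "mucosa": 4}


def write_vtk(mesh: HexMesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write the mesh as legacy ASCII VTK (hexahedral unstructured grid).

    The tissue region is always written as an integer cell field; extra
    point fields (e.g. displacement) and cell fields (e.g. strain) may be
    passed as dicts of arrays.
    """
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nairwaymech mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.9g")
        fh.write(f"CELLS {mesh.n_elems} {mesh.n_elems * 9}\n")
        cells = np.hstack([np.full((mesh.n_elems, 1), 8, dtype=np.int64),
                           mesh.elems])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {mesh.n_elems}\n")
        np.savetxt(fh, np.full(mesh.n_elems, 12, dtype=np.int64), fmt="%d")

        fh.write(f"CELL_DATA {mesh.n_elems}\n")
        fh.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        ids = np.array([_REGION_IDS.get(r, 0) for r in mesh.region])
        np.savetxt(fh, ids, fmt="%d")
        for name, arr in (cell_data or {}).items():
            arr = np.asarray(arr)
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.reshape(mesh.n_elems, -1)[:, 0], fmt="%.9g")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr).reshape(mesh.n_nodes, -1)
                if arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.9g")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr[:, 0], fmt="%.9g")
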
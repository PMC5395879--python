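"""Collapse quantification: lumen area ratios, instability onset, sweeps.

The collapse severity metric is the lumen area ratio — the deformed
mid-length internal airway area divided by the intact undeformed area —
tracked against exhalation pressure and its equivalent total airway force
(pressure x undeformed luminal surface area).  Snap-through onset is
flagged when the area reduction at a step exceeds what a linear extension
through the two previous (force, ratio) points predicts by more than a
threshold; runs that die under load control before the full pressure
program are themselves collapse indicators and are marked as onset at
their final step.

`run_sweep` drives the diameter x severity x malacic-extent grids for the
anterior (cartilage/fibrous weakening) and posterior (trachealis
weakening) studies and tabulates curve, onset and wall-strain summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.validation import make_valid

from .fem import TracheaModel, element_strains
from .geometry import (HexMesh, MalaciaSpec, TracheaConfig, build_trachea_mesh,
                       lumen_surface_area, mid_cross_section_loop)
from .ogden import CMH2O_TO_MPA, TissueLibrary
from .solver import (LoadProgram, SimulationResult, SolverConfig,
                     arc_length_trace, run_load_program)

logger = logging.getLogger("airwaymech")

__all__ = [
    "CollapseCurve",
    "InstabilityReport",
    "SweepResult",
    "polygon_area",
    "area_ratio_curve",
    "pressure_to_force",
    "detect_instability",
    "max_wall_strain",
    "run_sweep",
    "simulate_trachea",
    "collapsed_equilibrium_at_force",
    "trace_snap_through",
]


@dataclass
class CollapseCurve:
    """(pressure, total force, lumen area ratio) samples for one model."""

    pressure: np.ndarray          # cm H2O
    force: np.ndarray             # N
    area_ratio: np.ndarray        # dimensionless, 1 at zero load
    diameter: float | None = None
    severity: str | None = None
    extent: float | None = None
    termination: str = "completed"

    def __len__(self) -> int:
        return len(self.pressure)


@dataclass
class InstabilityReport:
    """Snap-through onset per the linear-extension criterion."""

    onset: bool
    onset_index: int | None = None
    onset_pressure: float | None = None
    onset_force: float | None = None
    deviation: float | None = None
    assessed: bool = True


def polygon_area(polygon: np.ndarray) -> float:
    """Absolute area (mm^2) of an ordered planar polygon (shoelace).

    Orientation-independent.  A self-intersecting loop (possible after
    wall contact) is repaired and the largest simple sub-loop is measured,
    with a warning — the analogue of outlining the remaining open lumen.
    """
    pts = np.asarray(polygon, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("polygon needs >= 3 planar vertices")
    poly = Polygon(pts)
    if poly.is_valid:
        return float(poly.area)
    warnings.warn("self-intersecting lumen polygon; measuring the largest "
                  "simple sub-loop", stacklevel=2)
    fixed = make_valid(poly)
    geoms = getattr(fixed, "geoms", [fixed])
    areas = [g.area for g in geoms if g.geom_type == "Polygon"]
    return float(max(areas)) if areas else 0.0


def pressure_to_force(pressure_cmh2o: float, lumen_area_mm2: float) -> float:
    """Total airway force (N) equivalent to a pressure on a luminal area.

    ``force = pressure x 98.0665 Pa/cmH2O x area``; exactly linear in
    both arguments.  The conversion uses the undeformed luminal area, so
    it is a per-model constant (larger airways see more force at the same
    pressure).
    """
    if pressure_cmh2o < 0 or lumen_area_mm2 < 0:
        raise ValueError("inputs must be non-negative")
    return pressure_cmh2o * CMH2O_TO_MPA * lumen_area_mm2


def area_ratio_curve(result: SimulationResult, mesh: HexMesh,
                     reference_area: float | None = None,
                     diameter: float | None = None,
                     severity: str | None = None,
                     extent: float | None = None) -> CollapseCurve:
    """Lumen area-ratio curve from a simulation's output states.

    Areas are calibrated to the intact undeformed lumen (the zero-pressure
    mid-section polygon of the same mesh unless ``reference_area`` is
    given), so the first ratio is exactly 1.
    """
    if not result.states:
        raise ValueError("simulation result has no states")
    if reference_area is None:
        reference_area = polygon_area(mid_cross_section_loop(mesh))
    area0 = lumen_surface_area(mesh)
    p, f, r = [], [], []
    for st in result.states:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = polygon_area(mid_cross_section_loop(mesh, st.displacements))
        p.append(st.pressure)
        f.append(pressure_to_force(st.pressure, area0))
        r.append(a / reference_area)
    if result.states[0].pressure == 0.0:
        r[0] = 1.0   # calibration identity
    cfg = mesh.config
    return CollapseCurve(np.array(p), np.array(f), np.array(r),
                         diameter=diameter or (cfg.diameter if cfg else None),
                         severity=severity, extent=extent,
                         termination=result.termination)


def detect_instability(curve: CollapseCurve, threshold: float = 0.05
                       ) -> InstabilityReport:
    """Flag snap-through onset on a collapse curve.

    At step i >= 2 the expected ratio is the linear extrapolation through
    the two previous (force, ratio) points; onset is the first step whose
    measured ratio falls short of that prediction by more than
    ``threshold`` (area-ratio units).  A run terminated by load-control
    non-convergence with no flagged step reports onset at its final step.
    Never fires on exactly affine curves, whatever their slope.
    """
    n = len(curve)
    if n < 3:
        if curve.termination == "non_convergence_collapse" and n >= 1:
            return InstabilityReport(True, n - 1, float(curve.pressure[-1]),
                                     float(curve.force[-1]), None)
        return InstabilityReport(False, assessed=False)
    F, r = curve.force, curve.area_ratio
    for i in range(2, n):
        dF = F[i - 1] - F[i - 2]
        slope = (r[i - 1] - r[i - 2]) / dF if dF != 0 else 0.0
        predicted = r[i - 1] + slope * (F[i] - F[i - 1])
        dev = predicted - r[i]
        if dev > threshold:
            return InstabilityReport(True, i, float(curve.pressure[i]),
                                     float(F[i]), float(dev))
    if curve.termination == "non_convergence_collapse":
        return InstabilityReport(True, n - 1, float(curve.pressure[-1]),
                                 float(F[-1]), None)
    return InstabilityReport(False)


def max_wall_strain(result: SimulationResult, at_force: float,
                    mesh: HexMesh) -> float:
    """Maximum wall strain at (or interpolated to) a total airway force.

    Wall strain is the per-element maximum principal Green-Lagrange
    strain; the curve of per-state maxima is interpolated linearly in
    force between the bracketing output states.
    """
    area0 = lumen_surface_area(mesh)
    forces = np.array([pressure_to_force(s.pressure, area0)
                       for s in result.states])
    if at_force < 0 or at_force > forces.max() + 1e-9:
        raise ValueError(f"requested force {at_force} N outside achieved "
                         f"range [0, {forces.max():.3f}]")
    maxima = np.array([element_strains(mesh, s.displacements)[:, 2].max()
                       for s in result.states])
    order = np.argsort(forces)
    return float(np.interp(at_force, forces[order], maxima[order]))


# ---------------------------------------------------------------------------
# simulation orchestration
# ---------------------------------------------------------------------------

def simulate_trachea(config: TracheaConfig, library: TissueLibrary | None = None,
                     malacia: MalaciaSpec | None = None,
                     program: LoadProgram | None = None,
                     solver: SolverConfig | None = None,
                     mesh: HexMesh | None = None):
    """Build (or reuse) the mesh and run one collapse simulation.

    Returns ``(result, mesh)``; continuation mode comes from the solver
    config (``load_control`` marches the pressure program and reports
    non-convergence collapse at limit points; ``arc_length`` traverses
    them).
    """
    library = library or TissueLibrary.default()
    program = program or LoadProgram()
    solver = solver or SolverConfig()
    mesh = mesh if mesh is not None else build_trachea_mesh(config)
    model = TracheaModel(mesh, library, malacia=malacia,
                         follower=program.follower)
    if solver.continuation == "arc_length":
        result = arc_length_trace(model, solver, lam_max=program.max_pressure)
    else:
        result = run_load_program(model, program, solver)
    return result, mesh


def collapsed_equilibrium_at_force(config: TracheaConfig, malacia: MalaciaSpec,
                                   target_force: float,
                                   library: TissueLibrary | None = None,
                                   solver: SolverConfig | None = None,
                                   mesh: HexMesh | None = None,
                                   settle_margins=(1.06, 1.2),
                                   settle_outer: int = 20):
    """Post-collapse equilibrium at a fixed total airway force.

    Marches load control until the snap-through limit point kills it,
    loads a few percent beyond that pressure and rides the collapse onto
    the contact-stabilized branch by damped (viscous) settling — the
    pseudo-dynamic analogue of the physical snap, where each regularized
    step is well-posed even while the static problem has no nearby
    solution — and finally walks the collapsed branch statically back to
    the pressure equivalent of ``target_force``.

    Returns ``(state, mesh, found)``: ``found`` is True when a verified
    static equilibrium at the target pressure on the collapsed branch was
    reached; otherwise ``state`` is the deepest state obtained (the last
    pre-collapse state if the model never snaps below ``max_pressure``).
    """
    from .solver import DeformedState, newton_solve, viscous_settle

    library = library or TissueLibrary.default()
    solver = solver or SolverConfig()
    mesh = mesh if mesh is not None else build_trachea_mesh(config)
    model = TracheaModel(mesh, library, malacia=malacia, follower=True)
    area0 = lumen_surface_area(mesh)
    p_target = target_force / (CMH2O_TO_MPA * area0)

    probe = run_load_program(model, LoadProgram(max_pressure=40.0,
                                                output_interval=4.0),
                             solver, record_final=True)
    last = probe.states[-1]
    if probe.termination != "non_convergence_collapse":
        # no limit point up to the full program: no collapsed branch to
        # settle onto; report the primary-branch state at the target
        near = min(probe.states, key=lambda s: abs(s.pressure - p_target))
        uf, ok, _ = newton_solve(model, near.displacements.ravel()[model.free],
                                 p_target, solver)
        if ok:
            last = DeformedState(pressure=p_target,
                                 displacements=model.expand(uf).reshape(-1, 3),
                                 contact_active=model.last_contact_active)
        else:
            last = near
        return last, mesh, False

    p_fold = last.pressure
    u = last.displacements.ravel()[model.free]
    # damped settling benefits from capped Newton steps; the load-control
    # probe above runs faster without them
    import dataclasses

    settle_cfg = dataclasses.replace(solver, max_newton=40,
                                     max_newton_step=0.5)
    settled = False
    for margin in settle_margins:
        p_settle = max(p_target, p_fold * margin)
        u_try, ok = viscous_settle(model, u, p_settle, settle_cfg,
                                   max_outer=settle_outer)
        if ok:
            u, settled = u_try, True
            break
    if not settled:
        return last, mesh, False

    # walk the collapsed branch statically to the target pressure
    p = p_settle
    dp = (p_target - p) / 4.0
    guard = 0
    while abs(p - p_target) > 1e-9 and guard < 60:
        guard += 1
        p_next = p_target if abs(dp) >= abs(p_target - p) else p + dp
        u_try, ok, _ = newton_solve(model, u, p_next, solver)
        if ok:
            u, p = u_try, p_next
        else:
            dp *= 0.5
            if abs(dp) < 1e-4:
                break
    found = abs(p - p_target) <= 1e-9
    state = DeformedState(pressure=p,
                          displacements=model.expand(u).reshape(-1, 3),
                          contact_active=model.last_contact_active)
    return state, mesh, found


def trace_snap_through(config: TracheaConfig, malacia: MalaciaSpec,
                       target_force: float,
                       library: TissueLibrary | None = None,
                       solver: SolverConfig | None = None,
                       lam_cap: float = 60.0,
                       max_steps: int = 500,
                       mesh: HexMesh | None = None):
    """Arc-length trace through snap-through to a post-collapse force level.

    Follows the equilibrium path past the limit point (where the pressure
    peaks), down the collapsing branch and through wall contact, stopping
    at the first state on the re-stabilized (load rising again) branch
    whose total airway force is at least ``target_force`` N — the state at
    which post-collapse wall strain is reported.  Returns
    ``(result, mesh, stop_index)`` where ``stop_index`` is the index of
    that state, or None if the trace never got there.
    """
    library = library or TissueLibrary.default()
    solver = solver or SolverConfig()
    mesh = mesh if mesh is not None else build_trachea_mesh(config)
    model = TracheaModel(mesh, library, malacia=malacia, follower=True)
    area0 = lumen_surface_area(mesh)
    target_lam = target_force / (CMH2O_TO_MPA * area0)

    # march the stable primary branch under plain load control first (cheap),
    # then continue with arc length from wherever that got to
    preload = run_load_program(
        model, LoadProgram(max_pressure=target_lam,
                           output_interval=max(target_lam / 8.0, 1.0)),
        solver)
    u0 = preload.states[-1].displacements.ravel()[model.free]
    lam0 = preload.states[-1].pressure

    def passed_limit(lams) -> bool:
        # a pressure drawdown anywhere along the path marks a traversed fold
        run_max = np.maximum.accumulate(lams)
        return bool((run_max - lams).max() > 0.02 * max(run_max[-1], 1e-9))

    def stop(states) -> bool:
        lams = np.array([s.pressure for s in states])
        if len(lams) < 3:
            return False
        rising = lams[-1] > lams[-2]
        return bool(passed_limit(lams) and rising and
                    lams[-1] >= target_lam)

    result = arc_length_trace(model, solver, lam_max=lam_cap,
                              max_steps=max_steps, stop_condition=stop,
                              u0=u0, lam0=lam0)
    states = preload.states[:-1] + result.states
    result = SimulationResult(states, result.termination,
                              preload.log + result.log)
    stop_index = None
    arc_states = states[len(preload.states) - 1:]
    if len(arc_states) >= 3 and stop(arc_states):
        stop_index = len(states) - 1
    return result, mesh, stop_index


@dataclass
class SweepResult:
    """Tabulated sweep outcome: a summary frame plus per-cell details."""

    summary: pd.DataFrame
    curves: dict = field(default_factory=dict)
    reports: dict = field(default_factory=dict)


def run_sweep(diameters=(6.0, 8.0, 10.0),
              anterior_severities=("soft", "mucosa"),
              ring_counts=(0, 1, 3, 5, 7),
              posterior_lengths=(),
              posterior_coeff_sets=((1.0, 7.0), (1.0, 1.0)),
              mesh_factory=TracheaConfig.coarse,
              library: TissueLibrary | None = None,
              program: LoadProgram | None = None,
              solver: SolverConfig | None = None,
              threshold: float = 0.05) -> SweepResult:
    """Run the anterior and posterior malacia grids.

    Anterior cells: every diameter x severity x ring count (0 rings = the
    intact model, run once per diameter).  Posterior cells: every diameter
    x coefficient set x malacic length.  Individual cell failures are
    logged and recorded, never fatal to the sweep.
    """
    library = library or TissueLibrary.default()
    program = program or LoadProgram()
    solver = solver or SolverConfig()
    rows, curves, reports = [], {}, {}

    def one_cell(key, cfg, mesh, malacia, severity, extent):
        try:
            result, _ = simulate_trachea(cfg, library, malacia, program,
                                         solver, mesh=mesh)
            curve = area_ratio_curve(result, mesh, severity=severity,
                                     extent=extent)
            rep = detect_instability(curve, threshold)
            strain = (element_strains(mesh, result.states[-1].displacements)
                      [:, 2].max() if len(result.states) else np.nan)
            rows.append({
                "diameter": cfg.diameter, "severity": severity,
                "extent": extent, "termination": result.termination,
                "final_pressure": curve.pressure[-1],
                "final_force": curve.force[-1],
                "final_area_ratio": curve.area_ratio[-1],
                "onset": rep.onset,
                "onset_force": rep.onset_force,
                "onset_pressure": rep.onset_pressure,
                "max_wall_strain": float(strain),
            })
            curves[key] = curve
            reports[key] = rep
        except Exception as exc:   # keep sweeping; record the failure
            logger.warning("sweep cell %s failed: %s", key, exc)
            rows.append({"diameter": cfg.diameter, "severity": severity,
                         "extent": extent, "termination": "error",
                         "final_pressure": np.nan, "final_force": np.nan,
                         "final_area_ratio": np.nan, "onset": False,
                         "onset_force": np.nan, "onset_pressure": np.nan,
                         "max_wall_strain": np.nan})

    for d in diameters:
        cfg = mesh_factory(diameter=d)
        mesh = build_trachea_mesh(cfg)
        for sev in anterior_severities:
            for n in ring_counts:
                if n == 0 and sev != anterior_severities[0]:
                    continue   # intact model is severity-independent
                mal = (MalaciaSpec("anterior", sev, n) if n else None)
                label = sev if n else "intact"
                one_cell((d, label, n), cfg, mesh, mal, label, n)
        for coeffs in (posterior_coeff_sets if posterior_lengths else ()):
            for length in posterior_lengths:
                mal = MalaciaSpec("posterior", "posterior", length,
                                  posterior_coeffs=coeffs)
                label = f"posterior(a={coeffs[0]:g},b={coeffs[1]:g})"
                one_cell((d, label, length), cfg, mesh, mal, label, length)

    return SweepResult(pd.DataFrame(rows), curves, reports)


def plot_collapse_curves(curves, ax=None, label_fmt="{severity} {extent}"):
    """Plot area-ratio vs force curves (matplotlib axes returned)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c in curves:
        ax.plot(c.force, c.area_ratio, marker="o", ms=3,
                label=label_fmt.format(severity=c.severity, extent=c.extent))
    ax.set_xlabel("total airway force (N)")
    ax.set_ylabel("lumen area ratio")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    return ax
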
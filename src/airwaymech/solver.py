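"""Nonlinear solution drivers: Newton, adaptive load control, arc-length.

The drivers operate on any system exposing the small protocol implemented
by `airwaymech.fem.TracheaModel` and by the reduced benchmark fixtures:

* ``n_free``                       — number of unknowns
* ``residual_and_tangent(u, lam)`` — out-of-balance force and Jacobian at
  load level ``lam`` (pressure in cm H2O for the trachea model)
* ``load_vector(u)``               — external load at unit load level

Load control marches the pressure program with adaptive substeps (halve on
divergence, grow after easy convergence) and reports
``non_convergence_collapse`` when the substep collapses below its floor —
the signature of a snap-through limit point under pure load control.  The
arc-length driver (cylindrical Crisfield constraint) parameterizes the
equilibrium path by arc length instead, so it can traverse the limit point
and follow the post-buckled branch down to wall contact.  Both drivers are
deterministic: no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

__all__ = [
    "LoadProgram",
    "SolverConfig",
    "DeformedState",
    "SimulationResult",
    "newton_solve",
    "run_load_program",
    "arc_length_trace",
]


@dataclass(frozen=True)
class LoadProgram:
    """Exhalation load program: 0 to ``max_pressure`` cm H2O, states
    recorded at every ``output_interval`` multiple (defaults 40 and 4)."""

    max_pressure: float = 40.0
    output_interval: float = 4.0
    follower: bool = True

    def __post_init__(self):
        if self.max_pressure < 0 or self.output_interval <= 0:
            raise ValueError("invalid load program")

    def output_pressures(self) -> np.ndarray:
        n = int(np.floor(self.max_pressure / self.output_interval + 1e-9))
        out = self.output_interval * np.arange(1, n + 1)
        if n == 0 or out[-1] < self.max_pressure - 1e-9:
            out = np.append(out, self.max_pressure)
        return out


@dataclass(frozen=True)
class SolverConfig:
    """Newton / stepping / continuation parameters (deterministic)."""

    tol_residual: float = 1e-6        # relative to the external load norm
    tol_displacement: float = 1e-8    # relative displacement increment
    max_newton: int = 25
    initial_substep: float = 1.0      # cm H2O
    min_substep: float = 1e-3
    max_substep: float = 4.0
    continuation: str = "load_control"   # or "arc_length"
    arc_initial: float = 0.5          # initial arc radius (norm of du, mm)
    arc_min: float = 1e-5
    arc_max: float = 5.0
    max_arc_steps: int = 400
    penetration_limit: float | None = None  # step-cut if exceeded (mm)
    max_newton_step: float | None = None  # cap on |du| per iteration (mm)

    def __post_init__(self):
        if min(self.tol_residual, self.tol_displacement,
               self.min_substep) <= 0:
            raise ValueError("tolerances and substeps must be positive")


@dataclass
class DeformedState:
    """One converged equilibrium state."""

    pressure: float                   # cm H2O
    displacements: np.ndarray         # (n_nodes, 3) mm (full field)
    converged: bool = True
    contact_active: bool = False
    newton_iterations: int = 0


@dataclass
class SimulationResult:
    """Ordered converged states plus the termination reason and log."""

    states: list[DeformedState]
    termination: str                  # completed | non_convergence_collapse | error
    log: list[dict] = field(default_factory=list)

    @property
    def pressures(self) -> np.ndarray:
        return np.array([s.pressure for s in self.states])

    @property
    def completed(self) -> bool:
        return self.termination == "completed"


def _solve(K, rhs):
    if sparse.issparse(K):
        return spsolve(K.tocsc(), rhs)
    K = np.atleast_2d(K)
    return np.linalg.solve(K, np.atleast_1d(rhs))


def _bordered_solve(K, fhat, c_row, rhs_top, rhs_bot):
    """Solve [[K, -fhat], [c^T, 0]] [x; y] = [rhs_top; rhs_bot].

    The bordered matrix is regular at load limit points (where K alone is
    singular), which is what carries the arc-length corrector around a
    fold."""
    n = len(fhat)
    rhs = np.concatenate([rhs_top, [rhs_bot]])
    if sparse.issparse(K):
        B = sparse.bmat([[K, -fhat.reshape(-1, 1)],
                         [sparse.csr_matrix(c_row.reshape(1, -1)), None]],
                        format="csc")
        sol = spsolve(B, rhs)
    else:
        B = np.zeros((n + 1, n + 1))
        B[:n, :n] = np.atleast_2d(K)
        B[:n, n] = -fhat
        B[n, :n] = c_row
        sol = np.linalg.solve(B, rhs)
    return sol[:n], float(sol[n])


def newton_solve(system, u0: np.ndarray, lam: float, config: SolverConfig):
    """Full Newton at fixed load level; returns (u, converged, n_iter)."""
    from .fem import _InvertedElement

    u = u0.copy()
    fhat = system.load_vector(u)
    scale = max(float(np.linalg.norm(fhat)) * abs(lam), 1e-10)
    for it in range(config.max_newton):
        try:
            r, K = system.residual_and_tangent(u, lam)
        except _InvertedElement:
            return u, False, it
        rnorm = float(np.linalg.norm(r))
        if not np.isfinite(rnorm):
            return u, False, it
        if it == 0:
            # displacement-driven problems have no external load to scale
            # against; fall back to the initial out-of-balance force
            scale = max(scale, rnorm)
        if rnorm <= config.tol_residual * scale:
            return u, True, it
        try:
            du = _solve(K, -r)
        except Exception:
            return u, False, it
        if not np.all(np.isfinite(du)):
            return u, False, it
        cap = config.max_newton_step
        if cap is not None:
            dun = float(np.linalg.norm(du))
            if dun > cap:       # crude trust region against contact blow-through
                du = du * (cap / dun)
        u = u + du
        dunorm = float(np.linalg.norm(du))
        if dunorm <= config.tol_displacement * max(np.linalg.norm(u), 1.0):
            r = system.residual(u, lam)
            ok = float(np.linalg.norm(r)) <= 100 * config.tol_residual * scale
            return u, ok, it + 1
        r_prev = rnorm
    return u, False, config.max_newton


def run_load_program(system, program: LoadProgram,
                     config: SolverConfig | None = None,
                     record_final: bool = False) -> SimulationResult:
    """March the pressure program under load control with adaptive substeps.

    States are recorded at every output-interval multiple (and at zero
    pressure).  If the substep is cut below ``min_substep`` — which is how
    a snap-through limit point manifests under load control — the run
    terminates with ``non_convergence_collapse`` and keeps the states
    reached so far.
    """
    config = config or SolverConfig()
    n = system.n_free
    u = np.zeros(n)
    u_prev, p_prev = u.copy(), 0.0
    log: list[dict] = []
    states = [_make_state(system, u, 0.0, 0)]
    outputs = list(program.output_pressures())
    if program.max_pressure <= 0:
        return SimulationResult(states, "completed", log)

    p = 0.0
    ds = min(config.initial_substep, program.max_pressure)
    pen_limit = config.penetration_limit
    rate_prev = None
    while p < program.max_pressure - 1e-9:
        next_out = outputs[0]
        p_try = min(p + ds, next_out)
        # secant predictor from the previous two converged levels
        if p_try > p and p > p_prev:
            u0 = u + (u - u_prev) * ((p_try - p) / (p - p_prev))
        else:
            u0 = u.copy()
        u_new, ok, iters = newton_solve(system, u0, p_try, config)
        if not ok and not np.allclose(u0, u):
            # retry once without extrapolation before cutting the step
            u_new, ok, iters = newton_solve(system, u.copy(), p_try, config)
        if ok and pen_limit is not None and \
                getattr(system, "last_max_penetration", 0.0) > pen_limit:
            ok = False
        if ok and rate_prev is not None and rate_prev > 0:
            # path-continuity guard: a converged state far from the current
            # branch means Newton hopped across a limit point (the dynamic
            # snap); load control must treat that as loss of convergence
            rate = float(np.linalg.norm(u_new - u)) / (p_try - p)
            if rate > 25.0 * rate_prev and rate * (p_try - p) > \
                    100 * config.tol_displacement * max(np.linalg.norm(u), 1.0):
                ok = False
        log.append({"pressure": p_try, "converged": bool(ok),
                    "iterations": iters, "substep": ds})
        if ok:
            if p_try > p:
                rate_prev = float(np.linalg.norm(u_new - u)) / (p_try - p)
            u_prev, p_prev = u, p
            u, p = u_new, p_try
            if abs(p - next_out) < 1e-9:
                states.append(_make_state(system, u, p, iters))
                outputs.pop(0)
            if iters <= 6:
                ds = min(ds * 1.5, config.max_substep)
        else:
            ds *= 0.5
            if ds < config.min_substep:
                if record_final and p > states[-1].pressure + 1e-9:
                    # keep the last converged (sub-cadence) state: it marks
                    # how close to the limit point load control got
                    states.append(_make_state(system, u, p, 0))
                return SimulationResult(states, "non_convergence_collapse", log)
    return SimulationResult(states, "completed", log)


def _make_state(system, u_free, pressure, iters) -> DeformedState:
    expand = getattr(system, "expand", None)
    disp = expand(u_free).reshape(-1, 3) if expand else u_free.copy()
    return DeformedState(pressure=float(pressure), displacements=disp,
                         converged=True,
                         contact_active=bool(getattr(system,
                                                     "last_contact_active",
                                                     False)),
                         newton_iterations=iters)


def viscous_settle(system, u0: np.ndarray, lam: float,
                   config: SolverConfig | None = None,
                   max_outer: int = 120):
    """Find a (possibly distant) static equilibrium by damped settling.

    Adds a viscous regularization ``alpha * (u - u_k)`` to the residual and
    marches pseudo-time: each inner problem has tangent ``K + alpha I`` and
    is well-posed even past a limit point, so the iterate can fall through
    a snap-through region and land on the contact-stabilized branch.  The
    damping is annealed away as the iterate approaches equilibrium and the
    result is verified with a plain (undamped) Newton solve.

    Returns ``(u, converged)``.  Deterministic.
    """
    from scipy.sparse import identity

    from .fem import _InvertedElement

    config = config or SolverConfig()
    u_k = u0.copy()
    try:
        r, K = system.residual_and_tangent(u_k, lam)
    except _InvertedElement:
        return u_k, False
    diag = K.diagonal() if sparse.issparse(K) else np.diag(np.atleast_2d(K))
    pos = diag[diag > 0]
    alpha = 0.05 * float(np.median(pos)) if len(pos) else 1.0
    fhat = system.load_vector(u_k)
    scale = max(float(np.linalg.norm(fhat)) * max(abs(lam), 1.0), 1e-10)
    n = len(u_k)
    eye = identity(n, format="csr") if sparse.issparse(K) else np.eye(n)

    for outer in range(max_outer):
        u = u_k.copy()
        inner_ok = False
        for it in range(config.max_newton):
            try:
                r, K = system.residual_and_tangent(u, lam)
            except _InvertedElement:
                break
            g = r + alpha * (u - u_k)
            if not np.all(np.isfinite(g)):
                break
            if float(np.linalg.norm(g)) <= config.tol_residual * scale:
                inner_ok = True
                break
            try:
                du = _solve(K + alpha * eye, -g)
            except Exception:
                break
            if not np.all(np.isfinite(du)):
                break
            u = u + du
        if not inner_ok:
            alpha *= 4.0
            continue
        moved = float(np.linalg.norm(u - u_k))
        u_k = u
        # static residual at a damped equilibrium is ~ alpha * step size
        if alpha * moved <= 100.0 * config.tol_residual * scale:
            u_s, ok, _ = newton_solve(system, u_k, lam, config)
            if ok:
                return u_s, True
            alpha *= 2.0
        else:
            alpha *= 0.5
    u_s, ok, _ = newton_solve(system, u_k, lam, config)
    return (u_s, True) if ok else (u_k, False)


def arc_length_trace(system, config: SolverConfig | None = None,
                     lam_max: float = 40.0, lam_stop: float | None = None,
                     max_steps: int | None = None,
                     stop_condition=None,
                     u0: np.ndarray | None = None,
                     lam0: float = 0.0) -> SimulationResult:
    """Trace the equilibrium path with arc-length continuation.

    The path is parameterized by the norm of the displacement increment
    (cylindrical constraint ``||du|| = dl``), so limit points where pure
    load control fails are traversed and the post-buckled branch is
    followed (the load factor may decrease).  Each Newton iteration solves
    the bordered system

        [ K     -fhat ] [du  ]   [ -r                  ]
        [ Du^T    0   ] [dlam] = [ (dl^2 - ||Du||^2)/2 ]

    which stays nonsingular at limit points where K itself is singular —
    the property that lets the trace turn the fold instead of stalling on
    it.  The trace stops when the load level reaches ``lam_stop`` (default
    ``lam_max``), when the step budget is exhausted, or when the arc
    radius collapses.  Every converged step is recorded as a state.  An
    optional ``stop_condition(states)`` is evaluated after each converged
    step and ends the trace with termination "completed" when true (used
    to stop on post-buckling criteria rather than a load level).
    """
    from .fem import _InvertedElement

    config = config or SolverConfig()
    max_steps = max_steps or config.max_arc_steps
    lam_stop = lam_max if lam_stop is None else lam_stop
    u = np.zeros(system.n_free) if u0 is None else u0.copy()
    lam = float(lam0)
    states = [_make_state(system, u, lam, 0)]
    log: list[dict] = []
    dl = config.arc_initial
    du_prev = None
    steps = 0
    while steps < max_steps and lam < lam_stop - 1e-9:
        steps += 1
        # tangent direction via the bordered system (previous increment as
        # the constraint row keeps it solvable on the fold itself)
        try:
            r, K = system.residual_and_tangent(u, lam)
            fhat = system.load_vector(u)
            if du_prev is None:
                zu = _solve(K, fhat)
                zl = 1.0
            else:
                c = du_prev / max(np.linalg.norm(du_prev), 1e-300)
                zu, zl = _bordered_solve(K, fhat, c,
                                         np.zeros(system.n_free), 1.0)
        except Exception:           # inverted element / singular first step
            zu = None
        if zu is None or not np.all(np.isfinite(zu)):
            dl *= 0.5
            if dl < config.arc_min:
                return SimulationResult(states, "non_convergence_collapse", log)
            continue
        norm_t = float(np.linalg.norm(zu))
        if norm_t == 0:
            return SimulationResult(states, "error", log)
        if du_prev is None:
            sign = 1.0 if zl >= 0 else -1.0    # start by loading
        else:
            sign = 1.0 if float(du_prev @ zu) >= 0 else -1.0
        du = sign * dl * zu / norm_t
        dlam = sign * dl * zl / norm_t
        ok = False
        scale = max(float(np.linalg.norm(fhat)) * max(abs(lam), 1.0), 1e-10)
        for it in range(config.max_newton):
            try:
                r, K = system.residual_and_tangent(u + du, lam + dlam)
            except _InvertedElement:
                break
            rnorm = float(np.linalg.norm(r))
            if not np.isfinite(rnorm):
                break
            gap = 0.5 * (dl * dl - float(du @ du))
            if rnorm <= config.tol_residual * scale and \
                    abs(gap) <= 1e-6 * dl * dl:
                ok = True
                break
            try:
                fhat_c = system.load_vector(u + du)
                ddu, ddl = _bordered_solve(K, fhat_c, du, -r, gap)
            except Exception:
                break
            if not np.all(np.isfinite(ddu)) or not np.isfinite(ddl):
                break
            cap = config.max_newton_step
            if cap is not None:
                ddn = float(np.linalg.norm(ddu))
                if ddn > cap:
                    ddu, ddl = ddu * (cap / ddn), ddl * (cap / ddn)
            du = du + ddu
            dlam = dlam + ddl
        log.append({"lam": lam + dlam, "converged": ok, "iterations": it,
                    "arc": dl})
        if ok:
            u = u + du
            lam = lam + dlam
            du_prev = du
            states.append(_make_state(system, u, lam, it))
            if stop_condition is not None and stop_condition(states):
                return SimulationResult(states, "completed", log)
            if it <= 5:
                dl = min(dl * 1.5, config.arc_max)
            elif it > 10:
                dl = max(dl * 0.75, config.arc_min)
        else:
            dl *= 0.5
            if dl < config.arc_min:
                return SimulationResult(states, "non_convergence_collapse", log)
    term = "completed" if lam >= lam_stop - 1e-9 else (
        "completed" if steps >= max_steps else "error")
    if steps >= max_steps and lam < lam_stop - 1e-9:
        term = "step_budget_exhausted"
    return SimulationResult(states, term, log)
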
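"""Forward time integration and stationary Newton solves.

The forward model

    u_t = div(D grad u) + div((div D) u) + rho u (1 - u)

is integrated by the unconditionally stable implicit Euler scheme with the
reaction treated fully implicitly (no operator splitting); each step solves
the nonlinear backward-Euler system with a damped Newton iteration.  The
stationalized problem replaces time stepping altogether: the logistic term
is augmented by the amplitude-only penalty ``p(u) = |v| sqrt(2/3)
(1 - sqrt(u)) u`` and the solution is pinned to the visibility threshold on
the discrete boundary of the imaging-visible region.  Small-amplitude
initial guesses (well inside the penalizing regime ``u < 4/9``) make Newton
converge to the clinically relevant *outward moving* branch; guesses near 1
select the inward branch.

Whenever an iterate leaves the physical range [0, 1], the model reaction is
replaced node-wise by the positivity guard ``n(w) = -rho w`` (w < 0) /
``rho (1 - w)`` (w > 1), preventing the logistic term from amplifying
negative densities.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

from .analytic import ANALYTIC_WAVE_SPEED, SQRT_2_3
from .discretization import (
    ConstraintSet,
    ScalarField,
    StructuredGrid,
    assemble,
)

__all__ = [
    "ModelParams",
    "TimeControls",
    "SolveReport",
    "NewtonError",
    "newton_solve",
    "solve_forward",
    "solve_stationary",
]


class NewtonError(RuntimeError):
    """Newton iteration failed; carries the last :class:`SolveReport`."""

    def __init__(self, message: str, report: "SolveReport"):
        super().__init__(message)
        self.report = report


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Parameters of the (stationalized) tumor growth model.

    rho:
        Logistic growth rate, 1/time.
    v_mag:
        Penalty magnitude; should match the front's limit propagation
        speed (``5/sqrt(6)`` in nondimensional runs).
    theta:
        Imaging visibility threshold pinning the internal Dirichlet
        constraint (default 0.16).
    alpha:
        Dimensionless water-to-tumor diffusivity scaling, applied when a
        DTI volume is turned into the model's tensor field.
    """

    rho: float = 1.0
    v_mag: float = ANALYTIC_WAVE_SPEED
    theta: float = 0.16
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not self.rho > 0.0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if not self.v_mag >= 0.0:
            raise ValueError(f"v_mag must be non-negative, got {self.v_mag}")
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta must lie in (0, 1), got {self.theta}")
        if not self.alpha > 0.0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")


@dataclasses.dataclass(frozen=True)
class TimeControls:
    """Implicit-Euler time stepping controls.

    ``checkpoints`` are the times at which the trajectory is recorded
    (snapped to the nearest step); the final time is always recorded.
    """

    t_end: float
    dt: float
    t_start: float = 0.0
    checkpoints: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.dt > 0.0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def n_steps(self) -> int:
        return max(1, int(round((self.t_end - self.t_start) / self.dt)))

    def checkpoint_steps(self) -> dict[int, float]:
        """Map step index -> requested checkpoint time."""
        steps: dict[int, float] = {}
        times = list(self.checkpoints) if self.checkpoints is not None else []
        times.append(self.t_end)
        for t in times:
            k = int(round((t - self.t_start) / self.dt))
            if 0 < k <= self.n_steps:
                steps.setdefault(k, float(t))
        return steps


@dataclasses.dataclass
class SolveReport:
    """Outcome of a Newton solve (or a sequence of them)."""

    converged: bool
    iterations: int
    residual_norm: float
    line_search_steps: int = 0
    message: str = ""
    step_iterations: list[int] = dataclasses.field(default_factory=list)
    flags: list[str] = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _reaction_terms(u: np.ndarray, rho: float, v_mag: float, guard: bool):
    """Vectorized effective reaction and its derivative with the
    positivity guard substituted outside [0, 1].

    The penalty derivative uses the one-sided limit
    ``d/du[(1 - sqrt(u)) u] -> 1`` for ``u -> 0+`` so the Jacobian stays
    finite at vanishing densities.
    """
    uc = np.clip(u, 0.0, 1.0)
    su = np.sqrt(uc)
    f_in = rho * uc * (1.0 - uc) - v_mag * SQRT_2_3 * (1.0 - su) * uc
    fp_in = rho * (1.0 - 2.0 * uc) - v_mag * SQRT_2_3 * (1.0 - 1.5 * su)
    if not guard:
        return f_in, fp_in
    below = u < 0.0
    above = u > 1.0
    f = np.where(below, -rho * u, np.where(above, rho * (1.0 - u), f_in))
    fp = np.where(below | above, -rho, fp_in)
    return f, fp


class _LinearSolver:
    """Factorization cache for the Newton linear solves.

    ``direct`` factorizes with SuperLU; ``krylov`` builds an ILU
    preconditioner for BiCGSTAB (falling back on the direct solve if the
    Krylov iteration breaks down).  A factorization is reused as long as
    the caller keeps passing the same Jacobian object, which is what the
    frozen-Jacobian (modified Newton) mode exploits.
    """

    def __init__(self, method: str):
        if method not in ("direct", "krylov"):
            raise ValueError(f"unknown linear solver {method!r}")
        self.method = method
        self._key = None
        self._solve = None

    def __call__(self, J, rhs: np.ndarray) -> np.ndarray:
        if not sparse.issparse(J):
            Jd = np.atleast_2d(np.asarray(J, dtype=float))
            return np.linalg.solve(Jd, rhs)
        if self._key is not J:
            Jc = J.tocsc()
            if self.method == "direct":
                self._solve = spla.splu(Jc).solve
            else:
                ilu = spla.spilu(Jc, drop_tol=1e-6, fill_factor=20)
                prec = spla.LinearOperator(Jc.shape, ilu.solve)

                def _krylov(b, _Jc=Jc, _prec=prec):
                    sol, info = spla.bicgstab(
                        _Jc, b, M=_prec, rtol=1e-12, atol=0.0
                    )
                    if info != 0:
                        sol = spla.spsolve(_Jc, b)
                    return sol

                self._solve = _krylov
            self._key = J
        return self._solve(rhs)


def newton_solve(
    residual: Callable[[np.ndarray], np.ndarray],
    jacobian: Callable[[np.ndarray], object],
    x0: np.ndarray,
    abs_tol: float = 1e-10,
    rel_tol: float = 1e-8,
    max_iter: int = 50,
    max_halvings: int = 20,
    linear_solver: str = "direct",
    frozen_jacobian: bool = False,
) -> tuple[np.ndarray, SolveReport]:
    """Damped Newton iteration with backtracking line search.

    Convergence when the residual 2-norm drops below ``abs_tol`` or is
    reduced by ``rel_tol`` relative to the initial guess.  The line search
    halves the step until the residual norm decreases; a stall (no
    decrease within ``max_halvings``) and exceeding ``max_iter`` are
    reported as distinct failures.

    With ``frozen_jacobian=True`` the Jacobian is assembled and factorized
    at the initial iterate only and reused (modified Newton) — convergence
    drops to linear but each iteration is a cheap triangular solve, which
    pays off inside small implicit-Euler steps where the initial iterate
    is already close.
    """
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    r = np.atleast_1d(residual(x))
    norm0 = float(np.linalg.norm(r))
    norm = norm0
    total_halvings = 0
    lin = _LinearSolver(linear_solver)
    J_frozen = jacobian(x) if frozen_jacobian else None
    for it in range(max_iter):
        if norm <= abs_tol or norm <= rel_tol * norm0:
            return x, SolveReport(
                converged=True,
                iterations=it,
                residual_norm=norm,
                line_search_steps=total_halvings,
            )
        J = J_frozen if frozen_jacobian else jacobian(x)
        dx = lin(J, -r)
        lam = 1.0
        for _ in range(max_halvings + 1):
            x_try = x + lam * dx
            r_try = np.atleast_1d(residual(x_try))
            norm_try = float(np.linalg.norm(r_try))
            if norm_try < (1.0 - 1e-4 * lam) * norm or norm_try <= abs_tol:
                break
            lam *= 0.5
            total_halvings += 1
        else:
            report = SolveReport(
                converged=False,
                iterations=it + 1,
                residual_norm=norm,
                line_search_steps=total_halvings,
                message="line search stalled",
            )
            raise NewtonError("Newton line search stalled", report)
        x, r, norm = x_try, r_try, norm_try
    if norm <= abs_tol or norm <= rel_tol * norm0:
        return x, SolveReport(
            converged=True,
            iterations=max_iter,
            residual_norm=norm,
            line_search_steps=total_halvings,
        )
    report = SolveReport(
        converged=False,
        iterations=max_iter,
        residual_norm=norm,
        line_search_steps=total_halvings,
        message="maximum Newton iterations exceeded",
    )
    raise NewtonError("Newton did not converge within max iterations", report)


def _forward_reaction(u, params: ModelParams, guard: bool, stationalized: bool):
    v = params.v_mag if stationalized else 0.0
    return _reaction_terms(u, params.rho, v, guard)


def solve_forward(
    grid: StructuredGrid,
    field,
    params: ModelParams,
    init: ScalarField,
    controls: TimeControls,
    drift=None,
    guard: bool = True,
    linear_solver: str = "direct",
    newton_kwargs: dict | None = None,
) -> tuple[list[tuple[float, ScalarField]], SolveReport]:
    """Implicit-Euler integration of the forward growth model.

    Returns the trajectory as ``(time, field)`` checkpoints (the final
    time always included) plus an aggregate :class:`SolveReport`.  With a
    near-zero tensor field the dynamics degenerate to the logistic ODE at
    each node; with ``rho`` effectively zero, to pure diffusion.
    """
    if np.any(init.values < 0.0) or np.any(init.values > 1.0):
        raise ValueError("initial condition must lie in [0, 1]")
    system = assemble(grid, field, drift)
    M = system.mass.tocsr()
    L = system.spatial_operator()
    dt = controls.dt
    nk = dict(newton_kwargs or {})
    nk.setdefault("linear_solver", linear_solver)
    # one factorization per implicit-Euler step; full Newton on fallback
    nk.setdefault("frozen_jacobian", True)

    u = init.flat().copy()
    checkpoints = controls.checkpoint_steps()
    trajectory: list[tuple[float, ScalarField]] = []
    total_iters = 0
    total_ls = 0
    step_iters: list[int] = []
    last_norm = 0.0

    for k in range(1, controls.n_steps + 1):
        u_old = u

        def residual(w: np.ndarray) -> np.ndarray:
            f, _ = _reaction_terms(w, params.rho, 0.0, guard)
            return M @ (w - u_old) - dt * (L @ w + M @ (f))

        def jacobian(w: np.ndarray):
            _, fp = _reaction_terms(w, params.rho, 0.0, guard)
            return (M - dt * (L + M @ sparse.diags(fp))).tocsc()

        try:
            u, rep = newton_solve(residual, jacobian, u_old, **nk)
        except NewtonError:
            if not nk.get("frozen_jacobian", False):
                raise
            # modified Newton stalled: retry the step with a full Newton
            retry = {**nk, "frozen_jacobian": False}
            try:
                u, rep = newton_solve(residual, jacobian, u_old, **retry)
            except NewtonError as err:
                err.report.message += (
                    f" (forward step {k}, t={controls.t_start + k * dt:g})"
                )
                raise
        total_iters += rep.iterations
        total_ls += rep.line_search_steps
        step_iters.append(rep.iterations)
        last_norm = rep.residual_norm
        if k in checkpoints:
            t = controls.t_start + k * dt
            trajectory.append((t, ScalarField.from_flat(grid, u.copy())))

    report = SolveReport(
        converged=True,
        iterations=total_iters,
        residual_norm=last_norm,
        line_search_steps=total_ls,
        step_iterations=step_iters,
    )
    return trajectory, report


def solve_stationary(
    grid: StructuredGrid,
    field,
    params: ModelParams,
    constraints: ConstraintSet,
    guess="oms-default",
    drift=None,
    guard: bool = True,
    linear_solver: str = "direct",
    newton_kwargs: dict | None = None,
) -> tuple[ScalarField, SolveReport]:
    """Newton solution of the constrained stationalized problem.

    Finds a root of ``div(D grad u) + div((div D) u) + rho u (1 - u)
    - p(u, v_mag)`` with the solution pinned to ``theta`` at the
    constraint nodes and zero-Neumann outer boundaries.

    ``guess`` selects the branch: ``"oms-default"`` starts from a small
    constant (1e-3) on free nodes outside the visible region — well
    inside the penalizing regime — which reliably selects the outward
    moving solution; nodes the segmentation marks as visible
    (``constraints.interior``) start at 1, since the density is known to
    exceed the threshold there.  ``"ims-default"`` starts near 1
    everywhere and converges to the inward branch.  A
    :class:`ScalarField` may be supplied instead.

    An empty constraint set converges to the trivial zero state; the
    report is flagged accordingly.
    """
    constraints.validate(grid)
    system = assemble(grid, field, drift)
    M = system.mass.tocsr()
    L = system.spatial_operator()
    idx = constraints.indices
    theta = constraints.value
    n = grid.n_nodes

    if isinstance(guess, ScalarField):
        u0 = guess.flat().copy()
    elif guess == "oms-default":
        u0 = np.full(n, 1e-3)
        if constraints.interior is not None:
            u0[constraints.interior] = 1.0
    elif guess == "ims-default":
        u0 = np.full(n, 0.999)
    else:
        raise ValueError(f"unknown guess {guess!r}")
    u0[idx] = theta

    free = np.ones(n)
    free[idx] = 0.0
    D_free = sparse.diags(free)
    D_pin = sparse.diags(1.0 - free)

    def residual(w: np.ndarray) -> np.ndarray:
        f, _ = _reaction_terms(w, params.rho, params.v_mag, guard)
        r = L @ w + M @ f
        r[idx] = w[idx] - theta
        return r

    def jacobian(w: np.ndarray):
        _, fp = _reaction_terms(w, params.rho, params.v_mag, guard)
        J = L + M @ sparse.diags(fp)
        return (D_free @ J + D_pin).tocsc()

    nk = dict(newton_kwargs or {})
    nk.setdefault("linear_solver", linear_solver)
    try:
        u, report = newton_solve(residual, jacobian, u0, **nk)
    except NewtonError as err:
        # Plain Newton can stall on coarse 3D shells where the pinned
        # staircase surface makes the basin of attraction tiny.  Fall
        # back on pseudo-transient continuation: integrate the
        # constrained stationalized dynamics until close enough for
        # Newton to finish.
        u, report = _pseudo_transient(
            M, L, idx, theta, params, guard, u0, residual, jacobian, nk
        )
        report.flags.append("pseudo-transient-continuation")
    if len(constraints) == 0:
        report.flags.append("empty-constraints:trivial-state")
    else:
        u[idx] = theta  # pinned nodes carry the constraint value exactly
    out = ScalarField.from_flat(grid, u)
    return out, report


def _pseudo_transient(
    M,
    L,
    idx,
    theta,
    params: ModelParams,
    guard: bool,
    u0: np.ndarray,
    residual,
    jacobian,
    newton_kwargs: dict,
    dtau0: float = 0.5,
    dtau_max: float = 50.0,
    grow: float = 1.4,
    max_steps: int = 200,
    polish_every: int = 5,
) -> tuple[np.ndarray, SolveReport]:
    """Pseudo-transient continuation toward the constrained steady state.

    Backward-Euler steps of the stationalized dynamics with an adaptive
    pseudo-time step: grow on success, halve and retry when a step fails
    or increases the stationary residual.  Every few steps a plain Newton
    polish of the stationary system is attempted from the current state.
    """
    n = u0.size
    free = np.ones(n)
    free[idx] = 0.0
    D_free = sparse.diags(free)
    D_pin = sparse.diags(1.0 - free)
    u = u0.copy()
    dtau = dtau0
    best_norm = float(np.linalg.norm(residual(u)))
    total_iters = 0
    nk_inner = {**newton_kwargs, "frozen_jacobian": True, "abs_tol": 1e-9, "rel_tol": 1e-6}
    nk_polish = dict(newton_kwargs)

    for step in range(1, max_steps + 1):
        u_old = u.copy()
        dt_step = dtau

        def res_step(w: np.ndarray) -> np.ndarray:
            f, _ = _reaction_terms(w, params.rho, params.v_mag, guard)
            r = M @ (w - u_old) - dt_step * (L @ w + M @ f)
            r[idx] = w[idx] - theta
            return r

        def jac_step(w: np.ndarray):
            _, fp = _reaction_terms(w, params.rho, params.v_mag, guard)
            J = M - dt_step * (L + M @ sparse.diags(fp))
            return (D_free @ J + D_pin).tocsc()

        try:
            u_new, rep = newton_solve(res_step, jac_step, u_old, **nk_inner)
        except NewtonError:
            dtau = max(dtau * 0.25, 1e-3)
            continue
        total_iters += rep.iterations
        norm_new = float(np.linalg.norm(residual(u_new)))
        if not np.isfinite(norm_new) or norm_new > 10.0 * best_norm:
            dtau = max(dtau * 0.25, 1e-3)
            continue
        u = u_new
        best_norm = min(best_norm, norm_new)
        dtau = min(dtau * grow, dtau_max)

        if step % polish_every == 0 or norm_new <= 1e-6:
            try:
                u_fin, rep_fin = newton_solve(residual, jacobian, u, **nk_polish)
            except NewtonError:
                continue
            rep_fin.iterations += total_iters
            rep_fin.flags.append(f"pseudo-time-steps:{step}")
            return u_fin, rep_fin

    report = SolveReport(
        converged=False,
        iterations=total_iters,
        residual_norm=best_norm,
        message="pseudo-transient continuation exhausted",
    )
    raise NewtonError("stationary solve did not converge", report)
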
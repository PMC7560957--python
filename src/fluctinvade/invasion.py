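"""Invasion fitness and its local expansion in strategy space.

The fitness of a rare mutant is always computed as the time average of its
per-capita growth rate along the resident attractor — never by simulating
the mutant's (exponentially growing or vanishing) population size — which
is numerically safe and equivalent for a rare mutant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, fsolve, root

from .model_core import Env, as_strategy
from .resident_analysis import (
    PeriodResult,
    batch_mean_se,
    default_initial_state,
    detect_period,
    growth_samples,
)
from .simulate import (
    SimulationConfig,
    Trajectory,
    build_deterministic_rhs,
    simulate_polymorphic,
    simulate_structured,
)

__all__ = [
    "InvasionResult",
    "LocalExpansion",
    "MethodError",
    "invasion_fitness",
    "selection_gradient",
    "second_order_coefficients",
    "expand_fitness_second_order",
    "find_singular_strategy",
]


class MethodError(ValueError):
    """The requested fitness method is unavailable for this model/state."""


DEFAULT_ERGODIC_CONFIG = SimulationConfig(dt=0.01, t_end=2000.0, seed=0,
                                          record_stride=10)


@dataclass
class InvasionResult:
    value: float
    method: str
    se: float = 0.0
    horizon: Optional[float] = None
    period: Optional[float] = None
    notes: str = ""


@dataclass
class LocalExpansion:
    """Selection gradient and the four second-order coefficient matrices of
    the two-argument fitness s(x', y') at a reference strategy.

    C11 = (1/2) d^2s/dx^2, C22 = (1/2) d^2s/dy^2, C21 = (1/2) d^2s/dydx,
    C12 = C21^T; they satisfy the conservation law
    C11 + C22 + C12 + C21 = 0 (up to finite-difference error).
    """

    gradient: np.ndarray
    C11: np.ndarray
    C12: np.ndarray
    C21: np.ndarray
    C22: np.ndarray
    h: float
    method: str = ""
    max_se: float = 0.0

    @property
    def conservation_defect(self) -> float:
        return float(np.max(np.abs(self.C11 + self.C22 + self.C12 + self.C21)))


def _check_lv_community(spec, residents):
    if getattr(spec, "env_tracks_populations", False):
        comm = tuple(float(np.atleast_1d(c)[0]) for c in (spec.community_strategies or ()))
        res = tuple(float(r[0]) for r in residents)
        if comm != res:
            raise ValueError(
                "this model binds the environment to a fixed community; "
                f"rebuild it with community_strategies={res} to simulate "
                "these residents"
            )


def _fitness_evaluator(spec, residents, method: str,
                       config: Optional[SimulationConfig],
                       resident_traj: Optional[Trajectory] = None,
                       resident_cycle: Optional[PeriodResult] = None,
                       burn_in: float = 0.2,
                       transient: float = 1000.0,
                       observe: float = 400.0,
                       rtol: float = 1e-10):
    """Do the resident-side work once and return ``y -> InvasionResult``."""
    residents = [as_strategy(r) for r in residents]
    if method == "closed_form":
        if spec.closed_form_fitness is None:
            raise MethodError("model has no closed-form fitness override")
        if len(residents) != 1:
            raise MethodError("closed-form fitness requires a single resident")
        x = residents[0]

        def evaluate(y):
            return InvasionResult(
                value=float(spec.closed_form_fitness(x, as_strategy(y))),
                method="closed_form")

        return evaluate

    if method == "ergodic":
        _check_lv_community(spec, residents)
        cfg = config or DEFAULT_ERGODIC_CONFIG
        traj = resident_traj
        if traj is None:
            init = default_initial_state(spec, residents)
            sim = simulate_structured if spec.is_structured else simulate_polymorphic
            traj = sim(spec, residents, init, cfg)

        def evaluate(y):
            samples = growth_samples(spec, traj, y, burn_in=burn_in)
            mean, se = batch_mean_se(samples)
            return InvasionResult(value=mean, method="ergodic", se=se,
                                  horizon=float(traj.times[-1]))

        return evaluate

    if method in ("periodic", "equilibrium"):
        if not spec.driver.is_deterministic:
            raise MethodError(f"{method} fitness requires a deterministic model")
        if len(residents) != 1:
            raise MethodError(f"{method} fitness requires a single resident")
        if spec.is_structured:
            raise MethodError(f"{method} fitness is implemented for "
                              "unstructured models only")
        x = residents[0]
        pack, rhs, unpack = build_deterministic_rhs(spec, [x])

        if method == "equilibrium":
            init = default_initial_state(spec, [x])
            warm = solve_ivp(rhs, (0.0, transient), pack(init), rtol=1e-8,
                             atol=1e-10)
            eq = fsolve(lambda v: rhs(0.0, np.asarray(v, dtype=float)),
                        warm.y[:, -1])
            eq_state = unpack(np.asarray(eq, dtype=float))
            theta = np.zeros(spec.driver.dim_theta)

            def evaluate(y):
                val = float(spec.growth(as_strategy(y), eq_state.env, theta))
                return InvasionResult(value=val, method="equilibrium")

            return evaluate

        pr = resident_cycle
        if pr is None:
            pr = detect_period(spec, x, transient=transient, observe=observe,
                               rtol=rtol)
        if pr.kind != "periodic":
            raise MethodError(
                f"no period found for the resident attractor (got {pr.kind!r})")
        tau = pr.tau
        n_eval = 4000
        t_eval = np.linspace(0.0, tau, n_eval)
        sol = solve_ivp(rhs, (0.0, tau), pr.end_state, rtol=rtol, atol=1e-12,
                        t_eval=t_eval)
        envs = [unpack(sol.y[:, i]).env for i in range(n_eval)]
        theta = np.zeros(spec.driver.dim_theta)

        def evaluate(y):
            yv = as_strategy(y)
            fs = np.array([float(spec.growth(yv, env, theta)) for env in envs])
            val = float(np.trapezoid(fs, t_eval) / tau)
            return InvasionResult(value=val, method="periodic", period=tau)

        return evaluate

    raise MethodError(f"unknown fitness method {method!r}")


def invasion_fitness(spec, resident, y, method: str = "ergodic",
                     config: Optional[SimulationConfig] = None,
                     resident_traj: Optional[Trajectory] = None,
                     resident_cycle: Optional[PeriodResult] = None,
                     burn_in: float = 0.2, transient: float = 1000.0,
                     observe: float = 400.0, rtol: float = 1e-10) -> InvasionResult:
    """Invasion fitness of mutant ``y`` in the environment set by the
    resident (or resident community).

    Methods: ``ergodic`` (time average of the mutant growth rate along a
    simulated resident trajectory, batch-means SE), ``periodic`` (average
    over one detected period of the deterministic resident limit cycle),
    ``equilibrium`` (growth rate at the deterministic fixed point),
    ``closed_form`` (model override).

    ``resident`` is one strategy, or a list of strategies for a polymorphic
    resident community (ergodic method).
    """
    if isinstance(resident, (list, tuple)) and len(resident) and \
            isinstance(resident[0], (list, tuple, np.ndarray)):
        residents = list(resident)
    else:
        residents = [resident]
    evaluate = _fitness_evaluator(spec, residents, method, config,
                                  resident_traj=resident_traj,
                                  resident_cycle=resident_cycle,
                                  burn_in=burn_in, transient=transient,
                                  observe=observe, rtol=rtol)
    return evaluate(y)


def _default_h(x):
    return 1e-3 * (1.0 + float(np.linalg.norm(as_strategy(x))))


def selection_gradient(spec, x, method: str = "closed_form",
                       h: Optional[float] = None,
                       config: Optional[SimulationConfig] = None,
                       crn: bool = True,
                       resident_traj: Optional[Trajectory] = None,
                       **kwargs) -> np.ndarray:
    """Selection gradient d/dy S_x(y) at y = x, by central differences.

    For the ``ergodic`` method all probe evaluations share one frozen
    resident trajectory (common random numbers) unless ``crn=False``, in
    which case every probe simulates its own resident path (for variance
    comparisons only).
    """
    x = as_strategy(x)
    d = x.size
    step = h if h is not None else _default_h(x)
    grad = np.zeros(d)
    if method == "ergodic" and not crn:
        cfg = config or DEFAULT_ERGODIC_CONFIG
        for i in range(d):
            vals = []
            for sgn, off in ((1.0, 0), (-1.0, 1)):
                probe_cfg = SimulationConfig(
                    dt=cfg.dt, t_end=cfg.t_end,
                    seed=(cfg.seed + 1000003 * (2 * i + off) + 1) % (2**31 - 1),
                    record_stride=cfg.record_stride,
                    implicit_tol=cfg.implicit_tol,
                    implicit_max_iter=cfg.implicit_max_iter)
                ev = _fitness_evaluator(spec, [x], "ergodic", probe_cfg, **kwargs)
                y = x.copy()
                y[i] += sgn * step
                vals.append(ev(y).value)
            grad[i] = (vals[0] - vals[1]) / (2.0 * step)
        return grad
    evaluate = _fitness_evaluator(spec, [x], method, config,
                                  resident_traj=resident_traj, **kwargs)
    for i in range(d):
        yp, ym = x.copy(), x.copy()
        yp[i] += step
        ym[i] -= step
        grad[i] = (evaluate(yp).value - evaluate(ym).value) / (2.0 * step)
    return grad


def second_order_coefficients(spec, x, method: str = "closed_form",
                              h: Optional[float] = None,
                              config: Optional[SimulationConfig] = None,
                              **kwargs) -> LocalExpansion:
    """Selection gradient plus the four C matrices at reference strategy
    ``x``, by mixed central differences of s(x', y') = S_{x'}(y').

    Resident-side work is cached per distinct resident stencil point; with a
    fixed-seed config, all stencil evaluations share the same noise path
    (common random numbers). C12 is set to C21 transposed; C11 and C22 are
    symmetrized.
    """
    x = as_strategy(x)
    d = x.size
    step = h if h is not None else _default_h(x)
    cache: dict = {}
    max_se = 0.0

    def s(xp, yp):
        nonlocal max_se
        key = tuple(np.round(xp, 12))
        if key not in cache:
            cache[key] = _fitness_evaluator(spec, [xp], method, config, **kwargs)
        res = cache[key](yp)
        max_se = max(max_se, res.se)
        return res.value

    def shift(v, i, amount):
        out = v.copy()
        out[i] += amount
        return out

    grad = np.zeros(d)
    for i in range(d):
        grad[i] = (s(x, shift(x, i, step)) - s(x, shift(x, i, -step))) / (2 * step)

    s_diag = s(x, x)

    C22 = np.zeros((d, d))
    C11 = np.zeros((d, d))
    C21 = np.zeros((d, d))
    for i in range(d):
        C22[i, i] = 0.5 * (s(x, shift(x, i, step)) - 2 * s_diag
                           + s(x, shift(x, i, -step))) / step**2
        C11[i, i] = 0.5 * (s(shift(x, i, step), x) - 2 * s_diag
                           + s(shift(x, i, -step), x)) / step**2
        for j in range(i + 1, d):
            spp = s(x, shift(shift(x, i, step), j, step))
            spm = s(x, shift(shift(x, i, step), j, -step))
            smp = s(x, shift(shift(x, i, -step), j, step))
            smm = s(x, shift(shift(x, i, -step), j, -step))
            C22[i, j] = C22[j, i] = 0.5 * (spp - spm - smp + smm) / (4 * step**2)
            xpp = s(shift(shift(x, i, step), j, step), x)
            xpm = s(shift(shift(x, i, step), j, -step), x)
            xmp = s(shift(shift(x, i, -step), j, step), x)
            xmm = s(shift(shift(x, i, -step), j, -step), x)
            C11[i, j] = C11[j, i] = 0.5 * (xpp - xpm - xmp + xmm) / (4 * step**2)
    for i in range(d):
        for j in range(d):
            C21[i, j] = 0.5 * (
                s(shift(x, j, step), shift(x, i, step))
                - s(shift(x, j, step), shift(x, i, -step))
                - s(shift(x, j, -step), shift(x, i, step))
                + s(shift(x, j, -step), shift(x, i, -step))
            ) / (4 * step**2)
    C12 = C21.T.copy()
    return LocalExpansion(gradient=grad, C11=C11, C12=C12, C21=C21, C22=C22,
                          h=step, method=method, max_se=max_se)


def expand_fitness_second_order(expansion: LocalExpansion, xi1, xi2,
                                eps: float):
    """Predicted pair (S_{x1}(x2), S_{x2}(x1)) for x_i = x + eps * xi_i,
    from the second-order Taylor expansion of s(x', y') at (x, x).

    Exact for quadratic fitness functions; error O(eps^3) otherwise.
    """
    xi1 = as_strategy(xi1)
    xi2 = as_strategy(xi2)
    g = expansion.gradient
    C11, C21, C22 = expansion.C11, expansion.C21, expansion.C22
    lin = float(g @ (xi2 - xi1)) * eps

    def quad(a, b):
        # second-order part of s(x + eps a, x + eps b)
        return float(a @ C11 @ a + b @ C22 @ b + 2.0 * b @ C21 @ a) * eps**2

    s12 = lin + quad(xi1, xi2)
    s21 = -lin + quad(xi2, xi1)
    return s12, s21


def find_singular_strategy(spec, bracket=None, box=None,
                           method: str = "closed_form",
                           h: Optional[float] = None,
                           config: Optional[SimulationConfig] = None,
                           n_grid: int = 21, n_starts: int = 8,
                           tol: float = 1e-4, **kwargs):
    """Locate strategies where the selection gradient vanishes.

    For 1-d strategies pass ``bracket=(lo, hi)``: the gradient is scanned on
    a grid and each sign change is bisected. For multi-dimensional
    strategies pass ``box=(lo_vec, hi_vec)``: quasi-root-finding from
    multiple random starts, keeping converged distinct roots. Returns a list
    of ``(strategy, residual_norm)`` pairs (empty when no root is found).
    """

    def grad_at(xv):
        return selection_gradient(spec, xv, method=method, h=h, config=config,
                                  **kwargs)

    results = []
    if bracket is not None:
        lo, hi = float(bracket[0]), float(bracket[1])
        grid = np.linspace(lo, hi, n_grid)
        gvals = np.array([grad_at(np.array([g]))[0] for g in grid])
        for i in range(len(grid) - 1):
            if gvals[i] == 0.0:
                results.append((np.array([grid[i]]), 0.0))
            elif gvals[i] * gvals[i + 1] < 0:
                rt = brentq(lambda u: grad_at(np.array([u]))[0],
                            grid[i], grid[i + 1], xtol=1e-10)
                resid = abs(grad_at(np.array([rt]))[0])
                results.append((np.array([rt]), float(resid)))
        return results
    if box is None:
        raise ValueError("provide bracket (1-d) or box (multi-d)")
    lo = np.atleast_1d(np.asarray(box[0], dtype=float))
    hi = np.atleast_1d(np.asarray(box[1], dtype=float))
    rng = np.random.default_rng(0)
    for _ in range(n_starts):
        x0 = lo + (hi - lo) * rng.random(lo.shape)
        sol = root(lambda v: grad_at(v), x0, method="hybr")
        resid = float(np.linalg.norm(grad_at(sol.x)))
        if resid <= tol:
            if not any(np.linalg.norm(sol.x - r[0]) < 1e-6 * (1 + np.linalg.norm(sol.x))
                       for r in results):
                results.append((np.asarray(sol.x, dtype=float), resid))
    return results
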
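"""Dimorphic (total size, relative frequency) simulation and empirical
validation of the fast-slow averaging predictions.

For a similar pair x_i = x + eps * xi_i the dimorphic system is simulated
directly in the variables (N, P) — total population size and relative
frequency of strategy 2 — which is algebraically equivalent to the
two-species simulation but exposes the slow variable P explicitly. With the
same seed, step size and driver, both parameterizations share the same
noise path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .classification import compute_regime_stats
from .invasion import LocalExpansion
from .model_core import Env, SystemState, as_strategy
from .simulate import (
    SimulationConfig,
    Trajectory,
    make_noise_generator,
    solve_env_implicit,
    _env_ode_drift,
    _theta_step,
    _guard,
)

__all__ = [
    "simulate_dimorphic",
    "SlowFastReport",
    "compare_to_averaged",
]


def simulate_dimorphic(spec, x, xi1, xi2, eps: float, init: SystemState,
                       config: SimulationConfig) -> Trajectory:
    """Simulate the dimorphic pair x + eps*xi1, x + eps*xi2 in (N, P)
    variables.

    ``init.n`` must hold the two initial sizes (n1, n2) — class-abundance
    rows for structured models — from which N(0) and P(0) are formed. The
    returned Trajectory stores sizes ``n = [n1, n2] = [(1-P)N, PN]`` so it is
    directly comparable with :func:`simulate_polymorphic` /
    :func:`simulate_structured`; the frequency path is ``traj.n[:, 1] /
    traj.n.sum(axis=1)``. P is clamped to [0, 1] (clamp events counted in
    ``clip_count``). At eps = 0 the frequency P is exactly constant.
    """
    x = as_strategy(x)
    x1 = x + eps * as_strategy(xi1)
    x2 = x + eps * as_strategy(xi2)
    strategies = [x1, x2]
    structured = spec.is_structured
    ell = spec.num_classes if structured else 1
    dt = config.dt
    n_steps = int(round(config.t_end / dt))
    stride = max(1, int(config.record_stride))
    rng = make_noise_generator(config.seed)

    if structured:
        raw = np.asarray(init.n, dtype=float).reshape(2, ell)
        sizes = raw.sum(axis=1)
        v = np.where(sizes[:, None] > 0,
                     raw / np.where(sizes[:, None] > 0, sizes[:, None], 1.0),
                     1.0 / ell)
    else:
        sizes = np.asarray(init.n, dtype=float).reshape(2)
        v = None
    N = float(sizes.sum())
    P = float(sizes[1] / N) if N > 0 else 0.0
    e1 = np.asarray(init.e1, dtype=float).reshape(spec.dim_e1).copy()
    theta = np.asarray(init.theta, dtype=float).reshape(spec.driver.dim_theta).copy()
    e2 = np.asarray(init.e2, dtype=float).reshape(-1)
    if e2.size != spec.dim_e2:
        e2 = np.zeros(spec.dim_e2)

    n_rec = n_steps // stride + 1
    rec_t = np.empty(n_rec)
    rec_n = np.empty((n_rec, 2))
    rec_v = np.empty((n_rec, 2, ell)) if structured else None
    rec_e1 = np.empty((n_rec, spec.dim_e1))
    rec_e2 = np.empty((n_rec, spec.dim_e2))
    rec_th = np.empty((n_rec, spec.driver.dim_theta))
    clamp_count = 0
    renorm_max = 0.0
    ones = np.ones(ell)
    r = 0
    for step in range(n_steps + 1):
        t = step * dt
        sizes = np.array([(1.0 - P) * N, P * N])
        loads = v * sizes[:, None] if structured else sizes
        if spec.dim_e2:
            e2 = solve_env_implicit(spec, loads, strategies, e1, theta, e2,
                                    config.implicit_tol, config.implicit_max_iter)
        env = Env(e1, e2)
        if step % stride == 0:
            rec_t[r] = t
            rec_n[r] = sizes
            if structured:
                rec_v[r] = v
            rec_e1[r] = e1
            rec_e2[r] = e2
            rec_th[r] = theta
            r += 1
        if step == n_steps:
            break
        if structured:
            rates = np.empty(2)
            v_new = v.copy()
            for i, xi in enumerate(strategies):
                F = np.asarray(spec.transition_matrix(xi, env, theta), dtype=float)
                rates[i] = float(ones @ F @ v[i])
                v_new[i] = v[i] + dt * (F @ v[i] - rates[i] * v[i])
            v_new = np.clip(v_new, 0.0, None)
            sums = v_new.sum(axis=1)
            renorm_max = max(renorm_max, float(np.max(np.abs(sums - 1.0))))
            v_new = v_new / np.where(sums[:, None] > 0, sums[:, None], 1.0)
        else:
            rates = np.array([float(spec.growth(xi, env, theta))
                              for xi in strategies])
            v_new = None
        f1, f2 = rates
        N_new = N * (1.0 + dt * ((1.0 - P) * f1 + P * f2))
        P_new = P + dt * P * (1.0 - P) * (f2 - f1)
        if N_new < 0:
            N_new = 0.0
        if P_new < 0.0 or P_new > 1.0:
            clamp_count += 1
            P_new = min(1.0, max(0.0, P_new))
        if spec.dim_e1:
            e1 = e1 + dt * _env_ode_drift(spec, env, theta, strategies, loads,
                                          ell if structured else None)
        theta = _theta_step(spec, theta, dt, rng)
        N, P, v = N_new, P_new, v_new
        _guard(np.array([N]), t + dt, config.overflow_guard)
        _guard(e1, t + dt, config.overflow_guard)
    return Trajectory(times=rec_t[:r], n=rec_n[:r], e1=rec_e1[:r],
                      e2=rec_e2[:r], theta=rec_th[:r], config=config,
                      model_id=spec.name + ":dimorphic",
                      strategies=(x1, x2),
                      structure=rec_v[:r] if structured else None,
                      clip_count=clamp_count, renorm_max=renorm_max)


def frequency_path(traj: Trajectory) -> np.ndarray:
    """Relative frequency of the second strategy along a two-strategy
    trajectory."""
    tot = traj.n.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(tot > 0, traj.n[:, 1] / np.where(tot > 0, tot, 1.0), 0.0)
    return P


@dataclass
class SlowFastReport:
    eps_grid: np.ndarray
    sup_dev: np.ndarray  # per (eps, seed): sup |P - p*| on the second half
    p_star: float
    delta: float
    passes: np.ndarray  # boolean, per (eps, seed)
    regime: str
    seeds: tuple
    horizons: np.ndarray

    @property
    def all_pass_smallest_eps(self) -> bool:
        return bool(np.all(self.passes[-1]))


def compare_to_averaged(spec, x, xi1, xi2, eps_grid, delta: float,
                        config: SimulationConfig,
                        expansion: Optional[LocalExpansion] = None,
                        p_star: Optional[float] = None,
                        regime: Optional[str] = None,
                        p0: float = 0.5,
                        seeds=(0, 1, 2, 3, 4),
                        t_slow: float = 20.0,
                        init: Optional[SystemState] = None,
                        max_steps: int = 20_000_000) -> SlowFastReport:
    """Empirical check that P stays close to the averaged-system prediction.

    For each eps (given in decreasing order) and each seed, the dimorphic
    system is simulated out to slow time ``t_slow`` on the appropriate clock
    (first-order: eps*t; second-order: eps^2*t) and the supremum of
    |P - p*| over the second half of the window is compared with ``delta``.
    """
    from .invasion import expand_fitness_second_order, second_order_coefficients
    from .classification import classify_outcome

    x = as_strategy(x)
    xi1 = as_strategy(xi1)
    xi2 = as_strategy(xi2)
    eps_grid = np.asarray(eps_grid, dtype=float)
    if expansion is None and (p_star is None or regime is None):
        method = "closed_form" if spec.closed_form_fitness is not None else "ergodic"
        expansion = second_order_coefficients(spec, x, method=method,
                                              config=config)
    if regime is None or p_star is None:
        stats = compute_regime_stats(expansion, xi1, xi2)
        eps_ref = float(eps_grid[0])
        S12, S21 = expand_fitness_second_order(expansion, xi1, xi2, eps_ref)
        tol = max(3.0 * expansion.max_se, 1e-10)
        cls = classify_outcome(S12, S21, stats, tol=tol)
        if cls.outcome == "undetermined":
            raise ValueError(
                "undetermined classification; pass p_star and regime explicitly")
        if regime is None:
            regime = "order1" if cls.regime == "order1" else "order2"
        if p_star is None:
            if cls.p_star is None:
                raise ValueError("no unique predicted equilibrium (mutual "
                                 "exclusion); pass p_star explicitly")
            p_star = float(cls.p_star)

    drive = None
    if any(float(e) != 0.0 for e in eps_grid):
        if expansion is None:
            method = ("closed_form" if spec.closed_form_fitness is not None
                      else "ergodic")
            expansion = second_order_coefficients(spec, x, method=method,
                                                  config=config)
        st = compute_regime_stats(expansion, xi1, xi2)
        if regime == "order1":
            drive = abs(st.drive1)
            if not drive:
                raise ValueError("zero first-order drive; use regime='order2'")
        else:
            drive = max(abs(st.quad), abs(st.mixed))
            if not drive:
                raise ValueError("zero second-order drive")

    sup_dev = np.zeros((len(eps_grid), len(seeds)))
    passes = np.zeros((len(eps_grid), len(seeds)), dtype=bool)
    horizons = np.zeros(len(eps_grid))
    for a, eps in enumerate(eps_grid):
        if eps == 0.0:
            sup_dev[a, :] = abs(p0 - p_star)
            passes[a, :] = sup_dev[a, :] <= delta
            horizons[a] = 0.0
            continue
        scale = eps if regime == "order1" else eps * eps
        horizon = t_slow / (drive * scale)
        n_steps = horizon / config.dt
        if n_steps > max_steps:
            horizon = max_steps * config.dt
        horizons[a] = horizon
        for b, seed in enumerate(seeds):
            cfg = SimulationConfig(dt=config.dt, t_end=horizon, seed=int(seed),
                                   record_stride=config.record_stride,
                                   implicit_tol=config.implicit_tol,
                                   implicit_max_iter=config.implicit_max_iter)
            ini = init or _default_dimorphic_init(spec, p0)
            traj = simulate_dimorphic(spec, x, xi1, xi2, float(eps), ini, cfg)
            P = frequency_path(traj)
            half = len(P) // 2
            sup_dev[a, b] = float(np.max(np.abs(P[half:] - p_star)))
            passes[a, b] = sup_dev[a, b] <= delta
    return SlowFastReport(eps_grid=eps_grid, sup_dev=sup_dev,
                          p_star=float(p_star), delta=float(delta),
                          passes=passes, regime=regime, seeds=tuple(seeds),
                          horizons=horizons)


def _default_dimorphic_init(spec, p0: float) -> SystemState:
    if spec.is_structured:
        ell = spec.num_classes
        n = np.vstack([np.full(ell, (1.0 - p0) * 0.5 / ell * 2),
                       np.full(ell, p0 * 0.5 / ell * 2)])
    else:
        n = np.array([(1.0 - p0), p0])
    e1 = np.full(spec.dim_e1, 1.0) if spec.dim_e1 else np.zeros(0)
    e2 = np.full(spec.dim_e2, 1.0) if spec.dim_e2 else np.zeros(0)
    return SystemState(n=n, e1=e1, e2=e2,
                       theta=np.zeros(spec.driver.dim_theta))
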
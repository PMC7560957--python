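"""Ergodic averaging along trajectories, resident diagnostics, and
characterization of deterministic resident attractors (equilibrium /
limit-cycle period / Hopf point).

All expectations against the invariant measure are long-run time averages
with a burn-in; the invariant measure itself is never represented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, fsolve

from .model_core import SystemState, as_strategy
from .simulate import (
    SimulationConfig,
    Trajectory,
    build_deterministic_rhs,
    simulate_polymorphic,
    simulate_structured,
)

__all__ = [
    "batch_mean_se",
    "birkhoff_average",
    "ResidentCheck",
    "resident_diagnostics",
    "PeriodResult",
    "detect_period",
    "find_hopf",
    "HopfNotFoundError",
    "default_initial_state",
]


class HopfNotFoundError(ValueError):
    """No Hopf crossing was found in the requested bracket."""


def batch_mean_se(samples: np.ndarray, n_batches: int = 30):
    """Mean and batch-means standard error of a correlated sample series."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("empty sample series")
    nb = min(n_batches, samples.size)
    m = samples.size // nb
    trimmed = samples[: m * nb].reshape(nb, m)
    bmeans = trimmed.mean(axis=1)
    mean = float(samples.mean())
    if nb < 2:
        return mean, 0.0
    se = float(bmeans.std(ddof=1) / math.sqrt(nb))
    return mean, se


def birkhoff_average(traj, observable: Optional[Callable] = None,
                     burn_in: float = 0.2, n_batches: int = 30):
    """Time average of an observable along a trajectory, with batch-means
    standard error.

    ``traj`` is a :class:`Trajectory` (then ``observable`` maps a
    :class:`SystemState` to a real) or a plain array of pre-computed
    observable samples.
    """
    if not 0.0 <= burn_in < 1.0:
        raise ValueError("burn_in must be in [0, 1)")
    if isinstance(traj, Trajectory):
        if observable is None:
            raise ValueError("an observable is required for a Trajectory input")
        start = int(burn_in * len(traj))
        if start >= len(traj):
            raise ValueError("empty post-burn-in window")
        samples = np.array([float(observable(traj.state_at(i)))
                            for i in range(start, len(traj))])
    else:
        samples = np.asarray(traj, dtype=float).ravel()
        start = int(burn_in * samples.size)
        if start >= samples.size:
            raise ValueError("empty post-burn-in window")
        samples = samples[start:]
        if observable is not None:
            samples = np.array([float(observable(s)) for s in samples])
    return batch_mean_se(samples, n_batches)


def default_initial_state(spec, strategies) -> SystemState:
    """A generic interior initial condition for a fixture."""
    k = len(strategies)
    if spec.is_structured:
        n = np.full((k, spec.num_classes), 0.5)
    else:
        n = np.full(k, 0.5)
    e1 = np.full(spec.dim_e1, 1.0) if spec.dim_e1 else np.zeros(0)
    e2 = np.full(spec.dim_e2, 1.0) if spec.dim_e2 else np.zeros(0)
    theta = np.zeros(spec.driver.dim_theta)
    return SystemState(n=n, e1=e1, e2=e2, theta=theta)


def growth_samples(spec, traj: Trajectory, y, burn_in: float = 0.0):
    """Per-capita growth rate of strategy ``y`` along a recorded trajectory.

    For structured models this integrates the structure vector of ``y``
    along the trajectory and returns its instantaneous log-growth rate of
    total size, which time-averages to the dominant growth rate without ever
    simulating the (possibly vanishing) size itself.
    """
    y = as_strategy(y)
    start = int(burn_in * len(traj))
    if not spec.is_structured:
        return np.array([
            float(spec.growth(y, traj.state_at(i).env, traj.theta[i]))
            for i in range(start, len(traj))
        ])
    ell = spec.num_classes
    ones = np.ones(ell)
    v = np.full(ell, 1.0 / ell)
    out = np.empty(len(traj) - start)
    times = traj.times
    for i in range(start, len(traj)):
        env = traj.state_at(i).env
        F = np.asarray(spec.transition_matrix(y, env, traj.theta[i]), dtype=float)
        rate = float(ones @ F @ v)
        out[i - start] = rate
        if i + 1 < len(traj):
            dt = times[i + 1] - times[i]
            v = v + dt * (F @ v - rate * v)
            v = np.clip(v, 0.0, None)
            s = v.sum()
            v = v / s if s > 0 else np.full(ell, 1.0 / ell)
    return out


@dataclass
class ResidentCheck:
    lambda_hat: float
    lambda_se: float
    occupancy_eta: dict
    verdict: str  # resident | not_resident | inconclusive
    eta_star: float
    eps_star: float
    median_population: float


def resident_diagnostics(spec, x, config: SimulationConfig,
                         eta_grid=None, init: Optional[SystemState] = None,
                         burn_in: float = 0.2,
                         eps_star: float = 0.01) -> ResidentCheck:
    """Check that the monomorphic population with strategy ``x`` is a
    resident: non-growing on the long run (zero time-averaged per-capita
    growth) and stochastically persistent (small occupancy of the
    near-extinction set)."""
    x = as_strategy(x)
    if init is None:
        init = default_initial_state(spec, [x])
    sim = simulate_structured if spec.is_structured else simulate_polymorphic
    traj = sim(spec, [x], init, config)
    samples = growth_samples(spec, traj, x, burn_in=burn_in)
    lam, se = batch_mean_se(samples)

    start = int(burn_in * len(traj))
    minpop = traj.n[start:].min(axis=1)
    median_pop = float(np.median(minpop))
    eta_star = 1e-3 * median_pop
    if eta_grid is None:
        eta_grid = [0.5 * eta_star, eta_star, 2.0 * eta_star, 10.0 * eta_star]
    occupancy = {float(eta): float(np.mean(minpop <= eta)) for eta in eta_grid}
    occ_star = float(np.mean(minpop <= eta_star))

    non_growing = abs(lam) <= 3.0 * se
    persistent = occ_star <= eps_star
    if non_growing and persistent:
        verdict = "resident"
    elif (lam < -3.0 * se) or not persistent:
        verdict = "not_resident"
    else:
        verdict = "inconclusive"
    return ResidentCheck(lambda_hat=lam, lambda_se=se, occupancy_eta=occupancy,
                         verdict=verdict, eta_star=eta_star, eps_star=eps_star,
                         median_population=median_pop)


@dataclass
class PeriodResult:
    kind: str  # equilibrium | periodic | none
    tau: Optional[float] = None
    tau_se: Optional[float] = None
    n_crossings: int = 0
    amplitude: float = 0.0
    message: str = ""
    #: dense samples (times, signal) of the observation window, when available
    window: Optional[tuple] = None
    #: solver end state of the observation window (deterministic input only)
    end_state: Optional[np.ndarray] = None


def _crossing_times(t, s, level):
    """Upward crossings of ``level`` with linear interpolation."""
    below = s[:-1] < level
    above = s[1:] >= level
    idx = np.nonzero(below & above)[0]
    frac = (level - s[idx]) / (s[idx + 1] - s[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def _classify_signal(t, s, equil_rtol=1e-6, period_cv_tol=0.05):
    mean = float(np.mean(s))
    amp = float(np.max(s) - np.min(s))
    if amp <= equil_rtol * (1.0 + abs(mean)):
        return PeriodResult(kind="equilibrium", amplitude=amp)
    crossings = _crossing_times(np.asarray(t), np.asarray(s), mean)
    if len(crossings) < 4:
        return PeriodResult(kind="none", n_crossings=len(crossings),
                            amplitude=amp,
                            message="too few Poincare-section returns")
    periods = np.diff(crossings)
    tau = float(np.mean(periods))
    tau_se = float(periods.std(ddof=1) / math.sqrt(len(periods)))
    if periods.std(ddof=1) > period_cv_tol * tau:
        return PeriodResult(kind="none", n_crossings=len(crossings),
                            amplitude=amp, tau=tau, tau_se=tau_se,
                            message="return times not settled")
    return PeriodResult(kind="periodic", tau=tau, tau_se=tau_se,
                        n_crossings=len(crossings), amplitude=amp)


def detect_period(obj, x=None, transient: float = 1000.0,
                  observe: float = 400.0, init: Optional[SystemState] = None,
                  rtol: float = 1e-10, n_samples: int = 20000) -> PeriodResult:
    """Classify the attractor of a deterministic resident system.

    ``obj`` is either a recorded :class:`Trajectory` (its first population
    coordinate is analyzed after discarding ``transient`` time units) or a
    deterministic model spec, in which case the monomorphic system with
    resident ``x`` is integrated with a high-accuracy adaptive solver. The
    period is estimated from upward crossings of the post-transient mean of
    the first population coordinate, with linear interpolation.
    """
    if isinstance(obj, Trajectory):
        mask = obj.times >= transient
        if not np.any(mask):
            mask = obj.times >= obj.times[-1] / 2.0
        return _classify_signal(obj.times[mask], obj.n[mask, 0])
    spec = obj
    if spec.driver.dim_theta and not spec.driver.is_deterministic:
        raise ValueError("detect_period requires a deterministic model")
    if x is None:
        raise ValueError("a resident strategy x is required for a spec input")
    x = as_strategy(x)
    if init is None:
        init = default_initial_state(spec, [x])
    pack, rhs, _ = build_deterministic_rhs(spec, [x])
    y0 = pack(init)
    sol = solve_ivp(rhs, (0.0, transient), y0, rtol=rtol, atol=1e-12,
                    dense_output=False)
    if not sol.success:
        return PeriodResult(kind="none", message=f"transient solve failed: {sol.message}")
    t_eval = np.linspace(0.0, observe, n_samples)
    sol2 = solve_ivp(rhs, (0.0, observe), sol.y[:, -1], rtol=rtol, atol=1e-12,
                     t_eval=t_eval)
    if not sol2.success:
        return PeriodResult(kind="none", message=f"observation solve failed: {sol2.message}")
    signal = sol2.y[0]
    result = _classify_signal(sol2.t, signal)
    result.window = (sol2.t, sol2.y)
    result.end_state = sol2.y[:, -1]
    return result


def _family_rhs(member, x):
    """Normalize a family member to an autonomous rhs(y) callable."""
    if hasattr(member, "is_structured"):
        _, rhs, _ = build_deterministic_rhs(member, [as_strategy(x)])
        return lambda y: rhs(0.0, y), None
    probe_dims = None

    def rhs(y):
        try:
            return np.asarray(member(y), dtype=float)
        except TypeError:
            return np.asarray(member(0.0, y), dtype=float)

    return rhs, probe_dims


def _jacobian(rhs, y, rel=1e-7):
    d = len(y)
    J = np.zeros((d, d))
    for j in range(d):
        h = rel * (1.0 + abs(y[j]))
        up, um = y.copy(), y.copy()
        up[j] += h
        um[j] -= h
        J[:, j] = (rhs(up) - rhs(um)) / (2.0 * h)
    return J


def find_hopf(model_family: Callable, bracket, xtol: float = 1e-5,
              guess=None, anchor: Optional[float] = None,
              warmup: float = 500.0, n_continuation: int = 15) -> float:
    """Locate the parameter value where the interior equilibrium loses
    stability (maximum real part of its Jacobian eigenvalues crosses zero).

    ``model_family`` maps a scalar parameter to either a model spec (the
    monomorphic deterministic system is used) or a plain vector field
    (``rhs(y)`` or ``rhs(t, y)``). The equilibrium is tracked by a
    continuation of root solves from an anchor parameter; the crossing is
    bisected to ``|dx| <= xtol``.
    """
    if hasattr(model_family, "is_structured"):
        # a bare spec: the bifurcation parameter is the resident strategy
        fixed_spec = model_family
        model_family = lambda _x: fixed_spec
    lo, hi = float(bracket[0]), float(bracket[1])
    if anchor is None:
        anchor = hi
    member0 = model_family(anchor)
    spec_mode = hasattr(member0, "is_structured")

    if spec_mode:
        if guess is None:
            init = default_initial_state(member0, [as_strategy(anchor)])
            pack, rhs0, _ = build_deterministic_rhs(member0, [as_strategy(anchor)])
            sol = solve_ivp(rhs0, (0.0, warmup), pack(init), rtol=1e-8,
                            atol=1e-10)
            guess = sol.y[:, -1]
    else:
        if guess is None:
            guess = np.zeros(2)
    guess = np.asarray(guess, dtype=float)

    eq_anchor = None

    def equilibrium_at(xval):
        nonlocal eq_anchor
        g = guess if eq_anchor is None else eq_anchor
        sol_prev = g
        for xv in np.linspace(anchor, xval, n_continuation):
            rhs, _ = _family_rhs(model_family(xv), xv)
            sol_prev = fsolve(lambda y: rhs(np.asarray(y, dtype=float)),
                              sol_prev, full_output=False)
        return np.asarray(sol_prev, dtype=float)

    def max_real_eig(xval):
        eq = equilibrium_at(xval)
        rhs, _ = _family_rhs(model_family(xval), xval)
        resid = np.linalg.norm(rhs(eq))
        if not np.isfinite(resid) or resid > 1e-6 * (1.0 + np.linalg.norm(eq)):
            raise HopfNotFoundError(
                f"interior equilibrium not locatable at parameter {xval}")
        J = _jacobian(rhs, eq)
        return float(np.max(np.linalg.eigvals(J).real))

    f_lo = max_real_eig(lo)
    f_hi = max_real_eig(hi)
    if f_lo * f_hi > 0:
        raise HopfNotFoundError(
            f"no stability change in bracket [{lo}, {hi}] "
            f"(eigenvalue real parts {f_lo:.3e} and {f_hi:.3e})")
    return float(brentq(max_real_eig, lo, hi, xtol=xtol))
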
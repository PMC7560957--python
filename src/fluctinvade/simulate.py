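"""Numerical integration of the coupled population/environment/driver system.

Populations and the ODE environment component are stepped explicitly
(forward Euler); the driver is stepped by Euler-Maruyama (Ito); the implicit
environment component is re-solved every step with a warm start. Noise is
drawn from a counter-based (Philox) generator, one vector per step, so that
simulations sharing a seed, step size and driver dimension share a noise
path regardless of how the populations are parameterized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize

from .model_core import (
    ConvergenceError,
    DivergenceError,
    Env,
    SystemState,
    UnstructuredModelSpec,
    as_strategy,
)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "solve_env_implicit",
    "simulate_polymorphic",
    "simulate_structured",
    "simulate_structured_raw",
    "build_deterministic_rhs",
    "make_noise_generator",
]


@dataclass(frozen=True)
class SimulationConfig:
    dt: float = 1e-3
    t_end: float = 100.0
    seed: int = 0
    scheme: str = "euler_maruyama"
    implicit_tol: float = 1e-10
    implicit_max_iter: int = 100
    record_stride: int = 1
    overflow_guard: float = 1e12

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.implicit_tol <= 0:
            raise ValueError("implicit_tol must be positive")
        if self.scheme != "euler_maruyama":
            raise ValueError(f"unknown scheme {self.scheme!r}")


def make_noise_generator(seed: int) -> np.random.Generator:
    """Counter-based generator used for all driver noise."""
    return np.random.Generator(np.random.Philox(key=int(seed)))


@dataclass
class Trajectory:
    """Recorded simulation output.

    ``n`` holds population sizes, shape ``(T, k)``; for structured models it
    holds the 1-norms of the class vectors and ``structure`` holds the
    normalized class distributions, shape ``(T, k, l)``.
    """

    times: np.ndarray
    n: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    theta: np.ndarray
    config: SimulationConfig
    model_id: str = ""
    strategies: tuple = ()
    structure: Optional[np.ndarray] = None
    clip_count: int = 0
    renorm_max: float = 0.0

    def __len__(self):
        return len(self.times)

    def state_at(self, i: int) -> SystemState:
        if self.structure is not None:
            n = self.structure[i] * self.n[i][:, None]
        else:
            n = self.n[i]
        return SystemState(n=n, e1=self.e1[i], e2=self.e2[i],
                           theta=self.theta[i], t=float(self.times[i]))

    def states(self):
        for i in range(len(self.times)):
            yield self.state_at(i)

    def to_csv(self, path):
        import pandas as pd

        cols = {"t": self.times}
        for i in range(self.n.shape[1]):
            cols[f"n_{i}"] = self.n[:, i]
        if self.structure is not None:
            for i in range(self.structure.shape[1]):
                for j in range(self.structure.shape[2]):
                    cols[f"v_{i}_{j}"] = self.structure[:, i, j]
        for j in range(self.e1.shape[1]):
            cols[f"e1_{j}"] = self.e1[:, j]
        for j in range(self.e2.shape[1]):
            cols[f"e2_{j}"] = self.e2[:, j]
        for j in range(self.theta.shape[1]):
            cols[f"theta_{j}"] = self.theta[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)
        meta = {
            "model_id": self.model_id,
            "strategies": [list(np.atleast_1d(s)) for s in self.strategies],
            "config": asdict(self.config),
            "clip_count": int(self.clip_count),
            "renorm_max": float(self.renorm_max),
        }
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @staticmethod
    def from_csv(path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path)
        with open(str(path) + ".meta.json") as fh:
            meta = json.load(fh)

        def block(prefix):
            names = [c for c in df.columns if c.startswith(prefix)]
            names.sort(key=lambda c: [int(p) for p in c[len(prefix):].split("_")])
            return df[names].to_numpy() if names else np.zeros((len(df), 0))

        n = block("n_")
        vcols = [c for c in df.columns if c.startswith("v_")]
        structure = None
        if vcols:
            k = n.shape[1]
            ell = len(vcols) // k
            structure = np.zeros((len(df), k, ell))
            for i in range(k):
                for j in range(ell):
                    structure[:, i, j] = df[f"v_{i}_{j}"].to_numpy()
        return Trajectory(
            times=df["t"].to_numpy(),
            n=n,
            e1=block("e1_"),
            e2=block("e2_"),
            theta=block("theta_"),
            config=SimulationConfig(**meta["config"]),
            model_id=meta["model_id"],
            strategies=tuple(np.asarray(s) for s in meta["strategies"]),
            structure=structure,
            clip_count=meta.get("clip_count", 0),
            renorm_max=meta.get("renorm_max", 0.0),
        )


def _impact_matrix(raw, dim_e, n_classes):
    arr = np.atleast_1d(np.asarray(raw, dtype=float))
    if n_classes is None:
        return arr.reshape(dim_e)
    if arr.ndim == 1:
        return arr.reshape(1, n_classes) if dim_e == 1 else arr.reshape(dim_e, n_classes)
    return arr.reshape(dim_e, n_classes)


def solve_env_implicit(spec, n, strategies, e1, theta, guess,
                       tol: float = 1e-10, max_iter: int = 100) -> np.ndarray:
    """Solve ``e2 = G2(e, theta) + sum_j H2(x_j, e, theta) load_j``.

    ``n`` carries the per-strategy loads: scalars for unstructured models and
    class vectors for structured ones. If the right-hand side does not depend
    on ``e2`` the explicit evaluation is returned after a single verification
    pass; otherwise a damped fixed-point iteration is used, with one
    root-solver fallback before reporting non-convergence.
    """
    if spec.dim_e2 == 0:
        return np.zeros(0)
    if spec.env_tracks_populations:
        return np.asarray(n, dtype=float).reshape(spec.dim_e2).copy()
    e1 = np.atleast_1d(np.asarray(e1, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    strategies = [as_strategy(s) for s in strategies]
    n_classes = spec.num_classes if spec.is_structured else None
    loads = [np.atleast_1d(np.asarray(nj, dtype=float)) for nj in n]

    def rhs(e2):
        env = Env(e1, e2)
        out = np.zeros(spec.dim_e2)
        if spec.env_implicit_intrinsic is not None:
            out += np.atleast_1d(
                np.asarray(spec.env_implicit_intrinsic(env, theta), dtype=float)
            )
        if spec.env_implicit_impact is not None:
            for x, load in zip(strategies, loads):
                h = _impact_matrix(spec.env_implicit_impact(x, env, theta),
                                   spec.dim_e2, n_classes)
                out += h @ load if n_classes is not None else h * float(load[0])
        return out

    guess = np.atleast_1d(np.asarray(guess, dtype=float)).copy()
    e2 = rhs(guess)
    check = rhs(e2)
    if np.linalg.norm(check - e2) <= tol:
        return check
    # damped fixed-point iteration
    omega = 0.5
    for _ in range(max_iter):
        e2_new = (1 - omega) * e2 + omega * rhs(e2)
        if np.linalg.norm(e2_new - rhs(e2_new)) <= tol:
            return e2_new
        e2 = e2_new
    sol = optimize.root(lambda v: v - rhs(v), e2, tol=tol)
    resid = np.linalg.norm(sol.x - rhs(sol.x))
    if resid <= max(tol, 1e3 * np.finfo(float).eps * (1 + np.linalg.norm(sol.x))):
        return sol.x
    raise ConvergenceError(
        f"implicit environment solve did not converge (residual {resid:.3e})"
    )


def _env_ode_drift(spec, env, theta, strategies, loads, n_classes):
    """Right-hand side of the e1 ODE: G1 + sum_j H1(x_j) load_j."""
    out = np.zeros(spec.dim_e1)
    if spec.env_ode_intrinsic is not None:
        out += np.atleast_1d(
            np.asarray(spec.env_ode_intrinsic(env, theta), dtype=float)
        )
    if spec.env_ode_impact is not None:
        for x, load in zip(strategies, loads):
            h = _impact_matrix(spec.env_ode_impact(x, env, theta),
                               spec.dim_e1, n_classes)
            out += h @ load if n_classes is not None else h * float(np.atleast_1d(load)[0])
    return out


def _theta_step(spec, theta, dt, rng):
    drv = spec.driver
    if drv.dim_theta == 0:
        return theta
    new = theta + dt * np.atleast_1d(np.asarray(drv.drift(theta), dtype=float))
    if drv.dim_noise and drv.diffusion is not None:
        dw = np.sqrt(dt) * rng.standard_normal(drv.dim_noise)
        B = np.atleast_2d(np.asarray(drv.diffusion(theta), dtype=float))
        new = new + B @ dw
    return new


def _guard(value, t, guard):
    if not np.all(np.isfinite(value)) or np.any(np.abs(value) > guard):
        raise DivergenceError(f"state exceeded overflow guard at t={t:.6g}")


def simulate_polymorphic(spec: UnstructuredModelSpec, strategies,
                         init: SystemState, config: SimulationConfig) -> Trajectory:
    """Integrate the unstructured polymorphic system."""
    if spec.is_structured:
        raise TypeError("use simulate_structured for structured models")
    strategies = [as_strategy(s) for s in strategies]
    k = len(strategies)
    dt = config.dt
    n_steps = int(round(config.t_end / dt))
    stride = max(1, int(config.record_stride))
    rng = make_noise_generator(config.seed)

    n = np.asarray(init.n, dtype=float).reshape(k).copy()
    e1 = np.asarray(init.e1, dtype=float).reshape(spec.dim_e1).copy()
    theta = np.asarray(init.theta, dtype=float).reshape(spec.driver.dim_theta).copy()
    e2 = np.asarray(init.e2, dtype=float).reshape(-1)
    if e2.size != spec.dim_e2:
        e2 = np.zeros(spec.dim_e2)

    n_rec = n_steps // stride + 1
    rec_t = np.empty(n_rec)
    rec_n = np.empty((n_rec, k))
    rec_e1 = np.empty((n_rec, spec.dim_e1))
    rec_e2 = np.empty((n_rec, spec.dim_e2))
    rec_th = np.empty((n_rec, spec.driver.dim_theta))
    clip_count = 0
    r = 0
    for step in range(n_steps + 1):
        t = step * dt
        if spec.dim_e2:
            e2 = solve_env_implicit(spec, n, strategies, e1, theta, e2,
                                    config.implicit_tol, config.implicit_max_iter)
        env = Env(e1, e2)
        if step % stride == 0:
            rec_t[r] = t
            rec_n[r] = n
            rec_e1[r] = e1
            rec_e2[r] = e2
            rec_th[r] = theta
            r += 1
        if step == n_steps:
            break
        fs = np.array([float(spec.growth(x, env, theta)) for x in strategies])
        n_new = n * (1.0 + dt * fs)
        neg = n_new < 0
        if np.any(neg):
            clip_count += int(np.count_nonzero(neg))
            n_new = np.where(neg, 0.0, n_new)
        if spec.dim_e1:
            e1 = e1 + dt * _env_ode_drift(spec, env, theta, strategies, n, None)
        theta = _theta_step(spec, theta, dt, rng)
        n = n_new
        _guard(n, t + dt, config.overflow_guard)
        _guard(e1, t + dt, config.overflow_guard)
    return Trajectory(times=rec_t[:r], n=rec_n[:r], e1=rec_e1[:r],
                      e2=rec_e2[:r], theta=rec_th[:r], config=config,
                      model_id=spec.name, strategies=tuple(strategies),
                      clip_count=clip_count)


def simulate_structured(spec, strategies, init: SystemState,
                        config: SimulationConfig) -> Trajectory:
    """Integrate a structured model in (size, structure) variables.

    ``init.n`` holds per-strategy class abundances, shape ``(k, l)``. Each
    structure vector is renormalized onto the probability simplex every step;
    the largest renormalization applied is reported as ``renorm_max``.
    """
    if not spec.is_structured:
        raise TypeError("use simulate_polymorphic for unstructured models")
    strategies = [as_strategy(s) for s in strategies]
    k = len(strategies)
    ell = spec.num_classes
    dt = config.dt
    n_steps = int(round(config.t_end / dt))
    stride = max(1, int(config.record_stride))
    rng = make_noise_generator(config.seed)

    raw = np.asarray(init.n, dtype=float).reshape(k, ell)
    N = raw.sum(axis=1)
    v = np.where(N[:, None] > 0, raw / np.where(N[:, None] > 0, N[:, None], 1.0),
                 1.0 / ell)
    e1 = np.asarray(init.e1, dtype=float).reshape(spec.dim_e1).copy()
    theta = np.asarray(init.theta, dtype=float).reshape(spec.driver.dim_theta).copy()
    e2 = np.asarray(init.e2, dtype=float).reshape(-1)
    if e2.size != spec.dim_e2:
        e2 = np.zeros(spec.dim_e2)

    n_rec = n_steps // stride + 1
    rec_t = np.empty(n_rec)
    rec_n = np.empty((n_rec, k))
    rec_v = np.empty((n_rec, k, ell))
    rec_e1 = np.empty((n_rec, spec.dim_e1))
    rec_e2 = np.empty((n_rec, spec.dim_e2))
    rec_th = np.empty((n_rec, spec.driver.dim_theta))
    clip_count = 0
    renorm_max = 0.0
    ones = np.ones(ell)
    r = 0
    for step in range(n_steps + 1):
        t = step * dt
        loads = v * N[:, None]
        if spec.dim_e2:
            e2 = solve_env_implicit(spec, loads, strategies, e1, theta, e2,
                                    config.implicit_tol, config.implicit_max_iter)
        env = Env(e1, e2)
        if step % stride == 0:
            rec_t[r] = t
            rec_n[r] = N
            rec_v[r] = v
            rec_e1[r] = e1
            rec_e2[r] = e2
            rec_th[r] = theta
            r += 1
        if step == n_steps:
            break
        N_new = N.copy()
        v_new = v.copy()
        for i, x in enumerate(strategies):
            F = np.asarray(spec.transition_matrix(x, env, theta), dtype=float)
            rate = float(ones @ F @ v[i])
            N_new[i] = N[i] * (1.0 + dt * rate)
            v_new[i] = v[i] + dt * (F @ v[i] - rate * v[i])
        neg = N_new < 0
        if np.any(neg):
            clip_count += int(np.count_nonzero(neg))
            N_new = np.where(neg, 0.0, N_new)
        v_new = np.clip(v_new, 0.0, None)
        sums = v_new.sum(axis=1)
        renorm_max = max(renorm_max, float(np.max(np.abs(sums - 1.0))))
        v_new = v_new / np.where(sums[:, None] > 0, sums[:, None], 1.0)
        if spec.dim_e1:
            e1 = e1 + dt * _env_ode_drift(spec, env, theta, strategies, loads, ell)
        theta = _theta_step(spec, theta, dt, rng)
        N, v = N_new, v_new
        _guard(N, t + dt, config.overflow_guard)
        _guard(e1, t + dt, config.overflow_guard)
    return Trajectory(times=rec_t[:r], n=rec_n[:r], e1=rec_e1[:r],
                      e2=rec_e2[:r], theta=rec_th[:r], config=config,
                      model_id=spec.name, strategies=tuple(strategies),
                      structure=rec_v[:r], clip_count=clip_count,
                      renorm_max=renorm_max)


def simulate_structured_raw(spec, strategies, init: SystemState,
                            config: SimulationConfig) -> Trajectory:
    """Integrate a structured model directly in class abundances.

    Reference implementation used to check the algebraic equivalence of the
    raw class dynamics and the (size, structure) decomposition.
    """
    strategies = [as_strategy(s) for s in strategies]
    k = len(strategies)
    ell = spec.num_classes
    dt = config.dt
    n_steps = int(round(config.t_end / dt))
    stride = max(1, int(config.record_stride))
    rng = make_noise_generator(config.seed)

    raw = np.asarray(init.n, dtype=float).reshape(k, ell).copy()
    e1 = np.asarray(init.e1, dtype=float).reshape(spec.dim_e1).copy()
    theta = np.asarray(init.theta, dtype=float).reshape(spec.driver.dim_theta).copy()
    e2 = np.asarray(init.e2, dtype=float).reshape(-1)
    if e2.size != spec.dim_e2:
        e2 = np.zeros(spec.dim_e2)

    n_rec = n_steps // stride + 1
    rec_t = np.empty(n_rec)
    rec_n = np.empty((n_rec, k))
    rec_v = np.empty((n_rec, k, ell))
    rec_e1 = np.empty((n_rec, spec.dim_e1))
    rec_e2 = np.empty((n_rec, spec.dim_e2))
    rec_th = np.empty((n_rec, spec.driver.dim_theta))
    clip_count = 0
    r = 0
    for step in range(n_steps + 1):
        t = step * dt
        if spec.dim_e2:
            e2 = solve_env_implicit(spec, raw, strategies, e1, theta, e2,
                                    config.implicit_tol, config.implicit_max_iter)
        env = Env(e1, e2)
        if step % stride == 0:
            N = raw.sum(axis=1)
            rec_t[r] = t
            rec_n[r] = N
            rec_v[r] = np.where(N[:, None] > 0,
                                raw / np.where(N[:, None] > 0, N[:, None], 1.0),
                                1.0 / ell)
            rec_e1[r] = e1
            rec_e2[r] = e2
            rec_th[r] = theta
            r += 1
        if step == n_steps:
            break
        raw_new = raw.copy()
        for i, x in enumerate(strategies):
            F = np.asarray(spec.transition_matrix(x, env, theta), dtype=float)
            raw_new[i] = raw[i] + dt * (F @ raw[i])
        neg = raw_new < 0
        if np.any(neg):
            clip_count += int(np.count_nonzero(neg))
            raw_new = np.where(neg, 0.0, raw_new)
        if spec.dim_e1:
            e1 = e1 + dt * _env_ode_drift(spec, env, theta, strategies, raw, ell)
        theta = _theta_step(spec, theta, dt, rng)
        raw = raw_new
        _guard(raw, t + dt, config.overflow_guard)
        _guard(e1, t + dt, config.overflow_guard)
    return Trajectory(times=rec_t[:r], n=rec_n[:r], e1=rec_e1[:r],
                      e2=rec_e2[:r], theta=rec_th[:r], config=config,
                      model_id=spec.name + ":raw", strategies=tuple(strategies),
                      structure=rec_v[:r], clip_count=clip_count)


def build_deterministic_rhs(spec, strategies, implicit_tol: float = 1e-12):
    """Build (pack, rhs, unpack) for the deterministic skeleton of a model.

    The driver is frozen at theta = 0 (valid for models with no driver or as
    the noise-free skeleton of a driven model). The packed state is
    ``concat(populations, e1)``: population sizes for unstructured models and
    flattened class abundances for structured ones. The implicit environment
    component is re-solved inside the right-hand side (warm-started).
    """
    strategies = [as_strategy(s) for s in strategies]
    k = len(strategies)
    theta = np.zeros(spec.driver.dim_theta)
    structured = spec.is_structured
    ell = spec.num_classes if structured else 1
    npop = k * ell
    warm = {"e2": np.zeros(spec.dim_e2)}

    def pack(state: SystemState) -> np.ndarray:
        n = np.asarray(state.n, dtype=float).reshape(npop if structured else k)
        return np.concatenate([n.ravel(), np.asarray(state.e1, dtype=float).reshape(spec.dim_e1)])

    def unpack(y: np.ndarray) -> SystemState:
        n = y[:npop].reshape(k, ell) if structured else y[:k]
        e1 = y[npop:npop + spec.dim_e1] if structured else y[k:k + spec.dim_e1]
        n_clip = np.clip(n, 0.0, None)
        loads = n_clip if structured else n_clip
        e2 = (solve_env_implicit(spec, loads, strategies, e1, theta, warm["e2"],
                                 implicit_tol)
              if spec.dim_e2 else np.zeros(0))
        warm["e2"] = e2
        return SystemState(n=n_clip, e1=e1, e2=e2, theta=theta)

    def rhs(t, y):
        state = unpack(y)
        env = state.env
        if structured:
            dn = np.empty((k, ell))
            for i, x in enumerate(strategies):
                F = np.asarray(spec.transition_matrix(x, env, theta), dtype=float)
                dn[i] = F @ state.n[i]
            loads = state.n
            n_classes = ell
        else:
            fs = np.array([float(spec.growth(x, env, theta)) for x in strategies])
            dn = fs * state.n
            loads = state.n
            n_classes = None
        de1 = (_env_ode_drift(spec, env, theta, strategies, loads, n_classes)
               if spec.dim_e1 else np.zeros(0))
        return np.concatenate([np.asarray(dn, dtype=float).ravel(), de1])

    return pack, rhs, unpack
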
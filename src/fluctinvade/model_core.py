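"""Core model definitions: strategy-indexed population models with
environmental feedback and a stochastic external driver.

A model couples
  * per-capita growth of each strategy-indexed (sub)population,
  * an ODE-driven environment component ``e1``,
  * an implicitly defined environment component ``e2``,
  * an autonomous stochastic driver ``theta`` (an SDE, unaffected by the
    populations).

Unstructured populations are scalars per strategy; structured populations
carry a class vector per strategy and a transition-rate matrix instead of a
scalar growth rate.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Env",
    "DriverSpec",
    "UnstructuredModelSpec",
    "StructuredModelSpec",
    "SystemState",
    "ValidationIssue",
    "ValidationReport",
    "validate_model",
    "ModelError",
    "ConvergenceError",
    "DivergenceError",
    "as_strategy",
]


class ModelError(Exception):
    """Base class for model/simulation errors."""


class ConvergenceError(ModelError):
    """An iterative solver failed to reach its tolerance."""


class DivergenceError(ModelError):
    """A simulated state exceeded the overflow guard."""


#: Environment value passed to model callables: ``env.e1`` and ``env.e2`` are
#: 1-d arrays (possibly empty).
Env = namedtuple("Env", ["e1", "e2"])


def as_strategy(x) -> np.ndarray:
    """Coerce a scalar or sequence to a 1-d float strategy vector."""
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValueError("strategy must be a scalar or 1-d vector")
    return arr


@dataclass(frozen=True)
class DriverSpec:
    """Autonomous SDE driver d(theta) = drift(theta) dt + diffusion(theta) dW.

    ``drift(theta) -> (dim_theta,)`` and ``diffusion(theta) ->
    (dim_theta, dim_noise)``.
    """

    drift: Optional[Callable[[np.ndarray], np.ndarray]]
    diffusion: Optional[Callable[[np.ndarray], np.ndarray]]
    dim_theta: int = 0
    dim_noise: int = 0

    @staticmethod
    def none() -> "DriverSpec":
        """No driver (deterministic model)."""
        return DriverSpec(drift=None, diffusion=None, dim_theta=0, dim_noise=0)

    @staticmethod
    def ou(a: float, b: float) -> "DriverSpec":
        """Scalar Ornstein-Uhlenbeck driver d(theta) = -a theta dt + b dW.

        Stationary distribution N(0, b^2/(2a));
        E[exp(rho * theta)] = exp(rho^2 b^2 / (4 a)).
        """
        a = float(a)
        b = float(b)
        return DriverSpec(
            drift=lambda th: -a * th,
            diffusion=lambda th: np.array([[b]]),
            dim_theta=1,
            dim_noise=1,
        )

    @property
    def is_deterministic(self) -> bool:
        return self.dim_theta == 0 or self.diffusion is None


@dataclass
class UnstructuredModelSpec:
    """Unstructured population model.

    Dynamics for strategies ``x_1..x_k`` with sizes ``n_1..n_k``::

        dn_i/dt = f(x_i, e, theta) * n_i
        de1/dt  = G1(e, theta) + sum_j H1(x_j, e, theta) * n_j
        e2      = G2(e, theta) + sum_j H2(x_j, e, theta) * n_j   (implicit)
        dtheta  = A(theta) dt + B(theta) dW

    ``growth`` is ``f``; the four environment callables are ``G1, H1, G2, H2``
    (any may be ``None`` when the corresponding component is absent).
    """

    growth: Optional[Callable] = None
    driver: DriverSpec = field(default_factory=DriverSpec.none)
    dim_e1: int = 0
    dim_e2: int = 0
    env_ode_intrinsic: Optional[Callable] = None  # G1(env, theta) -> (dim_e1,)
    env_ode_impact: Optional[Callable] = None  # H1(x, env, theta) -> (dim_e1,)
    env_implicit_intrinsic: Optional[Callable] = None  # G2(env, theta) -> (dim_e2,)
    env_implicit_impact: Optional[Callable] = None  # H2(x, env, theta) -> (dim_e2,)
    closed_form_fitness: Optional[Callable] = None  # (x, y) -> float
    dim_strategy: int = 1
    name: str = "unstructured"
    #: When True, e2 is (by construction) the vector of population sizes of the
    #: community members listed in ``community_strategies``; the simulator then
    #: sets e2 = n directly and ``growth`` may depend on those strategies.
    env_tracks_populations: bool = False
    community_strategies: Optional[tuple] = None
    #: Documented state box for validation probes, dict of field -> (lo, hi).
    default_probe_box: Optional[dict] = None

    @property
    def is_structured(self) -> bool:
        return False


@dataclass
class StructuredModelSpec:
    """Structured population model with ``num_classes`` i-states per strategy.

    Per-strategy class-abundance vectors ``n_i`` follow
    ``dn_i/dt = F(x_i, e, theta) n_i`` with an ``l x l`` transition-rate
    matrix ``F``; environment and driver are as in
    :class:`UnstructuredModelSpec` except that ``H1`` and ``H2`` return
    per-class impact rows (shape ``(dim_e, l)`` or ``(l,)`` when the
    environment component is scalar), contracted against the class vector.
    """

    transition_matrix: Callable = None  # F(x, env, theta) -> (l, l)
    num_classes: int = 2
    driver: DriverSpec = field(default_factory=DriverSpec.none)
    dim_e1: int = 0
    dim_e2: int = 0
    env_ode_intrinsic: Optional[Callable] = None
    env_ode_impact: Optional[Callable] = None
    env_implicit_intrinsic: Optional[Callable] = None
    env_implicit_impact: Optional[Callable] = None
    closed_form_fitness: Optional[Callable] = None
    dim_strategy: int = 1
    name: str = "structured"
    env_tracks_populations: bool = False
    community_strategies: Optional[tuple] = None
    default_probe_box: Optional[dict] = None

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError(
                "StructuredModelSpec requires num_classes >= 2; "
                "use UnstructuredModelSpec for a single class"
            )

    @property
    def is_structured(self) -> bool:
        return True


@dataclass
class SystemState:
    """Full system state at one time.

    ``n`` has shape ``(k,)`` for unstructured models and ``(k, l)`` (class
    abundances per strategy) for structured models.
    """

    n: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    theta: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=float)
        self.e1 = np.atleast_1d(np.asarray(self.e1, dtype=float))
        self.e2 = np.atleast_1d(np.asarray(self.e2, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if np.any(self.n < 0):
            raise ValueError("population sizes must be non-negative")

    @property
    def env(self) -> Env:
        return Env(self.e1, self.e2)


@dataclass
class ValidationIssue:
    field: str
    message: str
    point: Optional[dict] = None


@dataclass
class ValidationReport:
    ok: bool
    issues: list
    n_probes: int

    def __bool__(self):
        return self.ok


def _midpoint(bounds):
    lo, hi = (np.atleast_1d(np.asarray(v, dtype=float)) for v in bounds)
    return 0.5 * (lo + hi)


def _sample_points(bounds, m, rng):
    lo, hi = (np.atleast_1d(np.asarray(v, dtype=float)) for v in bounds)
    return [lo + (hi - lo) * rng.random(lo.shape) for _ in range(m)]


def _check_vector(value, length, fieldname, issues):
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.shape != (length,):
        issues.append(
            ValidationIssue(
                field=fieldname,
                message=f"expected shape ({length},), got {arr.shape}",
            )
        )
        return None
    return arr


def _check_impact(value, dim_e, n_classes, fieldname, issues):
    """Impact shapes: (dim_e,) unstructured; (dim_e, l) or (l,) structured."""
    arr = np.asarray(value, dtype=float)
    if n_classes is None:
        return _check_vector(arr, dim_e, fieldname, issues)
    arr = np.atleast_1d(arr)
    if arr.shape == (n_classes,) and dim_e == 1:
        return arr.reshape(1, n_classes)
    if arr.shape != (dim_e, n_classes):
        issues.append(
            ValidationIssue(
                field=fieldname,
                message=(
                    f"expected shape ({dim_e}, {n_classes}) or ({n_classes},),"
                    f" got {arr.shape}"
                ),
            )
        )
        return None
    return arr


def validate_model(spec, probe_box: Optional[dict] = None, n_points: int = 3,
                   seed: int = 0, fd_rel_step: float = 1e-5) -> ValidationReport:
    """Probe a model spec for shape consistency and smoothness.

    ``probe_box`` maps field names (``'x'``, ``'n'``, ``'e1'``, ``'e2'``,
    ``'theta'``) to ``(lo, hi)`` bounds; defaults to
    ``spec.default_probe_box``. Finite-difference probes of the growth rate
    (or transition matrix) are taken up to second order in both the strategy
    and the environment; non-finite outputs are reported as issues.
    """
    if probe_box is None:
        probe_box = spec.default_probe_box
    if probe_box is None:
        raise ValueError("no probe_box given and the spec declares no default")
    rng = np.random.default_rng(seed)
    issues: list = []
    n_probes = 0

    structured = spec.is_structured
    n_classes = spec.num_classes if structured else None
    if spec.dim_strategy and "x" in probe_box:
        xs = _sample_points(probe_box["x"], n_points, rng)
    else:
        xs = [np.zeros(spec.dim_strategy)]
    e1s = (
        _sample_points(probe_box["e1"], n_points, rng)
        if spec.dim_e1 and "e1" in probe_box
        else [np.zeros(spec.dim_e1)]
    )
    e2s = (
        _sample_points(probe_box["e2"], n_points, rng)
        if spec.dim_e2 and "e2" in probe_box
        else [np.zeros(spec.dim_e2)]
    )
    ths = (
        _sample_points(probe_box["theta"], n_points, rng)
        if spec.driver.dim_theta and "theta" in probe_box
        else [np.zeros(spec.driver.dim_theta)]
    )

    def rate_fn(x, env, th):
        if structured:
            return np.asarray(spec.transition_matrix(x, env, th), dtype=float)
        return float(spec.growth(x, env, th))

    # Shape checks at the box midpoints.
    x0 = _midpoint(probe_box["x"]) if "x" in probe_box else np.zeros(spec.dim_strategy)
    env0 = Env(
        _midpoint(probe_box["e1"]) if spec.dim_e1 and "e1" in probe_box else np.zeros(spec.dim_e1),
        _midpoint(probe_box["e2"]) if spec.dim_e2 and "e2" in probe_box else np.zeros(spec.dim_e2),
    )
    th0 = (
        _midpoint(probe_box["theta"])
        if spec.driver.dim_theta and "theta" in probe_box
        else np.zeros(spec.driver.dim_theta)
    )
    if structured:
        try:
            F0 = np.asarray(spec.transition_matrix(x0, env0, th0), dtype=float)
            if F0.shape != (n_classes, n_classes):
                issues.append(
                    ValidationIssue(
                        "transition_matrix",
                        f"expected shape ({n_classes}, {n_classes}), got {F0.shape}",
                    )
                )
        except Exception as exc:  # structural failure
            issues.append(ValidationIssue("transition_matrix", f"raised {exc!r}"))
    elif spec.growth is not None:
        try:
            f0 = spec.growth(x0, env0, th0)
            float(f0)
        except Exception as exc:
            issues.append(ValidationIssue("growth", f"raised {exc!r}"))
    if spec.dim_e1:
        if spec.env_ode_intrinsic is not None:
            _check_vector(spec.env_ode_intrinsic(env0, th0), spec.dim_e1,
                          "env_ode_intrinsic", issues)
        if spec.env_ode_impact is not None:
            _check_impact(spec.env_ode_impact(x0, env0, th0), spec.dim_e1,
                          n_classes, "env_ode_impact", issues)
    if spec.dim_e2 and not spec.env_tracks_populations:
        if spec.env_implicit_intrinsic is not None:
            _check_vector(spec.env_implicit_intrinsic(env0, th0), spec.dim_e2,
                          "env_implicit_intrinsic", issues)
        if spec.env_implicit_impact is not None:
            _check_impact(spec.env_implicit_impact(x0, env0, th0), spec.dim_e2,
                          n_classes, "env_implicit_impact", issues)
    if spec.driver.dim_theta:
        d0 = _check_vector(spec.driver.drift(th0), spec.driver.dim_theta,
                           "driver.drift", issues)
        B0 = np.atleast_2d(np.asarray(spec.driver.diffusion(th0), dtype=float))
        if B0.shape != (spec.driver.dim_theta, spec.driver.dim_noise):
            issues.append(
                ValidationIssue(
                    "driver.diffusion",
                    f"expected shape ({spec.driver.dim_theta}, "
                    f"{spec.driver.dim_noise}), got {B0.shape}",
                )
            )
        del d0

    # Finite-difference probes of the growth rate / transition matrix up to
    # second order in x and in e, at sampled interior points.
    if (structured and spec.transition_matrix is not None) or (
        not structured and spec.growth is not None
    ):
        for x in xs:
            for e1 in e1s:
                for e2 in e2s:
                    for th in ths:
                        env = Env(e1, e2)
                        point = {"x": x, "e1": e1, "e2": e2, "theta": th}
                        try:
                            base = rate_fn(x, env, th)
                        except Exception as exc:
                            issues.append(
                                ValidationIssue("growth", f"raised {exc!r}",
                                                point=point))
                            continue
                        vals = [np.asarray(base)]
                        # second-order stencils in each x and e1/e2 direction
                        for which, vec in (("x", x), ("e1", e1), ("e2", e2)):
                            for j in range(vec.size):
                                h = fd_rel_step * (1.0 + abs(vec[j]))
                                for s in (-1.0, 1.0):
                                    pert = vec.copy()
                                    pert[j] += s * h
                                    if which == "x":
                                        v = rate_fn(pert, env, th)
                                    elif which == "e1":
                                        v = rate_fn(x, Env(pert, e2), th)
                                    else:
                                        v = rate_fn(x, Env(e1, pert), th)
                                    vals.append(np.asarray(v))
                        n_probes += len(vals)
                        stacked = np.concatenate([v.ravel() for v in vals])
                        if not np.all(np.isfinite(stacked)):
                            issues.append(
                                ValidationIssue(
                                    "growth" if not structured else "transition_matrix",
                                    "non-finite value in probe stencil",
                                    point=point,
                                )
                            )
    return ValidationReport(ok=not issues, issues=issues, n_probes=n_probes)
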
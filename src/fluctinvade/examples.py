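"""Built-in example models, fully parameterized with their published
default values, plus closed-form or semi-analytic invasion-fitness
overrides.

Fixtures
--------
chemostat
    Bacteria competing for a single resource in a chemostat whose inflow
    concentration fluctuates with an Ornstein-Uhlenbeck driver. Strategy
    ``x = (beta, gamma, delta)`` (uptake, yield, death).
lotka_volterra
    Stochastic Lotka-Volterra competition along a 1-d trait axis; growth
    rate and carrying capacity fluctuate with a shared OU driver;
    competition acts through a trait-dependent kernel.
sirs
    Structured SIRS epidemic model (classes: infected, recovered) for the
    evolution of a viral trait; the transmission rate fluctuates with an OU
    driver.
prey_predator
    Deterministic prey-predator model for the evolution of prey timidity;
    the resident attractor is a limit cycle for low timidity.
analytic
    A user-chosen two-argument fitness function s(x, y) with s(x, x) = 0,
    exposed directly as ``closed_form_fitness`` — the unit-test workhorse
    for derivative extraction and classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.linalg import solve_continuous_lyapunov
from scipy.optimize import brentq

from .model_core import (
    DriverSpec,
    Env,
    StructuredModelSpec,
    UnstructuredModelSpec,
    as_strategy,
)

__all__ = [
    "FixtureParams",
    "DEFAULTS",
    "make_example_model",
    "chemostat_closed_form_fitness",
    "lv_closed_form_fitness",
    "sirs_small_noise_fitness",
    "sirs_endemic_equilibrium",
]


@dataclass
class FixtureParams:
    name: str
    params: dict = field(default_factory=dict)


#: Published default parameter values, frozen per fixture.
DEFAULTS = {
    "chemostat": {
        "D": 0.1,
        "rho1": 1.0,
        "rho2": 0.5,
        "a": 1.0,
        "b": 1.0,
    },
    "lotka_volterra": {
        "d1": 1.0,
        "d2": 0.5,
        "rho1": 1.0,
        "rho2": 0.8,
        "a": 1.0,
        "b": 1.0,
        # competition-kernel coefficients; variant "a" is the branching
        # landscape, variant "b" the invariant C11+C22=0 landscape
        "c_variant_a": (1.0, -11.0, 11.0, -4.0, 1.0, 0.5),
        "c_variant_b": (1.0, -2.0, 0.0, -2.0, 1.0, 0.5),
        "variant": "a",
        # closed-form conventions (see docs/methods.md)
        "prefactor_mode": "ou_exact",
        "arg_order": "resident_first",
    },
    "sirs": {
        "Lambda": 3.0,
        "delta": 0.2,
        "a": 2.0,
        "b": 1.0,
        "rho1": 0.1,
        "rho2": 0.0,
        "rho3": 0.0,
        "rho4": 0.0,
        # alpha(x) = alpha_coef * x; beta(x) = beta0 + beta1 x^2/(beta2 + beta3 x^2)
        # gamma(x) = gamma0; zeta(x) = exp(-zeta_scale * x^2)
        "alpha_coef": 1.0,
        "beta0": 5.65,
        "beta1": 2.0,
        "beta2": 6.0,
        "beta3": 0.1,
        "gamma0": 0.3,
        "zeta_scale": 0.5,
    },
    "prey_predator": {
        "a": 2.0,
        "c": 2.0,
        "mu": 1.0,
        "delta": 1.0,
        "h": 1.0,
        "T": 1.0,
        "gamma": 3.0,
        "lam": 0.6,
        "sigma": 0.7,
        "alpha": 0.0,
        "beta": 6.0,
    },
    "analytic": {
        # default quadratic s(x,y) = c11 x^2 + c22 y^2 + 2 c21 x y with
        # c11 + c22 + 2 c21 = 0 (selective neutrality on the diagonal)
        "c11": 1.0,
        "c22": 2.0,
        "c21": -1.5,
        "fitness": None,  # optional callable (x, y) -> float overriding the quadratic
    },
}


def _scalar(x):
    return float(np.atleast_1d(np.asarray(x, dtype=float))[0])


# ----------------------------------------------------------------------
# chemostat
# ----------------------------------------------------------------------

def chemostat_closed_form_fitness(params: dict, x, y) -> float:
    """Invasion fitness of mutant ``y=(beta', gamma', delta')`` in resident
    ``x=(beta, gamma, delta)``: ``gamma' beta' E[R] - delta' - D`` with the
    long-run mean resource ``E[R] = (delta + D)/(gamma beta)`` fixed by the
    resident's neutrality."""
    bx, gx, dx = as_strategy(x)
    by, gy, dy = as_strategy(y)
    D = params["D"]
    if gx * bx <= 0:
        raise ValueError("resident gamma*beta must be positive")
    ER = (dx + D) / (gx * bx)
    return gy * by * ER - dy - D


def _make_chemostat(p: dict) -> UnstructuredModelSpec:
    D, rho1, rho2 = p["D"], p["rho1"], p["rho2"]

    def r_in(theta):
        th = float(theta[0]) if len(theta) else 0.0
        return rho1 - rho2 * 2.0 * th / (1.0 + th * th)

    def growth(x, env, theta):
        beta, gamma, delta = x
        return gamma * beta * env.e1[0] - delta - D

    def g1(env, theta):
        return np.array([D * (r_in(theta) - env.e1[0])])

    def h1(x, env, theta):
        beta = x[0]
        return np.array([-beta * env.e1[0]])

    return UnstructuredModelSpec(
        growth=growth,
        driver=DriverSpec.ou(p["a"], p["b"]),
        dim_e1=1,
        dim_e2=0,
        env_ode_intrinsic=g1,
        env_ode_impact=h1,
        closed_form_fitness=lambda x, y: chemostat_closed_form_fitness(p, x, y),
        dim_strategy=3,
        name="chemostat",
        default_probe_box={
            "x": ((1.0, 0.5, 0.05), (3.0, 1.0, 0.2)),
            "e1": ((0.01,), (2.0,)),
            "theta": ((-2.0,), (2.0,)),
        },
    )


# ----------------------------------------------------------------------
# Lotka-Volterra competition
# ----------------------------------------------------------------------

def _lv_kernel_coeffs(p: dict):
    key = "c_variant_a" if p.get("variant", "a") == "a" else "c_variant_b"
    return p[key]


def _lv_alpha(p: dict, xi: float, xj: float) -> float:
    """Competition kernel in its published argument order (x_i, x_j);
    alpha(x, x) = 1 for all x."""
    c0, c1, c2, c3, c4, c5 = _lv_kernel_coeffs(p)
    return (1.0 - (xj - xi) * (c0 + c1 * xi * xi + c2 * xi * xj + c3 * xj * xj)
            * math.exp(c4 * xj * xj)) * math.exp(c5 * (xi * xi - xj * xj))


def _lv_alpha_effect(p: dict, impactor: float, focal: float) -> float:
    """Competitive effect of one ``impactor`` individual on a ``focal``
    individual, under the fixture's argument-order convention."""
    if p.get("arg_order", "resident_first") == "resident_first":
        return _lv_alpha(p, impactor, focal)
    return _lv_alpha(p, focal, impactor)


def lv_closed_form_fitness(params: dict, x, y,
                           prefactor_mode: Optional[str] = None) -> float:
    """Closed-form invasion fitness of mutant ``y`` in resident ``x``:
    ``r(y) * prefactor * (1 - alpha_eff(x -> y) K(x)/K(y))``.

    ``prefactor_mode='ou_exact'`` uses the exact OU moment
    ``exp(rho1^2 b^2/(4a))``; ``'sigma_eq_b'`` uses
    ``exp(rho1^2 b^2/(2a))``. The sign of the result is independent of the
    mode. The kernel argument order follows ``params['arg_order']``.
    """
    p = params
    mode = prefactor_mode or p.get("prefactor_mode", "ou_exact")
    if mode == "ou_exact":
        pref = math.exp(p["rho1"] ** 2 * p["b"] ** 2 / (4.0 * p["a"]))
    elif mode == "sigma_eq_b":
        pref = math.exp(p["rho1"] ** 2 * p["b"] ** 2 / (2.0 * p["a"]))
    else:
        raise ValueError(f"unknown prefactor_mode {mode!r}")
    xv, yv = _scalar(x), _scalar(y)
    r_y = math.exp(-p["d1"] * yv * yv)
    K = lambda u: math.exp(-p["d2"] * u * u)
    al = _lv_alpha_effect(p, xv, yv)
    return r_y * pref * (1.0 - al * K(xv) / K(yv))


def _make_lv(p: dict, community_strategies) -> UnstructuredModelSpec:
    if community_strategies is None:
        community_strategies = (0.0,)
    comm = tuple(float(np.atleast_1d(s)[0]) for s in community_strategies)
    k = len(comm)
    d1, d2, rho1, rho2 = p["d1"], p["d2"], p["rho1"], p["rho2"]

    def growth(x, env, theta):
        u = float(x[0])
        th = float(theta[0]) if len(theta) else 0.0
        r_t = math.exp(-d1 * u * u + rho1 * th)
        K_t = math.exp(-d2 * u * u + rho2 * th)
        interaction = sum(_lv_alpha_effect(p, cj, u) * env.e2[j]
                          for j, cj in enumerate(comm))
        return r_t * (1.0 - interaction / K_t)

    return UnstructuredModelSpec(
        growth=growth,
        driver=DriverSpec.ou(p["a"], p["b"]),
        dim_e1=0,
        dim_e2=k,
        env_tracks_populations=True,
        community_strategies=comm,
        closed_form_fitness=lambda x, y: lv_closed_form_fitness(p, x, y),
        dim_strategy=1,
        name="lotka_volterra",
        default_probe_box={
            "x": ((-1.0,), (1.0,)),
            "e2": (tuple(0.01 for _ in comm), tuple(2.0 for _ in comm)),
            "theta": ((-2.0,), (2.0,)),
        },
    )


# ----------------------------------------------------------------------
# structured SIRS
# ----------------------------------------------------------------------

def _sirs_rates(p: dict, x: float):
    alpha = p["alpha_coef"] * x
    beta = p["beta0"] + p["beta1"] * x * x / (p["beta2"] + p["beta3"] * x * x)
    gamma = p["gamma0"]
    zeta = math.exp(-p["zeta_scale"] * x * x)
    return alpha, beta, gamma, zeta


def sirs_endemic_equilibrium(params: dict, x) -> tuple:
    """Endemic equilibrium (S, I, R, M) of the deterministic resident
    system. Raises ``ValueError`` when the resident cannot establish
    (expected net invasion rate of the virgin environment non-positive)."""
    p = params
    xv = _scalar(x)
    al, be, ga, ze = _sirs_rates(p, xv)
    Lam, delta = p["Lambda"], p["delta"]
    if be - ga - al - Lam <= 0:
        raise ValueError(
            "no endemic equilibrium: the establishment condition "
            "beta - gamma - alpha - Lambda > 0 fails for this strategy"
        )

    def gap(M):
        S = M * (ga + al + delta * M) / be
        I = M * (Lam - delta * M) / al
        R = ga * I / (ze + delta * M)
        return S + I + R - M

    M = brentq(gap, 1e-9, Lam / delta - 1e-12, xtol=1e-14, rtol=8.9e-16)
    S = M * (ga + al + delta * M) / be
    I = M * (Lam - delta * M) / al
    R = ga * I / (ze + delta * M)
    return S, I, R, M


def _sirs_rhs3(p: dict, x: float, s3, th: float):
    """Right-hand side of the monomorphic (S, I, R) system at driver value
    ``th``."""
    S, I, R = s3
    M = S + I + R
    al, be, ga, ze = _sirs_rates(p, x)
    be_t = be * math.exp(p["rho1"] * th)
    ga_t = ga * math.exp(p["rho2"] * th)
    al_t = al * math.exp(p["rho3"] * th)
    ze_t = ze * math.exp(p["rho4"] * th)
    Lam, delta = p["Lambda"], p["delta"]
    dS = Lam * M - be_t * I / M * S - delta * M * S + ze_t * R
    dI = (be_t * S / M - ga_t - al_t - delta * M) * I
    dR = ga_t * I - (ze_t + delta * M) * R
    return np.array([dS, dI, dR])


def sirs_small_noise_fitness(params: dict, x, y) -> float:
    """Small-noise invasion fitness of mutant ``y`` in resident ``x``.

    Assembles ``(beta(y)-beta(x)) * q - (gamma(y)-gamma(x)) -
    (alpha(y)-alpha(x))`` where ``q = S_hat/M_hat + (1/2) tr(H Cov)``:
    ``(S_hat, M_hat)`` is the deterministic endemic equilibrium of the
    resident, ``Cov`` is the stationary covariance of ``(S, M, theta)``
    obtained by linearizing the resident SDE at the equilibrium and solving
    the continuous Lyapunov equation, and ``H`` is the Hessian of
    ``exp(rho1 theta) S/M`` at the equilibrium.

    Only transmission-rate fluctuations are supported (``rho2 = rho3 =
    rho4 = 0``).
    """
    p = params
    if any(abs(p[k]) > 0 for k in ("rho2", "rho3", "rho4")):
        raise NotImplementedError(
            "small-noise fitness implemented for transmission-only "
            "fluctuations (rho2 = rho3 = rho4 = 0)"
        )
    xv, yv = _scalar(x), _scalar(y)
    S0, I0, R0, M0 = sirs_endemic_equilibrium(p, xv)
    a, b, rho1 = p["a"], p["b"], p["rho1"]

    # Jacobian of the (S, I, R, theta) system at the equilibrium
    u0 = np.array([S0, I0, R0, 0.0])

    def rhs4(u):
        d3 = _sirs_rhs3(p, xv, u[:3], u[3])
        return np.array([d3[0], d3[1], d3[2], -a * u[3]])

    J = np.zeros((4, 4))
    for j in range(4):
        h = 1e-6 * (1.0 + abs(u0[j]))
        up, um = u0.copy(), u0.copy()
        up[j] += h
        um[j] -= h
        J[:, j] = (rhs4(up) - rhs4(um)) / (2.0 * h)
    GG = np.zeros((4, 4))
    GG[3, 3] = b * b
    Sig = solve_continuous_lyapunov(J, -GG)
    # covariance of (S, M, theta) = L (S, I, R, theta) with M = S + I + R
    L = np.array([[1.0, 0.0, 0.0, 0.0],
                  [1.0, 1.0, 1.0, 0.0],
                  [0.0, 0.0, 0.0, 1.0]])
    Cov = L @ Sig @ L.T

    # Hessian of phi(S, M, theta) = exp(rho1 theta) S/M at (S0, M0, 0)
    H = np.array([
        [0.0, -1.0 / M0**2, rho1 / M0],
        [-1.0 / M0**2, 2.0 * S0 / M0**3, -rho1 * S0 / M0**2],
        [rho1 / M0, -rho1 * S0 / M0**2, rho1**2 * S0 / M0],
    ])
    q = S0 / M0 + 0.5 * float(np.sum(H * Cov))

    al_x, be_x, ga_x, _ = _sirs_rates(p, xv)
    al_y, be_y, ga_y, _ = _sirs_rates(p, yv)
    return (be_y - be_x) * q - (ga_y - ga_x) - (al_y - al_x)


def _make_sirs(p: dict) -> StructuredModelSpec:
    Lam, delta = p["Lambda"], p["delta"]

    def rates(x, theta):
        al, be, ga, ze = _sirs_rates(p, float(x[0]))
        th = float(theta[0]) if len(theta) else 0.0
        return (al * math.exp(p["rho3"] * th),
                be * math.exp(p["rho1"] * th),
                ga * math.exp(p["rho2"] * th),
                ze * math.exp(p["rho4"] * th))

    def transition_matrix(x, env, theta):
        S, M = env.e1[0], env.e2[0]
        al, be, ga, ze = rates(x, theta)
        return np.array([
            [be * S / M - ga - al - delta * M, 0.0],
            [ga, -ze - delta * M],
        ])

    def g1(env, theta):
        S, M = env.e1[0], env.e2[0]
        return np.array([(Lam - delta * S) * M])

    def h1(x, env, theta):
        S, M = env.e1[0], env.e2[0]
        al, be, ga, ze = rates(x, theta)
        return np.array([-be * S / M, ze])

    def g2(env, theta):
        return np.array([env.e1[0]])

    def h2(x, env, theta):
        return np.array([1.0, 1.0])

    return StructuredModelSpec(
        transition_matrix=transition_matrix,
        num_classes=2,
        driver=DriverSpec.ou(p["a"], p["b"]),
        dim_e1=1,
        dim_e2=1,
        env_ode_intrinsic=g1,
        env_ode_impact=h1,
        env_implicit_intrinsic=g2,
        env_implicit_impact=h2,
        closed_form_fitness=lambda x, y: sirs_small_noise_fitness(p, x, y),
        dim_strategy=1,
        name="sirs",
        default_probe_box={
            "x": ((1.0,), (10.0,)),
            "e1": ((0.1,), (14.0,)),
            "e2": ((0.5,), (15.0,)),
            "theta": ((-2.0,), (2.0,)),
        },
    )


# ----------------------------------------------------------------------
# prey-predator (evolution of prey timidity)
# ----------------------------------------------------------------------

def _make_prey_predator(p: dict) -> UnstructuredModelSpec:
    a_, c_, mu, delta = p["a"], p["c"], p["mu"], p["delta"]
    h, T, gamma, lam = p["h"], p["T"], p["gamma"], p["lam"]
    sigma, alpha, beta = p["sigma"], p["alpha"], p["beta"]

    def growth(x, env, theta):
        e1, e2 = env.e1[0], env.e2[0]
        xv = float(x[0])
        return ((a_ - c_ * e2) / (1.0 + xv * e1) - mu
                - beta * e1 / ((1.0 + xv * e1) * (1.0 + beta * h * e2)))

    def g1(env, theta):
        return np.array([-delta * env.e1[0]])

    def h1(x, env, theta):
        e1, e2 = env.e1[0], env.e2[0]
        xv = float(x[0])
        return np.array([
            gamma * beta * e1
            / ((1.0 + xv * e1) * T
               * (sigma * (1.0 + beta * h * e2) + (1.0 - lam) * alpha * e1))
        ])

    def h2(x, env, theta):
        xv = float(x[0])
        return np.array([1.0 / (1.0 + xv * env.e1[0])])

    return UnstructuredModelSpec(
        growth=growth,
        driver=DriverSpec.none(),
        dim_e1=1,
        dim_e2=1,
        env_ode_intrinsic=g1,
        env_ode_impact=h1,
        env_implicit_impact=h2,
        dim_strategy=1,
        name="prey_predator",
        default_probe_box={
            "x": ((0.2,), (1.2,)),
            "e1": ((0.01,), (2.0,)),
            "e2": ((0.01,), (1.0,)),
        },
    )


# ----------------------------------------------------------------------
# analytic fixture
# ----------------------------------------------------------------------

def _make_analytic(p: dict) -> UnstructuredModelSpec:
    fit = p.get("fitness")
    if fit is None:
        c11, c22, c21 = p["c11"], p["c22"], p["c21"]

        def fit(x, y):
            xv, yv = _scalar(x), _scalar(y)
            return c11 * xv * xv + c22 * yv * yv + 2.0 * c21 * xv * yv

    def wrapped(x, y):
        return float(fit(x, y))

    return UnstructuredModelSpec(
        growth=None,
        driver=DriverSpec.none(),
        closed_form_fitness=wrapped,
        dim_strategy=1,
        name="analytic",
        default_probe_box={"x": ((-1.0,), (1.0,))},
    )


_BUILDERS = {
    "chemostat": lambda p, kw: _make_chemostat(p),
    "lotka_volterra": lambda p, kw: _make_lv(p, kw.get("community_strategies")),
    "sirs": lambda p, kw: _make_sirs(p),
    "prey_predator": lambda p, kw: _make_prey_predator(p),
    "analytic": lambda p, kw: _make_analytic(p),
}


def make_example_model(fixture, **overrides):
    """Build a validated model spec for a named fixture.

    ``fixture`` is a name or :class:`FixtureParams`; keyword overrides are
    merged over the defaults. ``community_strategies`` (Lotka-Volterra only)
    binds the finite community whose population sizes form the environment.
    """
    if isinstance(fixture, FixtureParams):
        name = fixture.name
        merged_params = dict(fixture.params)
    else:
        name = str(fixture)
        merged_params = {}
    if name not in _BUILDERS:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"known: {sorted(_BUILDERS)}")
    params = dict(DEFAULTS[name])
    params.update(merged_params)
    kw = {}
    for key, val in overrides.items():
        if key == "community_strategies":
            kw[key] = val
        elif key in params:
            params[key] = val
        else:
            raise KeyError(f"unknown parameter {key!r} for fixture {name!r}")
    spec = _BUILDERS[name](params, kw)
    spec.fixture_params = FixtureParams(name=name, params=params)
    return spec
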
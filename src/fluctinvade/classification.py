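"""Averaged slow dynamics of the invader's relative frequency and the
classification of invasion outcomes.

For similar strategies x_i = x + eps * xi_i the relative frequency P of
strategy 2 follows, after averaging over the fast dynamics, a closed scalar
ODE: at first order a logistic equation driven by the selection gradient;
at second order a cubic-type equation built from the C matrices. The
classification dispatches on which order is decisive:

* first-order drive nonzero -> invasion implies substitution;
* first-order drive zero, quadratic coefficient nonzero -> four generic
  cases (substitution either way, protected coexistence with interior
  equilibrium p* = S12/(S12+S21), or mutual exclusion with bistable
  boundaries);
* both zero but mixed coefficient nonzero -> substitution again;
* all below tolerance -> undetermined (higher-order terms decide).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .invasion import LocalExpansion
from .model_core import as_strategy

__all__ = [
    "OutcomeClassification",
    "RegimeStats",
    "compute_regime_stats",
    "averaged_rhs_order1",
    "averaged_rhs_order2",
    "classify_outcome",
    "solve_averaged_P",
]


@dataclass
class RegimeStats:
    """The three statistics that decide which theorem applies."""

    drive1: float  # gradient . (xi2 - xi1)
    quad: float  # (xi2 - xi1)^T (C22 + C11) (xi2 - xi1)
    mixed: float  # (xi2 + xi1)^T (C22 + C21) (xi2 - xi1)


def compute_regime_stats(expansion: LocalExpansion, xi1, xi2) -> RegimeStats:
    xi1 = as_strategy(xi1)
    xi2 = as_strategy(xi2)
    dxi = xi2 - xi1
    sxi = xi2 + xi1
    return RegimeStats(
        drive1=float(expansion.gradient @ dxi),
        quad=float(dxi @ (expansion.C22 + expansion.C11) @ dxi),
        mixed=float(sxi @ (expansion.C22 + expansion.C21) @ dxi),
    )


def averaged_rhs_order1(P: float, gradient, xi1, xi2) -> float:
    """dP/dt on the first-order slow clock: P(1-P) * gradient.(xi2-xi1)."""
    gradient = np.atleast_1d(np.asarray(gradient, dtype=float))
    dxi = as_strategy(xi2) - as_strategy(xi1)
    return float(P * (1.0 - P) * (gradient @ dxi))


def averaged_rhs_order2(P: float, expansion: LocalExpansion, xi1, xi2) -> float:
    """dP/dt on the second-order slow clock."""
    xi1 = as_strategy(xi1)
    xi2 = as_strategy(xi2)
    dxi = xi2 - xi1
    sxi = xi2 + xi1
    mixed = float(sxi @ (expansion.C22 + expansion.C21) @ dxi)
    quad = float(dxi @ (expansion.C22 + expansion.C11) @ dxi)
    return float(P * (1.0 - P) * (mixed + (0.5 - P) * quad))


@dataclass
class OutcomeClassification:
    regime: str  # order1 | order2_generic | order2_special | degenerate
    outcome: str  # substitution_invader_wins | substitution_resident_wins |
    #               coexistence | mutual_exclusion | undetermined
    p_star: Optional[float]
    theorem: str
    inputs_echo: dict = field(default_factory=dict)
    stable_points: tuple = ()
    inconsistent: bool = False
    notes: str = ""


def classify_outcome(S12: float, S21: float, regime_stats: RegimeStats,
                     tol: float = 1e-8) -> OutcomeClassification:
    """Classify the outcome of an invasion event from the fitness pair
    (S12 = fitness of strategy 2 in resident 1, S21 = the reverse) and the
    regime statistics, with a dead-band ``tol`` standing in for the strict
    inequalities of the theorems."""
    echo = {"S12": S12, "S21": S21, "drive1": regime_stats.drive1,
            "quad": regime_stats.quad, "mixed": regime_stats.mixed,
            "tol": tol}

    def res(regime, outcome, p_star, theorem, stable=(), inconsistent=False,
            notes=""):
        return OutcomeClassification(regime=regime, outcome=outcome,
                                     p_star=p_star, theorem=theorem,
                                     inputs_echo=echo, stable_points=stable,
                                     inconsistent=inconsistent, notes=notes)

    if not (np.isfinite(S12) and np.isfinite(S21)):
        raise ValueError("S12 and S21 must be finite")
    if abs(S12) <= tol or abs(S21) <= tol:
        return res("degenerate", "undetermined", None, "none",
                   notes="a fitness value is within the neutrality dead-band")

    if abs(regime_stats.drive1) > tol:
        # directional selection: invasion implies substitution
        if S12 > 0 and S21 < 0:
            return res("order1", "substitution_invader_wins", 1.0,
                       "invasion-implies-substitution", stable=(1.0,))
        if S12 < 0 and S21 > 0:
            return res("order1", "substitution_resident_wins", 0.0,
                       "invasion-implies-substitution", stable=(0.0,))
        return res("order1", "undetermined", None,
                   "invasion-implies-substitution", inconsistent=True,
                   notes="fitness signs inconsistent with a first-order regime")

    if abs(regime_stats.quad) > tol:
        if S12 > 0 and S21 < 0:
            return res("order2_generic", "substitution_invader_wins", 1.0,
                       "second-order classification", stable=(1.0,))
        if S12 < 0 and S21 > 0:
            return res("order2_generic", "substitution_resident_wins", 0.0,
                       "second-order classification", stable=(0.0,))
        if S12 > 0 and S21 > 0:
            p_star = S12 / (S12 + S21)
            return res("order2_generic", "coexistence", p_star,
                       "second-order classification", stable=(p_star,))
        return res("order2_generic", "mutual_exclusion", None,
                   "second-order classification", stable=(0.0, 1.0))

    if abs(regime_stats.mixed) > tol:
        if S12 > 0 and S21 < 0:
            return res("order2_special", "substitution_invader_wins", 1.0,
                       "special invasion-substitution", stable=(1.0,))
        if S12 < 0 and S21 > 0:
            return res("order2_special", "substitution_resident_wins", 0.0,
                       "special invasion-substitution", stable=(0.0,))
        return res("order2_special", "undetermined", None,
                   "special invasion-substitution", inconsistent=True,
                   notes="fitness signs inconsistent with the special "
                         "substitution regime")

    return res("degenerate", "undetermined", None, "none",
               notes="all regime statistics within tolerance; higher-order "
                     "terms decide")


def solve_averaged_P(regime: str, expansion_or_gradient, xi1, xi2,
                     p0: float, t_end: float, n_points: int = 201):
    """Solve the averaged slow ODE for the invader frequency.

    ``regime='order1'`` uses the logistic closed form (``expansion_or_gradient``
    is the gradient vector or a LocalExpansion); ``regime='order2'`` solves
    the second-order averaged equation numerically with a stiff-safe method.
    Returns ``(times, P)`` with the path clipped to [0, 1].
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    t = np.linspace(0.0, t_end, n_points)
    if regime == "order1":
        grad = (expansion_or_gradient.gradient
                if isinstance(expansion_or_gradient, LocalExpansion)
                else np.atleast_1d(np.asarray(expansion_or_gradient, dtype=float)))
        drive = float(grad @ (as_strategy(xi2) - as_strategy(xi1)))
        if p0 in (0.0, 1.0):
            return t, np.full_like(t, p0)
        # logistic closed form
        expo = np.exp(np.clip(drive * t, -700, 700))
        P = p0 * expo / (1.0 - p0 + p0 * expo)
        return t, np.clip(P, 0.0, 1.0)
    if regime == "order2":
        expansion = expansion_or_gradient
        sol = solve_ivp(
            lambda _t, p: [averaged_rhs_order2(float(np.clip(p[0], 0.0, 1.0)),
                                               expansion, xi1, xi2)],
            (0.0, t_end), [p0], t_eval=t, method="Radau", rtol=1e-8,
            atol=1e-10)
        return sol.t, np.clip(sol.y[0], 0.0, 1.0)
    raise ValueError(f"unknown regime {regime!r}")
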
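import numpy as np
import pytest

from fluctinvade import (
    MethodError,
    SimulationConfig,
    default_initial_state,
    expand_fitness_second_order,
    find_singular_strategy,
    invasion_fitness,
    make_example_model,
    second_order_coefficients,
    selection_gradient,
    simulate_polymorphic,
)

C11, C22, C21 = 1.0, 2.0, -1.5  # analytic fixture defaults


def analytic_s(x, y):
    return C11 * x * x + C22 * y * y + 2.0 * C21 * x * y


def test_selective_neutrality_of_closed_forms():
    for fixture, x in [("chemostat", np.array([2.0, 0.8, 0.095])),
                       ("lotka_volterra", np.array([0.48])),
                       ("analytic", np.array([0.3]))]:
        spec = make_example_model(fixture)
        val = invasion_fitness(spec, x, x, method="closed_form").value
        assert val == pytest.approx(0.0, abs=1e-12)


def test_selection_gradient_matches_analytic_derivative():
    spec = make_example_model("analytic")
    g = selection_gradient(spec, np.array([0.3]))
    # d/dy s(x, y) at y = x: 2 C22 x + 2 C21 x
    assert g[0] == pytest.approx(2.0 * (C22 + C21) * 0.3, rel=1e-6)


def test_second_order_coefficients_recover_quadratic_exactly():
    spec = make_example_model("analytic")
    exp = second_order_coefficients(spec, np.array([0.4]))
    assert exp.C11[0, 0] == pytest.approx(C11, abs=1e-5)
    assert exp.C22[0, 0] == pytest.approx(C22, abs=1e-5)
    assert exp.C21[0, 0] == pytest.approx(C21, abs=1e-5)
    np.testing.assert_allclose(exp.C12, exp.C21.T)
    assert exp.conservation_defect < 1e-5


def test_taylor_expansion_is_exact_for_quadratic_fitness():
    spec = make_example_model("analytic")
    x0, eps = 0.2, 0.07
    xi1, xi2 = np.array([-1.0]), np.array([1.3])
    exp = second_order_coefficients(spec, np.array([x0]))
    s12, s21 = expand_fitness_second_order(exp, xi1, xi2, eps)
    x1, x2 = x0 + eps * xi1[0], x0 + eps * xi2[0]
    assert s12 == pytest.approx(analytic_s(x1, x2), abs=1e-6)
    assert s21 == pytest.approx(analytic_s(x2, x1), abs=1e-6)


def test_ergodic_estimate_agrees_with_closed_form():
    spec = make_example_model("chemostat")
    x = np.array([2.0, 0.8, 0.095])
    y = np.array([1.99, 0.85, 0.09])
    cfg = SimulationConfig(dt=0.01, t_end=800.0, seed=3, record_stride=10)
    res = invasion_fitness(spec, x, y, method="ergodic", config=cfg)
    exact = invasion_fitness(spec, x, y, method="closed_form").value
    assert res.se > 0
    assert abs(res.value - exact) <= 3.0 * res.se + 5e-4


def test_frozen_resident_trajectory_is_reused():
    spec = make_example_model("chemostat")
    x = np.array([2.0, 0.8, 0.095])
    cfg = SimulationConfig(dt=0.01, t_end=100.0, seed=3, record_stride=10)
    traj = simulate_polymorphic(spec, [x], default_initial_state(spec, [x]), cfg)
    a = invasion_fitness(spec, x, x, method="ergodic", config=cfg,
                         resident_traj=traj)
    b = invasion_fitness(spec, x, x, method="ergodic", config=cfg,
                         resident_traj=traj)
    assert a.value == b.value  # identical samples, no fresh simulation


def test_common_random_numbers_remove_gradient_noise():
    """With a shared resident path, antithetic probes of a neutral direction
    cancel exactly for the chemostat: scaling (beta, gamma) as (c beta,
    gamma / c) leaves the growth rate unchanged, so the CRN gradient along
    a probe of that invariance has no simulation noise."""
    spec = make_example_model("chemostat")
    x = np.array([2.0, 0.8, 0.095])
    cfg = SimulationConfig(dt=0.01, t_end=200.0, seed=5, record_stride=10)
    g_crn = selection_gradient(spec, x, method="ergodic", config=cfg, crn=True)
    g_ind = selection_gradient(spec, x, method="ergodic", config=cfg, crn=False)
    exact = selection_gradient(spec, x, method="closed_form")
    assert np.linalg.norm(g_crn - exact) < np.linalg.norm(g_ind - exact)


def test_method_errors_for_unavailable_methods():
    chemostat = make_example_model("chemostat")
    with pytest.raises(MethodError):
        invasion_fitness(chemostat, np.array([2.0, 0.8, 0.095]),
                         np.array([2.0, 0.8, 0.095]), method="periodic")
    pp = make_example_model("prey_predator")
    with pytest.raises(MethodError):
        invasion_fitness(pp, np.array([0.5]), np.array([0.5]),
                         method="closed_form")
    with pytest.raises(MethodError):
        invasion_fitness(pp, np.array([0.5]), np.array([0.5]),
                         method="astral")


def test_singular_strategy_of_quadratic_landscape():
    # gradient(x) = 2 (C22 + C21) x vanishes only at x = 0
    spec = make_example_model("analytic")
    roots = find_singular_strategy(spec, bracket=(-1.0, 1.0))
    assert len(roots) == 1
    assert roots[0][0][0] == pytest.approx(0.0, abs=1e-8)


def test_equilibrium_fitness_sign_flips_across_hopf_side_strategies():
    """At a stable equilibrium of the prey-predator model the resident's own
    equilibrium growth rate is zero."""
    spec = make_example_model("prey_predator")
    x = np.array([0.9])
    res = invasion_fitness(spec, x, x, method="equilibrium", transient=500)
    assert res.value == pytest.approx(0.0, abs=1e-7)
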
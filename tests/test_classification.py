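import numpy as np
import pytest

from fluctinvade import (
    RegimeStats,
    averaged_rhs_order1,
    averaged_rhs_order2,
    classify_outcome,
    compute_regime_stats,
    make_example_model,
    second_order_coefficients,
    solve_averaged_P,
)


def stats(drive1=0.0, quad=0.0, mixed=0.0):
    return RegimeStats(drive1=drive1, quad=quad, mixed=mixed)


def test_directional_selection_implies_substitution():
    cls = classify_outcome(0.02, -0.019, stats(drive1=0.02))
    assert cls.regime == "order1"
    assert cls.outcome == "substitution_invader_wins"
    assert cls.p_star == 1.0
    rev = classify_outcome(-0.02, 0.019, stats(drive1=0.02))
    assert rev.outcome == "substitution_resident_wins"
    assert rev.p_star == 0.0


def test_mutual_invasion_gives_protected_coexistence():
    cls = classify_outcome(0.02, 0.01, stats(quad=1.0))
    assert cls.regime == "order2_generic"
    assert cls.outcome == "coexistence"
    assert cls.p_star == pytest.approx(0.02 / 0.03)
    assert cls.stable_points == (pytest.approx(0.02 / 0.03),)


def test_mutual_exclusion_has_bistable_boundaries():
    cls = classify_outcome(-0.02, -0.01, stats(quad=1.0))
    assert cls.outcome == "mutual_exclusion"
    assert cls.p_star is None
    assert set(cls.stable_points) == {0.0, 1.0}


def test_special_regime_still_substitutes():
    cls = classify_outcome(0.02, -0.019, stats(mixed=0.5))
    assert cls.regime == "order2_special"
    assert cls.outcome == "substitution_invader_wins"


def test_neutral_dead_band_is_undetermined():
    cls = classify_outcome(1e-12, 0.02, stats(drive1=1.0), tol=1e-8)
    assert cls.outcome == "undetermined"
    assert cls.regime == "degenerate"


def test_sign_pattern_inconsistent_with_regime_is_flagged():
    # first-order regime cannot produce mutual invasion
    cls = classify_outcome(0.02, 0.015, stats(drive1=0.5))
    assert cls.inconsistent
    assert cls.outcome == "undetermined"


def test_all_statistics_below_tolerance_defers_to_higher_order():
    cls = classify_outcome(0.02, 0.01, stats())
    assert cls.regime == "degenerate"
    assert cls.outcome == "undetermined"


def test_non_finite_fitness_rejected():
    with pytest.raises(ValueError):
        classify_outcome(np.nan, 0.01, stats(drive1=1.0))


def test_first_order_averaged_flow_is_logistic():
    grad = np.array([0.4])
    xi1, xi2 = np.array([0.0]), np.array([1.0])
    assert averaged_rhs_order1(0.5, grad, xi1, xi2) == pytest.approx(0.1)
    t, P = solve_averaged_P("order1", grad, xi1, xi2, p0=0.2, t_end=40.0)
    # closed-form logistic solution
    expo = np.exp(0.4 * t)
    np.testing.assert_allclose(P, 0.2 * expo / (0.8 + 0.2 * expo), rtol=1e-10)
    assert P[-1] > 0.99


def test_second_order_averaged_flow_settles_at_interior_equilibrium():
    spec = make_example_model("analytic")  # C11=1, C22=2, C21=-1.5
    exp = second_order_coefficients(spec, np.array([0.0]))
    xi1, xi2 = np.array([-1.0]), np.array([1.0])
    st = compute_regime_stats(exp, xi1, xi2)
    assert st.drive1 == pytest.approx(0.0, abs=1e-6)
    assert st.quad == pytest.approx(12.0, rel=1e-4)  # (C22 + C11) * (2)^2
    assert st.mixed == pytest.approx(0.0, abs=1e-4)
    # symmetric mutual invasion: interior equilibrium at 1/2
    t, P = solve_averaged_P("order2", exp, xi1, xi2, p0=0.1, t_end=10.0)
    assert P[-1] == pytest.approx(0.5, abs=1e-3)
    assert averaged_rhs_order2(0.5, exp, xi1, xi2) == pytest.approx(0.0, abs=1e-4)


def test_averaged_solver_rejects_invalid_start():
    with pytest.raises(ValueError):
        solve_averaged_P("order1", np.array([1.0]), [0.0], [1.0], p0=1.2,
                         t_end=1.0)
    with pytest.raises(ValueError):
        solve_averaged_P("order3", np.array([1.0]), [0.0], [1.0], p0=0.5,
                         t_end=1.0)
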
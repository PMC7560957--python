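import numpy as np
import pytest

from fluctinvade import (
    DEFAULTS,
    FixtureParams,
    lv_closed_form_fitness,
    make_example_model,
    sirs_endemic_equilibrium,
    sirs_small_noise_fitness,
)
from fluctinvade.examples import _sirs_rhs3


def test_fixture_catalog_is_complete():
    assert set(DEFAULTS) == {"chemostat", "lotka_volterra", "sirs",
                             "prey_predator", "analytic"}


def test_unknown_fixture_and_parameter_are_rejected():
    with pytest.raises(KeyError):
        make_example_model("wright_fisher")
    with pytest.raises(KeyError):
        make_example_model("chemostat", carrying_capacity=3.0)


def test_parameter_overrides_are_applied():
    spec = make_example_model(FixtureParams("chemostat", {"D": 0.25}))
    assert spec.fixture_params.params["D"] == 0.25
    # E[R] = (delta + D)/(gamma beta) doubles the D-dependence
    x = np.array([2.0, 0.8, 0.095])
    val = spec.closed_form_fitness(x, x)
    assert val == pytest.approx(0.0, abs=1e-12)


def test_competition_kernel_is_neutral_on_the_diagonal():
    p = DEFAULTS["lotka_volterra"]
    for x in (-0.5, 0.0, 0.48, 1.1):
        assert lv_closed_form_fitness(p, x, x) == pytest.approx(0.0, abs=1e-12)


def test_lv_fitness_reproduces_published_branching_values():
    p = DEFAULTS["lotka_volterra"]
    assert lv_closed_form_fitness(p, 0.48, 0.51) == pytest.approx(0.00454545, abs=5e-9)
    assert lv_closed_form_fitness(p, 0.51, 0.48) == pytest.approx(0.00346302, abs=5e-9)
    assert lv_closed_form_fitness(p, -0.53, -0.47) == pytest.approx(-0.0179815, abs=5e-8)
    assert lv_closed_form_fitness(p, -0.47, -0.53) == pytest.approx(-0.0143759, abs=5e-8)


def test_sirs_endemic_equilibrium_solves_the_steady_state():
    p = DEFAULTS["sirs"]
    S, I, R, M = sirs_endemic_equilibrium(p, 8.7)
    assert min(S, I, R) > 0
    assert S + I + R == pytest.approx(M, rel=1e-10)
    resid = _sirs_rhs3(p, 8.7, np.array([S, I, R]), 0.0)
    np.testing.assert_allclose(resid, 0.0, atol=1e-8)


def test_sirs_establishment_condition_guards_equilibrium():
    with pytest.raises(ValueError):
        sirs_endemic_equilibrium(DEFAULTS["sirs"], 20.0)


def test_sirs_small_noise_fitness_requires_transmission_only_noise():
    p = dict(DEFAULTS["sirs"])
    p["rho2"] = 0.1
    with pytest.raises(NotImplementedError):
        sirs_small_noise_fitness(p, 8.7, 8.68)


def test_sirs_small_noise_fitness_is_antisymmetric_in_sign():
    p = DEFAULTS["sirs"]
    fwd = sirs_small_noise_fitness(p, 8.7, 8.68)
    rev = sirs_small_noise_fitness(p, 8.68, 8.7)
    assert fwd > 0 > rev  # mutual exclusion pair


def test_lv_community_binding_fixes_environment_dimension():
    spec = make_example_model("lotka_volterra",
                              community_strategies=[0.1, 0.5])
    assert spec.dim_e2 == 2
    assert spec.env_tracks_populations
    assert spec.community_strategies == (0.1, 0.5)
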
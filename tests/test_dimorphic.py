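import numpy as np
import pytest

from fluctinvade import (
    SimulationConfig,
    SystemState,
    compare_to_averaged,
    frequency_path,
    make_example_model,
    simulate_dimorphic,
    simulate_polymorphic,
)

X = np.array([2.0, 0.8, 0.095])
XI1 = np.zeros(3)
XI2 = np.array([-1.0, 5.0, -0.5])


def chemostat_init():
    return SystemState(n=np.array([0.3, 0.3]), e1=np.array([1.0]),
                       e2=np.zeros(0), theta=np.zeros(1))


def test_change_of_variables_matches_direct_simulation_under_shared_noise():
    spec = make_example_model("chemostat")
    eps = 0.01
    errs = []
    for dt in (0.02, 0.01):
        cfg = SimulationConfig(dt=dt, t_end=40.0, seed=11, record_stride=10)
        td = simulate_dimorphic(spec, X, XI1, XI2, eps, chemostat_init(), cfg)
        tp = simulate_polymorphic(spec, [X + eps * XI1, X + eps * XI2],
                                  chemostat_init(), cfg)
        np.testing.assert_array_equal(td.theta, tp.theta)  # same noise path
        errs.append(float(np.max(np.abs(td.n - tp.n))))
    assert errs[1] < errs[0]  # discretization mismatch vanishes as dt -> 0
    assert errs[1] < 1e-3


def test_identical_strategies_keep_frequency_exactly_constant():
    spec = make_example_model("chemostat")
    cfg = SimulationConfig(dt=0.01, t_end=20.0, seed=2, record_stride=10)
    traj = simulate_dimorphic(spec, X, XI1, XI2, eps=0.0,
                              init=chemostat_init(), config=cfg)
    P = frequency_path(traj)
    np.testing.assert_array_equal(P, np.full_like(P, 0.5))


def test_frequency_path_is_bounded_in_unit_interval():
    spec = make_example_model("chemostat")
    cfg = SimulationConfig(dt=0.01, t_end=100.0, seed=8, record_stride=10)
    traj = simulate_dimorphic(spec, X, XI1, XI2, eps=0.05,
                              init=chemostat_init(), config=cfg)
    P = frequency_path(traj)
    assert np.all((P >= 0.0) & (P <= 1.0))


def test_frequency_converges_to_averaged_prediction_in_directional_regime():
    """The Fig.-style chemostat pair has first-order drive toward the second
    strategy, so the averaged prediction is fixation (p* = 1)."""
    spec = make_example_model("chemostat")
    cfg = SimulationConfig(dt=0.01, t_end=1.0, seed=0, record_stride=20)
    report = compare_to_averaged(spec, X, XI1, XI2, eps_grid=[0.05], delta=0.1,
                                 config=cfg, seeds=(0, 1), t_slow=20.0)
    assert report.regime == "order1"
    assert report.p_star == 1.0
    assert report.all_pass_smallest_eps, report.sup_dev


def test_zero_eps_reports_exact_initial_deviation():
    spec = make_example_model("chemostat")
    cfg = SimulationConfig(dt=0.01, t_end=1.0, seed=0, record_stride=20)
    report = compare_to_averaged(spec, X, XI1, XI2, eps_grid=[0.0], delta=0.6,
                                 config=cfg, p_star=1.0, regime="order1",
                                 expansion=None, p0=0.5, seeds=(0,))
    np.testing.assert_allclose(report.sup_dev, 0.5)
    assert report.passes.all()
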
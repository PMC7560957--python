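import numpy as np
import pytest

from fluctinvade import (
    HopfNotFoundError,
    SimulationConfig,
    Trajectory,
    batch_mean_se,
    birkhoff_average,
    detect_period,
    find_hopf,
    make_example_model,
    resident_diagnostics,
)


def test_batch_means_of_constant_series():
    mean, se = batch_mean_se(np.full(300, 2.5))
    assert mean == 2.5
    assert se == 0.0


def test_batch_means_shrink_with_sample_size():
    rng = np.random.default_rng(0)
    short = batch_mean_se(rng.standard_normal(300))[1]
    long = batch_mean_se(rng.standard_normal(30000))[1]
    assert long < short


def test_birkhoff_average_discards_burn_in():
    samples = np.concatenate([np.full(50, 100.0), np.full(50, 1.0)])
    mean, _ = birkhoff_average(samples, burn_in=0.5)
    assert mean == 1.0
    with pytest.raises(ValueError):
        birkhoff_average(samples, burn_in=1.5)


def synthetic_trajectory(signal, times):
    cfg = SimulationConfig(dt=float(times[1] - times[0]), t_end=float(times[-1]))
    z = np.zeros((len(times), 0))
    return Trajectory(times=times, n=signal[:, None], e1=z, e2=z, theta=z,
                      config=cfg)


def test_period_detection_recovers_sinusoid_period():
    times = np.linspace(0.0, 400.0, 40001)
    traj = synthetic_trajectory(1.0 + 0.3 * np.sin(2 * np.pi * times / 7.3),
                                times)
    res = detect_period(traj, transient=100.0)
    assert res.kind == "periodic"
    assert res.tau == pytest.approx(7.3, rel=1e-3)


def test_period_detection_flags_equilibrium():
    times = np.linspace(0.0, 100.0, 5001)
    traj = synthetic_trajectory(np.full_like(times, 0.7), times)
    assert detect_period(traj, transient=10.0).kind == "equilibrium"


def test_period_detection_rejects_aperiodic_signal():
    rng = np.random.default_rng(1)
    times = np.linspace(0.0, 200.0, 20001)
    sig = 1.0 + np.cumsum(rng.standard_normal(len(times))) * 0.01
    res = detect_period(synthetic_trajectory(sig, times), transient=10.0)
    assert res.kind in ("none", "equilibrium")


def test_prey_predator_attractor_changes_with_timidity():
    spec = make_example_model("prey_predator")
    cyc = detect_period(spec, np.array([0.3764]), transient=600, observe=200)
    assert cyc.kind == "periodic"
    assert 5.0 < cyc.tau < 20.0
    # above the stability threshold the spiral decays slowly; allow a long
    # transient so the residual oscillation falls below the amplitude floor
    eq = detect_period(spec, np.array([0.9]), transient=1500, observe=200)
    assert eq.kind == "equilibrium"


def test_hopf_location_on_normal_form():
    """dx = mu x - y - x(x^2+y^2); dy = x + mu y - y(x^2+y^2): the origin
    loses stability exactly at mu = 0."""

    def family(mu):
        def rhs(y):
            x1, x2 = y
            r2 = x1 * x1 + x2 * x2
            return np.array([mu * x1 - x2 - x1 * r2,
                             x1 + mu * x2 - x2 * r2])
        return rhs

    hopf = find_hopf(family, (-0.5, 0.5), xtol=1e-8, guess=np.zeros(2),
                     anchor=-0.5)
    assert hopf == pytest.approx(0.0, abs=1e-6)


def test_hopf_raises_when_no_crossing_in_bracket():
    def family(mu):
        def rhs(y):
            return np.array([-y[0] + mu * 0.0, -y[1]])
        return rhs

    with pytest.raises(HopfNotFoundError):
        find_hopf(family, (-0.5, 0.5), guess=np.zeros(2), anchor=0.5)


def test_chemostat_strategy_is_a_resident():
    spec = make_example_model("chemostat")
    cfg = SimulationConfig(dt=0.01, t_end=600.0, seed=6, record_stride=10)
    check = resident_diagnostics(spec, np.array([2.0, 0.8, 0.095]), cfg)
    assert check.verdict == "resident"
    assert abs(check.lambda_hat) <= 3.0 * check.lambda_se


def test_unsustainable_death_rate_is_not_a_resident():
    spec = make_example_model("chemostat")
    cfg = SimulationConfig(dt=0.01, t_end=300.0, seed=6, record_stride=10)
    # death rate far above what the resource supply can sustain
    check = resident_diagnostics(spec, np.array([2.0, 0.8, 3.0]), cfg)
    assert check.verdict == "not_resident"
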
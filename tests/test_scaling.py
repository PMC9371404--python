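"""Nondimensionalisation maps, trajectory equivalence, structural symmetry
and qualitative system-level properties of the circuits."""

import numpy as np
import pytest

from assoclearn.circuits import (
    FDDimensionalParams,
    FDParams,
    FernandoDimensionalParams,
    FernandoParams,
    fd_dimensional_rhs,
    fd_rhs,
    fernando_dimensional_rhs,
    fernando_rhs,
    nondimensionalize_fd,
    nondimensionalize_fernando,
)
from assoclearn.integrate import IntegratorSettings, integrate
from assoclearn.protocols import Protocol, Pulse, scale_protocol

# ---------------------------------------------------------------------------
# Algebraic reduction
# ---------------------------------------------------------------------------


def test_unit_constants_reduce_to_identity():
    p, s = nondimensionalize_fernando(FernandoDimensionalParams(
        v_p=1.3, v_w=0.7, eps1=0.2))
    assert p.alpha == 1.3 and p.beta == 0.7 and p.tau1 == 0.2 and p.S == 1.0
    q, _ = nondimensionalize_fd(FDDimensionalParams(alpha_yx=2.5))
    assert q.alpha_yx == 2.5 and q.beta_u == pytest.approx(0.1)


def test_production_over_constant_times_decay():
    p, _ = nondimensionalize_fernando(
        FernandoDimensionalParams(v_p=2.0, K_p=4.0, delta_p=0.5)
    )
    assert p.alpha == pytest.approx(1.0)
    q, _ = nondimensionalize_fd(FDDimensionalParams(delta_y=2.0, alpha_yx=4.0))
    assert q.alpha_yx == pytest.approx(2.0)
    assert q.alpha_ux == pytest.approx(FDDimensionalParams().alpha_ux / 2.0)


def test_scaling_maps_invert():
    _, s = nondimensionalize_fernando(
        FernandoDimensionalParams(K_p=3.0, K_w=0.5, K_r=2.0, delta_p=0.25, k=4.0)
    )
    state = np.array([1.7, 0.3, 0.9])
    np.testing.assert_allclose(
        s.to_dimensional_state(s.to_dimensionless_state(state)), state
    )
    assert s.to_dimensional_time(s.to_dimensionless_time(3.0)) == pytest.approx(3.0)
    _, f = nondimensionalize_fd(
        FDDimensionalParams(K_x=2.0, K_z=3.0, K_u=0.5, K_v=4.0, delta_y=2.0)
    )
    np.testing.assert_allclose(
        f.to_dimensional_inputs(f.to_dimensionless_inputs([1.0, 2.0])), [1.0, 2.0]
    )


def test_zero_constants_rejected():
    with pytest.raises(ValueError):
        FernandoDimensionalParams(delta_p=0.0)
    with pytest.raises(ValueError):
        FDDimensionalParams(K_u=0.0)


# ---------------------------------------------------------------------------
# Trajectory equivalence: simulate the dimensional system, map through the
# scaling, compare with the dimensionless system under the scaled protocol.
# ---------------------------------------------------------------------------


def _random_fernando_dim(rng):
    # delta_p is drawn from powers of two so that scaled sample times land
    # exactly on the scaled pulse edges (multiplication by 2^k is exact);
    # incommensurate time scales would shift edge sampling by one RK4 stage
    return FernandoDimensionalParams(
        v_p=rng.uniform(0.5, 2), v_w=rng.uniform(0.5, 2),
        delta_p=float(rng.choice([0.5, 1.0, 2.0])), delta_w=rng.uniform(0.05, 0.5),
        K_w=rng.uniform(0.5, 2), K_r=rng.uniform(0.5, 2),
        K_p=rng.uniform(0.5, 2), R=rng.uniform(1, 5), k=rng.uniform(0.5, 2),
        eps1=rng.uniform(0, 0.3), eps2=0.0, a=int(rng.integers(1, 5)), b=2,
    )


def _random_fd_dim(rng):
    return FDDimensionalParams(
        alpha_yx=rng.uniform(0.5, 3), alpha_yz=rng.uniform(0.5, 3),
        alpha_xyz=rng.uniform(0.5, 3), alpha_ux=rng.uniform(0.2, 1),
        alpha_vx=rng.uniform(0.5, 2), delta_y=float(rng.choice([0.5, 1.0, 2.0])),
        delta_u=rng.uniform(0.05, 0.5), delta_v=rng.uniform(0.02, 0.2),
        K_x=rng.uniform(0.5, 2), K_z=rng.uniform(0.5, 2),
        K_v=rng.uniform(0.5, 2), K_u=rng.uniform(0.5, 2),
        a=int(rng.integers(1, 5)),
    )


def _dim_protocol(channels, horizon=10.0):
    pulses = [
        Pulse(channels[0], 1.0, 2.0, 3.0),
        Pulse(channels[1], 4.0, 2.0, 5.0),
        Pulse(channels[0], 4.0, 2.0, 2.0),
    ]
    return Protocol(pulses, horizon)


@pytest.mark.parametrize("trial", range(3))
def test_fernando_dimensional_equals_scaled_dimensionless(rng, trial):
    for _ in range(trial + 1):
        params = _random_fernando_dim(rng)
    dimless, s = nondimensionalize_fernando(params)
    proto = _dim_protocol(("u1", "u2"))
    state0 = np.array([0.4, 1.0, 0.2])

    dt = 1e-3
    dim = integrate(fernando_dimensional_rhs, state0, proto,
                    IntegratorSettings(method="rk4", dt=dt),
                    params=params, channels=("u1", "u2"))
    # same grid in scaled time: t_bar = delta_p * t, u_bar = k * u
    sproto = scale_protocol(proto, s.delta_p, {"u1": s.k, "u2": s.k})
    nondim = integrate(fernando_rhs, s.to_dimensionless_state(state0), sproto,
                       IntegratorSettings(method="rk4", dt=dt * s.delta_p),
                       params=dimless, channels=("u1", "u2"))
    mapped = s.to_dimensionless_state(dim.states)
    assert np.max(np.abs(mapped - nondim.states)) < 1e-6


@pytest.mark.parametrize("trial", range(3))
def test_fd_dimensional_equals_scaled_dimensionless(rng, trial):
    for _ in range(trial + 1):
        params = _random_fd_dim(rng)
    dimless, s = nondimensionalize_fd(params)
    proto = _dim_protocol(("x", "z"))
    state0 = np.array([0.1, 0.2, 2.0])

    dt = 1e-3
    dim = integrate(fd_dimensional_rhs, state0, proto,
                    IntegratorSettings(method="rk4", dt=dt),
                    params=params, channels=("x", "z"))
    sproto = scale_protocol(proto, s.delta_y, {"x": 1 / s.K_x, "z": 1 / s.K_z})
    nondim = integrate(fd_rhs, s.to_dimensionless_state(state0), sproto,
                       IntegratorSettings(method="rk4", dt=dt * s.delta_y),
                       params=dimless, channels=("x", "z"))
    mapped = s.to_dimensionless_state(dim.states)
    assert np.max(np.abs(mapped - nondim.states)) < 1e-6


def test_unit_constants_give_identical_rhs():
    # with every Hill constant, binding coefficient and response decay at 1,
    # the dimensional and dimensionless derivatives coincide pointwise
    dp = FernandoDimensionalParams(v_p=1.1, v_w=0.8, delta_w=0.02, R=10.0,
                                   eps1=0.1)
    p, _ = nondimensionalize_fernando(dp)
    state, inputs = np.array([0.5, 2.0, 0.1]), (3.0, 0.0)
    np.testing.assert_allclose(
        fernando_dimensional_rhs(state, inputs, dp),
        fernando_rhs(state, inputs, p), atol=1e-14,
    )
    dq = FDDimensionalParams(delta_u=0.1, delta_v=0.02)
    q, _ = nondimensionalize_fd(dq)
    np.testing.assert_allclose(
        fd_dimensional_rhs(state, inputs, dq), fd_rhs(state, inputs, q),
        atol=1e-14,
    )


# ---------------------------------------------------------------------------
# Structural symmetry and decay/boundedness properties
# ---------------------------------------------------------------------------


def test_fernando_channel_swap_symmetry():
    """The Hebbian circuit is structurally symmetric: swapping the two
    stimulus channels together with the weight initial conditions and basal
    rates permutes the weight trajectories and leaves the response alone."""
    params = FernandoParams(tau1=0.05, tau2=0.05)
    proto = Protocol(
        [Pulse("u1", 2.0, 2.0, 100.0), Pulse("u2", 10.0, 3.0, 50.0)],
        horizon=30.0,
    )
    swapped = Protocol(
        [Pulse("u2", 2.0, 2.0, 100.0), Pulse("u1", 10.0, 3.0, 50.0)],
        horizon=30.0,
    )
    st = IntegratorSettings(dt=0.01)
    one = integrate(fernando_rhs, [0.0, 2.0, 0.5], proto, st,
                    params=params, channels=("u1", "u2"))
    two = integrate(fernando_rhs, [0.0, 0.5, 2.0], swapped, st,
                    params=params, channels=("u1", "u2"))
    np.testing.assert_allclose(one.states[:, 0], two.states[:, 0], atol=1e-12)
    np.testing.assert_allclose(one.states[:, 1], two.states[:, 2], atol=1e-12)
    np.testing.assert_allclose(one.states[:, 2], two.states[:, 1], atol=1e-12)


ZERO_INPUT_CASES = [
    ("fernando", fernando_rhs, FernandoParams(tau1=0.0, tau2=0.0), [1.0, 2.0, 0.5]),
    ("fernando_dim", fernando_dimensional_rhs,
     FernandoDimensionalParams(eps1=0.0, eps2=0.0), [1.0, 2.0, 0.5]),
    ("fd", fd_rhs, FDParams(), [1.0, 2.0, 3.0]),
    ("fd_dim", fd_dimensional_rhs, FDDimensionalParams(), [1.0, 2.0, 3.0]),
]


@pytest.mark.parametrize("name,rhs,params,state0", ZERO_INPUT_CASES,
                         ids=[c[0] for c in ZERO_INPUT_CASES])
def test_zero_input_states_decay_monotonically(name, rhs, params, state0):
    proto = Protocol([], horizon=50.0)
    traj = integrate(rhs, state0, proto, IntegratorSettings(dt=0.01),
                     params=params, channels=("c1", "c2"))
    diffs = np.diff(traj.states, axis=0)
    assert np.all(diffs <= 1e-12)
    assert np.all(traj.states[-1] < np.asarray(state0) * 0.7)


def test_response_respects_production_bound(fernando_default_run, fd_default_run,
                                            adjusted_default_run):
    """The dimensionless response can never exceed the sum of its production
    strengths (each Hill gate is < 1): p < 2*alpha, y < sum of alpha_y*."""
    traj_f, _, _ = fernando_default_run
    p = FernandoParams()
    assert traj_f.states[:, 0].max() <= 2 * p.alpha * 1.01
    traj_d, _, _ = fd_default_run
    q = FDParams()
    assert traj_d.states[:, 0].max() <= (q.alpha_yx + q.alpha_yz + q.alpha_xyz) * 1.01
    traj_a, _, _ = adjusted_default_run
    r = traj_a.states[:, 0].max()
    from assoclearn.circuits import AdjustedFDParams

    s = AdjustedFDParams()
    assert r <= (s.alpha_yx + s.alpha_yz) * 1.01


def test_no_negative_states_under_default_runs(fernando_default_run, fd_default_run):
    for run in (fernando_default_run, fd_default_run):
        traj, _, _ = run
        assert traj.states.min() >= -1e-9
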
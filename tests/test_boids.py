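"""Unit and property tests for the Boids tank simulation."""

import numpy as np
import pytest

from rastank import boids
from rastank.errors import (
    InfeasibleGeometryError,
    InvalidArgumentError,
    NumericalFailureError,
)

from conftest import make_state


def no_force_config(**kw):
    """Config with all steering weights and vortices off, no barrier."""
    params = boids.BoidsParams(
        separation_weight=0.0, alignment_weight=0.0, cohesion_weight=0.0,
        min_speed=0.01, max_speed=10.0, **kw,
    )
    return boids.SimulationConfig(n_fish=1, params=params, vortices=(), barrier=None)


# ---------------------------------------------------------------------------
# type validation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "factory",
    [
        lambda: boids.TankGeometry(radius=-1.0),
        lambda: boids.TankGeometry(radius=1.0, wall_margin=1.5),
        lambda: boids.VortexForce(0.0, 2, 1.0, 1.0),
        lambda: boids.VortexForce(0.0, 1, 1.0, -0.5),
        lambda: boids.Barrier(center=(0, 0, 0), half_extents=(0.1, -0.1, 0.1)),
        lambda: boids.BoidsParams(min_speed=0.5, max_speed=0.2),
        lambda: boids.BoidsParams(dt=0.0),
        lambda: boids.BoidsParams(perception_radius=0.1, min_separation=0.2),
    ],
)
def test_invalid_configs_rejected(factory):
    with pytest.raises(InvalidArgumentError):
        factory()


# ---------------------------------------------------------------------------
# init_school
# ---------------------------------------------------------------------------


def test_init_school_seed_determinism(small_tank, default_params):
    a = boids.init_school(1, small_tank, default_params, seed=7)
    b = boids.init_school(1, small_tank, default_params, seed=7)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.velocities, b.velocities)


def test_init_school_containment_and_speeds(default_params):
    geo = boids.TankGeometry(radius=2.0, height=1.0, wall_margin=0.1)
    state = boids.init_school(50, geo, default_params, seed=3)
    r = np.linalg.norm(state.positions[:, :2], axis=1)
    assert np.all(r <= geo.inner_radius + 1e-12)
    assert np.all((state.positions[:, 2] >= 0) & (state.positions[:, 2] <= geo.height))
    speeds = np.linalg.norm(state.velocities, axis=1)
    assert np.all(speeds >= default_params.min_speed - 1e-12)
    assert np.all(speeds <= default_params.max_speed + 1e-12)


def test_init_school_uniform_z_mean(default_params):
    # mean of Uniform(0, h) is h/2 with standard error h/sqrt(12 n)
    geo = boids.TankGeometry(radius=3.45, height=4.0, wall_margin=0.2)
    state = boids.init_school(1000, geo, default_params, seed=11)
    se = geo.height / np.sqrt(12 * 1000)
    assert abs(state.positions[:, 2].mean() - geo.height / 2) < 3 * se


def test_init_school_excludes_barrier(small_tank, default_params):
    barrier = boids.Barrier(center=(1.0, 0.0, 0.5), half_extents=(0.4, 0.4, 0.4))
    state = boids.init_school(200, small_tank, default_params, seed=5, barrier=barrier,
                              min_spacing=0.01)
    assert not barrier.contains(state.positions).any()


def test_init_school_errors(small_tank, default_params):
    with pytest.raises(InvalidArgumentError):
        boids.init_school(0, small_tank, default_params, seed=0)
    # barrier swallowing the whole tank leaves nowhere to place fish
    huge = boids.Barrier(center=(0, 0, 0.75), half_extents=(5.0, 5.0, 5.0))
    with pytest.raises(InfeasibleGeometryError):
        boids.init_school(5, small_tank, default_params, seed=0, barrier=huge)


# ---------------------------------------------------------------------------
# vortex force
# ---------------------------------------------------------------------------


def test_vortex_on_axis_is_zero():
    v = boids.VortexForce(source_height=1.0, rotation_sign=1, strength=2.0, decay_length=1.0)
    assert np.array_equal(boids.vortex_acceleration(np.array([0.0, 0.0, 0.5]), v), np.zeros(3))


def test_vortex_closed_form():
    # at the source plane the decay factor is 1: unit radius, +1 spin -> (0, strength, 0)
    v = boids.VortexForce(source_height=0.7, rotation_sign=1, strength=2.0, decay_length=1.0)
    acc = boids.vortex_acceleration(np.array([1.0, 0.0, 0.7]), v)
    assert acc == pytest.approx([0.0, 2.0, 0.0])
    # off the source plane: magnitude strength * exp(-dz / decay_length), still tangential
    acc2 = boids.vortex_acceleration(np.array([0.0, 2.0, 1.7]), v)
    expected_mag = 2.0 * np.exp(-1.0)
    assert acc2 == pytest.approx([-expected_mag, 0.0, 0.0])


def test_vortex_sign_flip_negates():
    up = boids.VortexForce(0.2, 1, 1.3, 0.8)
    dn = boids.VortexForce(0.2, -1, 1.3, 0.8)
    p = np.array([0.3, -1.1, 0.9])
    assert np.allclose(boids.vortex_acceleration(p, up), -boids.vortex_acceleration(p, dn))


def test_vortex_is_tangential_and_horizontal():
    v = boids.VortexForce(0.0, 1, 1.0, 2.0)
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = rng.uniform(-2, 2, 3)
        acc = boids.vortex_acceleration(p, v)
        assert acc[2] == 0.0
        assert abs(acc[:2] @ p[:2]) < 1e-12  # no radial component


# ---------------------------------------------------------------------------
# steering
# ---------------------------------------------------------------------------


def test_single_fish_zero_steering(default_params):
    state = make_state([[0.0, 0.0, 1.0]], [[0.5, 0.0, 0.0]])
    assert np.array_equal(boids.boids_steering(state, default_params), np.zeros((1, 3)))


def test_out_of_range_fish_zero_steering(default_params):
    state = make_state(
        [[0.0, 0.0, 1.0], [default_params.perception_radius * 3, 0.0, 1.0]],
        [[0.3, 0.0, 0.0], [0.0, 0.3, 0.0]],
    )
    assert np.array_equal(boids.boids_steering(state, default_params), np.zeros((2, 3)))


def test_separation_line_symmetry():
    """Three fish in a line inside min_separation: middle is balanced, ends point outward."""
    params = boids.BoidsParams(
        separation_weight=1.0, alignment_weight=0.0, cohesion_weight=0.0,
        min_separation=0.5, perception_radius=1.0,
    )
    spacing = 0.2
    state = make_state(
        [[-spacing, 0.0, 1.0], [0.0, 0.0, 1.0], [spacing, 0.0, 1.0]],
        np.zeros((3, 3)),
    )
    acc = boids.boids_steering(state, params)
    assert acc[1] == pytest.approx([0.0, 0.0, 0.0], abs=1e-12)
    assert acc[0][0] < 0 and acc[2][0] > 0
    assert acc[0] == pytest.approx(-acc[2])


def test_steering_matches_per_fish_oracle():
    """Vectorized steering equals a scalar per-fish re-evaluation of the three rules."""
    params = boids.BoidsParams()
    rng = np.random.default_rng(42)
    p = rng.uniform(-1, 1, (12, 3))
    v = rng.uniform(-0.5, 0.5, (12, 3))
    state = make_state(p, v)
    acc = boids.boids_steering(state, params)

    def clamp(vec):
        n = np.linalg.norm(vec)
        return vec * (params.max_accel / n) if n > params.max_accel else vec

    for i in range(12):
        nbrs = [j for j in range(12) if j != i
                and np.linalg.norm(p[i] - p[j]) <= params.perception_radius]
        sep = np.zeros(3)
        for j in nbrs:
            d = np.linalg.norm(p[i] - p[j])
            if d < params.min_separation:
                sep += (p[i] - p[j]) / d ** 3
        expected = clamp(params.separation_weight * sep)
        if nbrs:
            expected = expected + clamp(
                params.alignment_weight * (np.mean([v[j] for j in nbrs], axis=0) - v[i]))
            expected = expected + clamp(
                params.cohesion_weight * (np.mean([p[j] for j in nbrs], axis=0) - p[i]))
        assert acc[i] == pytest.approx(clamp(expected), abs=1e-9)


# ---------------------------------------------------------------------------
# avoidance
# ---------------------------------------------------------------------------


def test_avoidance_zero_in_open_water(small_tank):
    barrier = boids.Barrier(center=(1.5, 0.0, 0.4), half_extents=(0.2, 0.2, 0.2))
    state = make_state([[0.0, 0.0, small_tank.height / 2]])
    acc = boids.avoidance_acceleration(state, small_tank, barrier)
    assert np.array_equal(acc, np.zeros((1, 3)))


def test_avoidance_pushes_inward_near_wall(small_tank):
    r = small_tank.inner_radius - small_tank.wall_margin / 2
    state = make_state([[r, 0.0, small_tank.height / 2]])
    acc = boids.avoidance_acceleration(state, small_tank, None)
    assert acc[0, 0] < 0  # strictly inward radial push
    assert acc[0, 1] == 0 and acc[0, 2] == 0


def test_avoidance_floor_and_lid(small_tank):
    low = make_state([[0.0, 0.0, 0.02]])
    high = make_state([[0.0, 0.0, small_tank.height - 0.02]])
    assert boids.avoidance_acceleration(low, small_tank, None)[0, 2] > 0
    assert boids.avoidance_acceleration(high, small_tank, None)[0, 2] < 0


def test_avoidance_barrier_top_face_pushes_up(small_tank):
    """0.01 m above the top face: push along the outward (up) normal with linear falloff."""
    barrier = boids.Barrier(center=(1.0, 0.0, 0.4), half_extents=(0.3, 0.3, 0.4),
                            repulsion_strength=3.0, repulsion_range=0.5)
    state = make_state([[1.0, 0.0, 0.81]])
    acc = boids.avoidance_acceleration(state, small_tank, barrier)
    expected = 3.0 * (1 - 0.01 / 0.5)  # strength * (1 - dist/range), straight up
    assert acc[0, 2] == pytest.approx(expected, abs=1e-9)
    assert acc[0, :2] == pytest.approx([0.0, 0.0], abs=1e-12)


def test_avoidance_continuous_at_trigger(small_tank):
    """The wall ramp is continuous: accelerations just inside/outside the trigger agree."""
    la = max(small_tank.wall_margin, 0.25)
    r0 = small_tank.inner_radius - la
    for eps in (1e-7, -1e-7):
        state = make_state([[r0 + eps, 0.0, small_tank.height / 2]])
        acc = boids.avoidance_acceleration(state, small_tank, None)
        assert np.linalg.norm(acc) < 1e-5


# ---------------------------------------------------------------------------
# step / simulate
# ---------------------------------------------------------------------------


def test_step_ballistic():
    """With no forces, position advances by dt * v exactly."""
    cfg = no_force_config(dt=0.1)
    v = np.array([[0.3, -0.2, 0.1]])
    state = make_state([[0.5, 0.5, 0.7]], v)
    out = boids.step(state, cfg.geometry, None, (), cfg.params)
    assert np.array_equal(out.velocities, v)
    assert out.positions == pytest.approx(state.positions + 0.1 * v)
    assert out.time == pytest.approx(0.1)


def test_step_containment_over_random_states(default_params):
    geo = boids.TankGeometry(radius=1.5, height=1.0, wall_margin=0.1)
    barrier = boids.Barrier(center=(1.0, 0.0, 0.3), half_extents=(0.25, 0.25, 0.3))
    vortices = (boids.VortexForce(0.0, 1, 0.8, 1.0),)
    rng = np.random.default_rng(123)
    for _ in range(30):
        n = int(rng.integers(1, 20))
        rr = geo.inner_radius * np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0, 2 * np.pi, n)
        p = np.stack([rr * np.cos(th), rr * np.sin(th), rng.uniform(0, geo.height, n)], axis=1)
        v = rng.uniform(-1, 1, (n, 3))
        out = boids.step(make_state(p, v), geo, barrier, vortices, default_params)
        r_out = np.linalg.norm(out.positions[:, :2], axis=1)
        assert np.all(r_out <= geo.inner_radius + 1e-9)
        assert np.all((out.positions[:, 2] >= -1e-9) & (out.positions[:, 2] <= geo.height + 1e-9))
        assert not barrier.contains(out.positions).any()
        speeds = np.linalg.norm(out.velocities, axis=1)
        assert np.all(speeds <= default_params.max_speed + 1e-9)
        assert np.all(speeds >= default_params.min_speed - 1e-9)


def test_step_nan_raises_with_index():
    cfg = no_force_config()
    state = make_state([[0.2, 0.1, 0.5], [np.nan, 0.0, 0.5]], np.zeros((2, 3)))
    with pytest.raises(NumericalFailureError) as exc:
        boids.step(state, cfg.geometry, None, (), cfg.params)
    assert exc.value.fish_index == 1


def test_single_fish_rotation_sign_matches_refined_dt():
    """Signed angular displacement under one vortex has the vortex's sign,
    and agrees with the same ODE integrated at 10x smaller dt."""
    for sign in (+1, -1):
        vortex = boids.VortexForce(source_height=2.0, rotation_sign=sign,
                                   strength=0.5, decay_length=2.0)
        for dt, n in ((0.05, 200), (0.005, 2000)):
            cfg = no_force_config(dt=dt)
            state = make_state([[1.5, 0.0, 2.0]], [[0.0, 0.1 * sign, 0.0]])
            angles = [0.0]
            for _ in range(n):
                state = boids.step(state, boids.TankGeometry(), None, (vortex,), cfg.params)
                angles.append(np.arctan2(state.positions[0, 1], state.positions[0, 0]))
            unwrapped = np.unwrap(angles)
            assert np.sign(unwrapped[-1] - unwrapped[0]) == sign


def test_school_rotation_responds_to_vortex_sign():
    """Bottom vortex +1 drives positive mean tangential velocity; -1 negative."""
    for sign in (+1, -1):
        cfg = boids.SimulationConfig(
            n_fish=30,
            vortices=(boids.VortexForce(0.0, sign, 0.6, 2.5),),
            barrier=None,
        )
        traj = boids.simulate(cfg, 600, seed=4, thin=600)
        vt = boids.mean_tangential_velocity(traj[-1])
        assert np.sign(vt) == sign


def test_dt_convergence_first_order():
    """Halving dt shrinks the endpoint error roughly linearly (explicit Euler)."""
    vortex = boids.VortexForce(source_height=1.0, rotation_sign=1, strength=0.8, decay_length=2.0)
    geo = boids.TankGeometry()
    T = 2.0
    endpoints = {}
    for dt in (0.02, 0.01, 0.0025):
        cfg = no_force_config(dt=dt)
        state = make_state([[1.0, 0.0, 1.0]], [[0.0, 0.3, 0.05]])
        for _ in range(int(round(T / dt))):
            state = boids.step(state, geo, None, (vortex,), cfg.params)
        endpoints[dt] = state.positions[0].copy()
    e1 = np.linalg.norm(endpoints[0.02] - endpoints[0.0025])
    e2 = np.linalg.norm(endpoints[0.01] - endpoints[0.0025])
    assert e2 < e1  # error decreases with dt
    assert e1 / e2 == pytest.approx(2.0, rel=0.6)  # ~first-order ratio


def test_simulate_single_step_equals_step(small_tank, default_params):
    cfg = boids.SimulationConfig(n_fish=5, geometry=small_tank, params=default_params,
                                 barrier=None)
    initial = boids.init_school(5, small_tank, default_params, seed=9)
    traj = boids.simulate(cfg, 1, seed=9)
    expected = boids.step(initial, cfg.geometry, None, cfg.vortices, default_params)
    assert len(traj) == 1
    assert np.array_equal(traj[0].positions, expected.positions)


def test_simulate_determinism_and_thinning():
    cfg = boids.SimulationConfig(n_fish=10)
    a = boids.simulate(cfg, 50, seed=21, thin=10)
    b = boids.simulate(cfg, 50, seed=21, thin=10)
    assert len(a) == 5
    for sa, sb in zip(a, b):
        assert np.array_equal(sa.positions, sb.positions)
        assert np.array_equal(sa.velocities, sb.velocities)
    # final state always kept even when n_steps is not a multiple of thin
    c = boids.simulate(cfg, 55, seed=21, thin=10)
    assert len(c) == 6 and c[-1].time == pytest.approx(55 * cfg.params.dt)


def test_trajectory_roundtrip(tmp_path):
    cfg = boids.SimulationConfig(n_fish=8)
    traj = boids.simulate(cfg, 30, seed=2, thin=10)
    path = tmp_path / "traj.npz"
    boids.save_trajectory(path, traj)
    loaded = boids.load_trajectory(path)
    assert len(loaded) == len(traj)
    for a, b in zip(traj, loaded):
        assert np.array_equal(a.positions, b.positions)
        assert a.time == b.time


def test_config_yaml_roundtrip(tmp_path):
    cfg = boids.SimulationConfig(n_fish=42)
    path = tmp_path / "config.yaml"
    cfg.to_yaml(path)
    loaded = boids.SimulationConfig.from_yaml(path)
    assert loaded == cfg


def test_vertical_distribution_stays_spread():
    """Long default-config runs keep the school spread through the water column:
    the Monte-Carlo mean top-half fraction over 10 seeds stays in [0.3, 0.7]."""
    cfg = boids.SimulationConfig(n_fish=50)
    fracs = []
    for seed in range(10):
        traj = boids.simulate(cfg, 2000, seed=seed, thin=2000)
        z = traj[-1].positions[:, 2]
        fracs.append(np.mean(z > cfg.geometry.height / 2))
    assert 0.3 <= np.mean(fracs) <= 0.7
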
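"""Boids fish schooling in a cylindrical recirculating-aquaculture (RAS) tank.

Each fish is a point agent steered by the classic Reynolds rules — separation,
alignment, cohesion — evaluated over neighbours within a perception radius,
plus three environment forces that shape RAS-like swimming:

* smooth avoidance of the tank wall, floor, and an invisible lid,
* smooth repulsion from a cuboid barrier placed near the camera,
* a pair of vortex force fields (one sourced near the floor, one near the
  lid) that induce circular swimming about the tank axis.

Integration is explicit Euler with a hard reflective containment pass, so
every state along a trajectory satisfies the containment invariants exactly.
Units are metres and seconds throughout; the default tank is a 150 m^3
cylinder (radius 3.45 m, height 4.0 m).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InfeasibleGeometryError, InvalidArgumentError, NumericalFailureError

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TankGeometry:
    """Cylindrical tank: wall at ``radius``, floor at z=0, invisible lid at ``height``.

    ``wall_margin`` is the stand-off the fish keep from the physical wall; the
    swimmable region is the cylinder of radius ``radius - wall_margin``.
    """

    radius: float = 3.45
    height: float = 4.0
    wall_margin: float = 0.2

    def __post_init__(self):
        if self.radius <= 0 or self.height <= 0:
            raise InvalidArgumentError("tank radius and height must be positive")
        if not (0 <= self.wall_margin < self.radius):
            raise InvalidArgumentError("wall_margin must satisfy 0 <= wall_margin < radius")

    @property
    def inner_radius(self) -> float:
        return self.radius - self.wall_margin


@dataclass(frozen=True)
class VortexForce:
    """Tangential force field about the tank axis with exponential axial falloff.

    The acceleration at a point with radial offset r > 0 and height z is
    tangent to the circle through the point, with magnitude
    ``strength * exp(-|z - source_height| / decay_length)``.
    ``rotation_sign`` +1 is counter-clockwise viewed from above.
    """

    source_height: float
    rotation_sign: int
    strength: float
    decay_length: float

    def __post_init__(self):
        if self.strength < 0:
            raise InvalidArgumentError("vortex strength must be >= 0")
        if self.decay_length <= 0:
            raise InvalidArgumentError("vortex decay_length must be > 0")
        if self.rotation_sign not in (-1, 1):
            raise InvalidArgumentError("rotation_sign must be -1 or +1")


@dataclass(frozen=True)
class Barrier:
    """Axis-aligned cuboid deflector that pushes fish away from the camera zone."""

    center: tuple[float, float, float]
    half_extents: tuple[float, float, float]
    repulsion_strength: float = 3.0
    repulsion_range: float = 0.5

    def __post_init__(self):
        if any(h <= 0 for h in self.half_extents):
            raise InvalidArgumentError("barrier half_extents must be positive componentwise")
        if self.repulsion_range <= 0 or self.repulsion_strength < 0:
            raise InvalidArgumentError("barrier repulsion parameters must be non-negative")

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask of points strictly inside the cuboid."""
        p = np.atleast_2d(positions)
        c = np.asarray(self.center)
        h = np.asarray(self.half_extents)
        inside = np.all(np.abs(p - c) < h, axis=1)
        return inside if positions.ndim == 2 else inside[0]


@dataclass(frozen=True)
class BoidsParams:
    perception_radius: float = 1.2
    separation_weight: float = 2.5
    alignment_weight: float = 0.6
    cohesion_weight: float = 0.25
    min_separation: float = 0.3
    max_speed: float = 0.6
    min_speed: float = 0.05
    max_accel: float = 8.0
    dt: float = 0.05

    def __post_init__(self):
        if not (0 < self.min_speed <= self.max_speed):
            raise InvalidArgumentError("need 0 < min_speed <= max_speed")
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        if not (self.perception_radius > self.min_separation > 0):
            raise InvalidArgumentError("need perception_radius > min_separation > 0")
        if min(self.separation_weight, self.alignment_weight, self.cohesion_weight) < 0:
            raise InvalidArgumentError("steering weights must be >= 0")


@dataclass
class SchoolState:
    """Positions (N,3) and velocities (N,3) of the school at a time point."""

    positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0
    rng_seed: int = 0

    @property
    def n_fish(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SchoolState":
        return SchoolState(self.positions.copy(), self.velocities.copy(), self.time, self.rng_seed)


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of everything `simulate` needs, loadable from YAML."""

    n_fish: int = 200
    geometry: TankGeometry = field(default_factory=TankGeometry)
    params: BoidsParams = field(default_factory=BoidsParams)
    # counter-clockwise bottom vortex dominant (long decay: tank circulation is
    # nearly depth-uniform) + weak clockwise top vortex, so net rotation is
    # well-defined and the vertical fish distribution stays even
    vortices: tuple[VortexForce, ...] = (
        VortexForce(source_height=0.0, rotation_sign=+1, strength=0.45, decay_length=20.0),
        VortexForce(source_height=4.0, rotation_sign=-1, strength=0.02, decay_length=1.0),
    )
    # full water-column cuboid near the wall: diverts fish horizontally
    # around the camera zone at every depth
    barrier: Barrier | None = Barrier(
        center=(2.6, 0.0, 2.0), half_extents=(0.5, 0.6, 2.0)
    )

    def to_dict(self) -> dict:
        d: dict = {
            "n_fish": self.n_fish,
            "tank": vars(self.geometry).copy(),
            "boids": vars(self.params).copy(),
            "vortices": [vars(v).copy() for v in self.vortices],
        }
        if self.barrier is not None:
            b = vars(self.barrier).copy()
            b["center"] = list(b["center"])
            b["half_extents"] = list(b["half_extents"])
            d["barrier"] = b
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        barrier = None
        if d.get("barrier"):
            b = dict(d["barrier"])
            b["center"] = tuple(b["center"])
            b["half_extents"] = tuple(b["half_extents"])
            barrier = Barrier(**b)
        return cls(
            n_fish=int(d.get("n_fish", 200)),
            geometry=TankGeometry(**d.get("tank", {})),
            params=BoidsParams(**d.get("boids", {})),
            vortices=tuple(VortexForce(**v) for v in d.get("vortices", [])),
            barrier=barrier,
        )

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def init_school(
    n_fish: int,
    geometry: TankGeometry,
    params: BoidsParams,
    seed: int,
    barrier: Barrier | None = None,
    min_spacing: float | None = None,
) -> SchoolState:
    """Seed a school with uniform positions in the swimmable cylinder.

    Positions are dart-throwing samples: uniform in the cylinder of radius
    ``inner_radius``, rejected if inside the barrier or closer than
    ``min_spacing`` (default: ``params.min_separation``) to an already placed
    fish, so the school starts without contacts. Velocities point along the
    local tangential direction with random jitter, speeds uniform in
    [min_speed, max_speed]. Identical seeds give bit-identical states.
    """
    if n_fish < 1:
        raise InvalidArgumentError(f"n_fish must be >= 1, got {n_fish}")
    if min_spacing is None:
        min_spacing = params.min_separation
    rng = np.random.default_rng(seed)
    r_max = geometry.inner_radius

    placed = np.empty((n_fish, 3))
    count = 0
    attempts = 0
    max_attempts = max(20000, 2000 * n_fish)
    while count < n_fish:
        attempts += 1
        if attempts > max_attempts:
            raise InfeasibleGeometryError(
                f"placed only {count}/{n_fish} fish after {attempts} attempts; "
                "barrier or spacing leaves too little free volume"
            )
        r = r_max * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        z = rng.uniform(0, geometry.height)
        p = np.array([r * np.cos(theta), r * np.sin(theta), z])
        if barrier is not None and bool(barrier.contains(p)):
            continue
        if count and np.min(np.linalg.norm(placed[:count] - p, axis=1)) < min_spacing:
            continue
        placed[count] = p
        count += 1

    # tangentially biased headings: swim around the tank from the start
    xy = placed[:, :2]
    r = np.linalg.norm(xy, axis=1)
    tangent = np.zeros((n_fish, 3))
    ok = r > _EPS
    tangent[ok, 0] = -xy[ok, 1] / r[ok]
    tangent[ok, 1] = xy[ok, 0] / r[ok]
    jitter = rng.normal(scale=0.4, size=(n_fish, 3))
    direction = tangent + jitter
    norms = np.linalg.norm(direction, axis=1, keepdims=True)
    norms[norms < _EPS] = 1.0
    direction /= norms
    speeds = rng.uniform(params.min_speed, params.max_speed, size=(n_fish, 1))
    return SchoolState(positions=placed, velocities=direction * speeds, time=0.0, rng_seed=seed)


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------


def vortex_acceleration(
    position: np.ndarray,
    vortex: VortexForce,
    tank_axis_origin: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Tangential acceleration at one point; zero exactly on the axis."""
    p = np.asarray(position, dtype=float)
    origin = np.asarray(tank_axis_origin, dtype=float)
    dx, dy = p[0] - origin[0], p[1] - origin[1]
    r = np.hypot(dx, dy)
    if r < _EPS:
        return np.zeros(3)
    mag = vortex.strength * np.exp(-abs(p[2] - vortex.source_height) / vortex.decay_length)
    return np.array([-dy / r, dx / r, 0.0]) * (vortex.rotation_sign * mag)


def _vortex_accels(positions: np.ndarray, vortices) -> np.ndarray:
    """Vectorized sum of vortex accelerations over the school."""
    acc = np.zeros_like(positions)
    xy = positions[:, :2]
    r = np.linalg.norm(xy, axis=1)
    ok = r > _EPS
    for v in vortices:
        mag = v.strength * np.exp(-np.abs(positions[:, 2] - v.source_height) / v.decay_length)
        acc[ok, 0] += -xy[ok, 1] / r[ok] * v.rotation_sign * mag[ok]
        acc[ok, 1] += xy[ok, 0] / r[ok] * v.rotation_sign * mag[ok]
    return acc


def _clamp_norm(vectors: np.ndarray, limit: float) -> np.ndarray:
    """Rescale rows whose norm exceeds `limit` (keeps direction)."""
    norms = np.linalg.norm(vectors, axis=-1, keepdims=True)
    scale = np.where(norms > limit, limit / np.maximum(norms, _EPS), 1.0)
    return vectors * scale


def boids_steering(state: SchoolState, params: BoidsParams) -> np.ndarray:
    """Reynolds separation + alignment + cohesion accelerations, (N,3).

    Neighbours are fish within ``perception_radius`` (self excluded).
    Separation repels from neighbours closer than ``min_separation`` with
    inverse-square distance weighting; alignment steers toward the mean
    neighbour velocity; cohesion toward the neighbour centroid. Each term and
    the total are clamped to ``max_accel``.
    """
    p, v = state.positions, state.velocities
    n = p.shape[0]
    if n == 1:
        return np.zeros_like(p)

    diff = p[:, None, :] - p[None, :, :]  # diff[i,j] = p_i - p_j
    dist = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(dist, np.inf)
    neighbor = dist <= params.perception_radius
    n_neighbors = neighbor.sum(axis=1)

    # separation: inverse-square push away from crowding neighbours
    close = neighbor & (dist < params.min_separation)
    w = np.where(close, 1.0 / np.maximum(dist, 1e-6) ** 2, 0.0)
    sep = np.einsum("ij,ijk->ik", w, diff / np.maximum(dist, 1e-6)[:, :, None])
    a_sep = _clamp_norm(params.separation_weight * sep, params.max_accel)

    has_nb = n_neighbors > 0
    denom = np.maximum(n_neighbors, 1)[:, None]

    mean_v = (neighbor[:, :, None] * v[None, :, :]).sum(axis=1) / denom
    ali = np.where(has_nb[:, None], mean_v - v, 0.0)
    a_ali = _clamp_norm(params.alignment_weight * ali, params.max_accel)

    centroid = (neighbor[:, :, None] * p[None, :, :]).sum(axis=1) / denom
    coh = np.where(has_nb[:, None], centroid - p, 0.0)
    a_coh = _clamp_norm(params.cohesion_weight * coh, params.max_accel)

    return _clamp_norm(a_sep + a_ali + a_coh, params.max_accel)


def avoidance_acceleration(
    state: SchoolState,
    geometry: TankGeometry,
    barrier: Barrier | None = None,
    strength: float = 4.0,
    lookahead: float | None = None,
) -> np.ndarray:
    """Smooth boundary avoidance: wall (inward), floor (up), lid (down), barrier.

    Each boundary term ramps linearly from zero at ``lookahead`` distance to
    ``strength`` at the boundary itself, so the field is continuous in
    position. The barrier push acts along the outward normal from the nearest
    cuboid surface point within ``repulsion_range``.
    """
    if lookahead is None:
        lookahead = max(geometry.wall_margin, 0.25)
    p = state.positions
    acc = np.zeros_like(p)

    # cylinder wall: inward radial ramp
    xy = p[:, :2]
    r = np.linalg.norm(xy, axis=1)
    r_in = geometry.inner_radius
    ramp = np.clip((r - (r_in - lookahead)) / lookahead, 0.0, 1.0)
    ok = (r > _EPS) & (ramp > 0)
    acc[ok, :2] -= strength * ramp[ok, None] * xy[ok] / r[ok, None]

    # floor and lid
    z = p[:, 2]
    acc[:, 2] += strength * np.clip(1.0 - z / lookahead, 0.0, 1.0)
    acc[:, 2] -= strength * np.clip(1.0 - (geometry.height - z) / lookahead, 0.0, 1.0)

    if barrier is not None:
        c = np.asarray(barrier.center)
        h = np.asarray(barrier.half_extents)
        nearest = np.clip(p, c - h, c + h)
        delta = p - nearest
        dist = np.linalg.norm(delta, axis=1)
        outside_near = (dist > _EPS) & (dist < barrier.repulsion_range)
        falloff = barrier.repulsion_strength * (1.0 - dist[outside_near] / barrier.repulsion_range)
        acc[outside_near] += delta[outside_near] / dist[outside_near, None] * falloff[:, None]
        # on/inside the surface: push along the axis of least penetration
        inside = dist <= _EPS
        if np.any(inside):
            pen = h - np.abs(p[inside] - c)  # distance to each face pair
            axis = np.argmin(pen, axis=1)
            sign = np.sign(p[inside, axis] - c[axis])
            sign[sign == 0] = 1.0
            rows = np.where(inside)[0]
            acc[rows, axis] += sign * barrier.repulsion_strength
    return acc


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def _clamp_speed(v: np.ndarray, params: BoidsParams) -> np.ndarray:
    speed = np.linalg.norm(v, axis=1, keepdims=True)
    safe = np.maximum(speed, _EPS)
    target = np.clip(speed, params.min_speed, params.max_speed)
    return v / safe * target


def _contain(positions: np.ndarray, velocities: np.ndarray, geometry: TankGeometry,
             barrier: Barrier | None) -> None:
    """Reflect positions/velocities at the wall, floor, lid and barrier, in place."""
    # cylinder wall (mirror the radial overshoot, flip radial velocity)
    xy = positions[:, :2]
    r = np.linalg.norm(xy, axis=1)
    r_in = geometry.inner_radius
    out = r > r_in
    if np.any(out):
        u = xy[out] / r[out, None]
        r_new = np.clip(2 * r_in - r[out], 0.0, r_in)
        positions[out, :2] = u * r_new[:, None]
        v_rad = np.sum(velocities[out, :2] * u, axis=1)
        flip = v_rad > 0
        rows = np.where(out)[0][flip]
        velocities[rows, :2] -= 2 * v_rad[flip, None] * u[flip]

    # floor / lid
    z = positions[:, 2]
    below = z < 0
    positions[below, 2] = np.minimum(-z[below], geometry.height)
    velocities[below, 2] = np.abs(velocities[below, 2])
    above = positions[:, 2] > geometry.height
    positions[above, 2] = np.clip(2 * geometry.height - positions[above, 2], 0, geometry.height)
    velocities[above, 2] = -np.abs(velocities[above, 2])

    if barrier is not None:
        inside = barrier.contains(positions)
        if np.any(inside):
            c = np.asarray(barrier.center)
            h = np.asarray(barrier.half_extents)
            rows = np.where(inside)[0]
            pen = h - np.abs(positions[rows] - c)
            axis = np.argmin(pen, axis=1)
            sign = np.sign(positions[rows, axis] - c[axis])
            sign[sign == 0] = 1.0
            positions[rows, axis] = c[axis] + sign * h[axis]
            wrong_way = np.sign(velocities[rows, axis]) == -sign
            velocities[rows[wrong_way], axis[wrong_way]] *= -1


def step(
    state: SchoolState,
    geometry: TankGeometry,
    barrier: Barrier | None,
    vortices,
    params: BoidsParams,
) -> SchoolState:
    """One explicit-Euler step followed by hard containment projection."""
    bad_state = ~(
        np.all(np.isfinite(state.positions), axis=1)
        & np.all(np.isfinite(state.velocities), axis=1)
    )
    if np.any(bad_state):
        idx = int(np.where(bad_state)[0][0])
        raise NumericalFailureError(f"non-finite state for fish {idx}", fish_index=idx)
    acc = (
        boids_steering(state, params)
        + avoidance_acceleration(state, geometry, barrier)
        + _vortex_accels(state.positions, vortices)
    )
    bad = ~np.all(np.isfinite(acc), axis=1)
    if np.any(bad):
        idx = int(np.where(bad)[0][0])
        raise NumericalFailureError(f"non-finite acceleration for fish {idx}", fish_index=idx)

    v = _clamp_speed(state.velocities + params.dt * acc, params)
    p = state.positions + params.dt * v
    _contain(p, v, geometry, barrier)
    return SchoolState(positions=p, velocities=v, time=state.time + params.dt,
                       rng_seed=state.rng_seed)


def simulate(
    config: SimulationConfig,
    n_steps: int,
    seed: int,
    thin: int = 1,
    initial_state: SchoolState | None = None,
) -> list[SchoolState]:
    """Run ``n_steps`` steps from a seeded initial school; return every ``thin``-th state.

    The final state is always included. Identical (config, seed) pairs give
    bit-identical trajectories.
    """
    if n_steps < 1:
        raise InvalidArgumentError("n_steps must be >= 1")
    if thin < 1:
        raise InvalidArgumentError("thin must be >= 1")
    state = initial_state if initial_state is not None else init_school(
        config.n_fish, config.geometry, config.params, seed, barrier=config.barrier
    )
    out: list[SchoolState] = []
    for i in range(1, n_steps + 1):
        state = step(state, config.geometry, config.barrier, config.vortices, config.params)
        if i % thin == 0 or i == n_steps:
            out.append(state.copy())
        if i % 1000 == 0:
            _log_summary(state, i)
    return out


def _log_summary(state: SchoolState, step_no: int) -> None:
    speed = np.linalg.norm(state.velocities, axis=1)
    xy = state.positions[:, :2]
    r = np.linalg.norm(xy, axis=1)
    ok = r > _EPS
    # tangential speed: v . t_hat with t_hat = (-y, x)/r
    vt = np.where(
        ok,
        (-xy[:, 1] * state.velocities[:, 0] + xy[:, 0] * state.velocities[:, 1])
        / np.maximum(r, _EPS),
        0.0,
    )
    logger.info(
        "step %d: mean speed %.3f m/s, mean z %.2f m, mean tangential velocity %.3f m/s",
        step_no, speed.mean(), state.positions[:, 2].mean(), vt.mean(),
    )


def mean_tangential_velocity(state: SchoolState) -> float:
    """School-mean signed tangential velocity about the tank axis (m/s; + is CCW)."""
    xy = state.positions[:, :2]
    r = np.linalg.norm(xy, axis=1)
    ok = r > _EPS
    vt = (-xy[ok, 1] * state.velocities[ok, 0] + xy[ok, 0] * state.velocities[ok, 1]) / r[ok]
    return float(vt.mean()) if vt.size else 0.0


def save_trajectory(path, trajectory: list[SchoolState]) -> None:
    """Write a thinned trajectory as named arrays (positions, velocities, times)."""
    np.savez_compressed(
        path,
        positions=np.stack([s.positions for s in trajectory]),
        velocities=np.stack([s.velocities for s in trajectory]),
        times=np.array([s.time for s in trajectory]),
        rng_seed=np.array(trajectory[0].rng_seed),
    )


def load_trajectory(path) -> list[SchoolState]:
    with np.load(path) as data:
        seed = int(data["rng_seed"])
        return [
            SchoolState(positions=p.copy(), velocities=v.copy(), time=float(t), rng_seed=seed)
            for p, v, t in zip(data["positions"], data["velocities"], data["times"])
        ]
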
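import numpy as np
import pytest

from rastank import boids, render


@pytest.fixture
def small_tank() -> boids.TankGeometry:
    return boids.TankGeometry(radius=2.0, height=1.5, wall_margin=0.15)


@pytest.fixture
def default_params() -> boids.BoidsParams:
    return boids.BoidsParams()


@pytest.fixture
def small_camera() -> render.CameraSpec:
    return render.CameraSpec(width=64, height=64, hfov=90.0, position=(0.0, 0.0, 0.0),
                             view_direction=(0.0, 1.0, 0.0), up=(0.0, 0.0, 1.0))


@pytest.fixture
def fish_mesh() -> render.FishMesh:
    return render.procedural_fish_mesh()


def make_state(positions, velocities=None, seed=0) -> boids.SchoolState:
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if velocities is None:
        velocities = np.zeros_like(positions)
    else:
        velocities = np.atleast_2d(np.asarray(velocities, dtype=float))
    return boids.SchoolState(positions=positions, velocities=velocities, time=0.0, rng_seed=seed)


def random_layered_frame(rng, h=64, w=64, max_fish=10):
    """Random index/depth layers for annotation tests: blobby fish ids + noise depth."""
    index = np.zeros((h, w), dtype=np.int32)
    n_fish = rng.integers(0, max_fish + 1)
    for fid in range(1, n_fish + 1):
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        ry, rx = rng.integers(1, 8), rng.integers(1, 8)
        yy, xx = np.ogrid[:h, :w]
        blob = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        index[blob] = fid  # later fish may occlude earlier ones
    depth = np.full((h, w), np.inf)
    fg = index > 0
    depth[fg] = rng.uniform(0.5, 6.0, size=int(fg.sum()))
    rgb = np.zeros((h, w, 3))
    rgb[fg] = rng.uniform(0.2, 1.0, size=(int(fg.sum()), 3))
    return render.LayeredFrame(rgb=rgb, depth=depth, index=index)
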
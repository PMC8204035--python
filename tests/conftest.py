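import numpy as np
import pytest

from erupt3d.core_io import ImageVolume, RigidTransform
from erupt3d.phantom import PhantomSpec, batch_generate, generate_pair, make_tooth_mesh


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def tooth_mesh(default_spec):
    """Clean analytic tooth surface (tooth frame)."""
    return make_tooth_mesh(default_spec)


@pytest.fixture(scope="session")
def cohort20(default_spec):
    """20 phantom pairs with randomized local + global motions (seeds 1-20)
    and their ground-truth table; shared across the suite."""
    pairs, truth = batch_generate(20, default_spec, list(range(1, 21)))
    return pairs, truth


@pytest.fixture(scope="session")
def phantom_pair(cohort20):
    """One representative phantom pair with nonzero local + global motion."""
    return cohort20[0][0]


@pytest.fixture(scope="session")
def null_pair(default_spec):
    """Zero local tooth motion but nonzero global repositioning."""
    import numpy as np
    from dataclasses import replace
    from scipy.spatial.transform import Rotation

    r = Rotation.from_euler("xyz", [2.0, -1.5, 3.0], degrees=True).as_matrix()
    center = np.array(default_spec.grid_dims) * default_spec.voxel_mm / 2
    glob = RigidTransform.from_rotation_translation(
        r, np.array([1.0, -0.8, 1.2]) + center - r @ center)
    return generate_pair(replace(default_spec, global_motion=glob, seed=99))


@pytest.fixture(scope="session")
def pipeline_result(phantom_pair):
    """Full-pipeline output on the representative pair (shared)."""
    from erupt3d.pipeline import run_phantom_case

    return run_phantom_case(phantom_pair, run_seed=11)


def make_smooth_volume(shape=(56, 56, 56), spacing=0.2, seed=0,
                       transform: RigidTransform | None = None) -> ImageVolume:
    """Band-limited synthetic volume sampled from an analytic field, so a
    rigidly moved copy with known ground truth can be resampled exactly."""
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(8, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    freqs = rng.uniform(0.3, 1.2, size=8)           # cycles / mm
    phases = rng.uniform(0, 2 * np.pi, size=8)
    amps = rng.uniform(0.5, 1.0, size=8)

    nz, ny, nx = shape
    half = spacing / 2
    xs = half + spacing * np.arange(nx)
    ys = half + spacing * np.arange(ny)
    zs = half + spacing * np.arange(nz)
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    if transform is not None:
        pts = transform.inverse().apply(pts)
    vals = np.zeros(len(pts))
    for d, f, ph, a in zip(dirs, freqs, phases, amps):
        vals += a * np.sin(2 * np.pi * f * (pts @ d) + ph)
    return ImageVolume(vals.reshape(shape), np.full(3, spacing), np.full(3, half))
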
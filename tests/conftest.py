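import numpy as np
import pytest

import mlmoshape as ms
from mlmoshape.particles import ParticleSystem


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tetra_mesh():
    vertices = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return ms.SurfaceMesh(vertices, faces)


@pytest.fixture(scope="session")
def small_ensemble():
    """Centered 4-subject, 2-object supershape ensemble (coarse meshes)."""
    cfg = ms.EnsembleConfig(
        n_subjects=4, n_objects=2, mesh_resolution=14, seed=42
    )
    subjects, manifest = ms.generate_synthetic_ensemble(cfg)
    subjects, _ = ms.center_ensemble(subjects)
    return subjects, manifest, cfg


def random_system(rng, n_subjects=4, counts=(2, 3), spread=3.0, offset=20.0):
    counts = list(counts)
    pts = rng.normal(scale=spread, size=(n_subjects, sum(counts), 3))
    pts += rng.normal(scale=offset, size=(n_subjects, 1, 3))
    return ParticleSystem(
        pts,
        counts,
        [f"s{i}" for i in range(n_subjects)],
        [f"o{k}" for k in range(len(counts))],
    )


@pytest.fixture
def make_system(rng):
    return lambda **kw: random_system(rng, **kw)
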
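import numpy as np
import pytest

import mlmoshape as ms
from mlmoshape.analysis import SubspaceModel, fit_mlca, fit_shared_pca
from mlmoshape.metrics import (
    compactness,
    coverage_area,
    dominant_mode_count,
    generalization,
    generalization_curve,
    relative_error,
    specificity,
)
from mlmoshape.mlmo import decompose
from mlmoshape.particles import ParticleSystem

from conftest import random_system


def unit_square(z=0.0, shift=(0.0, 0.0)):
    sx, sy = shift
    v = np.array(
        [[sx, sy, z], [1 + sx, sy, z], [1 + sx, 1 + sy, z], [sx, 1 + sy, z]]
    )
    return ms.SurfaceMesh(v, np.array([[0, 1, 2], [0, 2, 3]]))


def ray_hits_triangle(o, d, tri, eps=1e-9):
    """Scalar Möller–Trumbore, written independently as the test oracle."""
    e1, e2 = tri[1] - tri[0], tri[2] - tri[0]
    h = np.cross(d, e2)
    a = np.dot(e1, h)
    if abs(a) < 1e-14:
        return False
    f = 1.0 / a
    s = o - tri[0]
    u = f * np.dot(s, h)
    if u < -1e-12 or u > 1 + 1e-12:
        return False
    q = np.cross(s, e1)
    v = f * np.dot(d, q)
    if v < -1e-12 or u + v > 1 + 1e-12:
        return False
    return f * np.dot(e2, q) > eps


def coverage_oracle(mesh_a, mesh_b):
    area = 0.0
    for fid in range(len(mesh_a.faces)):
        o = mesh_a.triangles[fid].mean(axis=0)
        d = mesh_a.face_normals[fid]
        if any(ray_hits_triangle(o, d, tri) for tri in mesh_b.triangles):
            area += mesh_a.face_areas[fid]
    return area


class TestCompactness:
    def test_definition(self):
        model = SubspaceModel("G", np.zeros(3), np.eye(3),
                              np.array([3.0, 2.0, 1.0]), [1], ["a"])
        assert compactness(model, 2) == 5.0
        assert compactness(model, 3) == model.total_variance
        with pytest.raises(ValueError):
            compactness(model, 4)

    def test_cumulative_fraction_monotone(self, rng):
        sys_ = random_system(rng, n_subjects=6)
        model = fit_shared_pca(sys_)
        vals = [compactness(model, p) for p in range(1, model.rank + 1)]
        fr = np.array(vals) / model.total_variance
        assert (np.diff(fr) >= -1e-12).all() and fr[0] > 0 and fr[-1] == pytest.approx(1.0)


class TestGeneralization:
    def test_identical_subjects_zero_error(self):
        pts = np.tile(np.arange(12, dtype=float).reshape(1, 4, 3), (5, 1, 1))
        sys_ = ParticleSystem(pts, [2, 2], [f"s{i}" for i in range(5)], ["a", "b"])
        for tag in ("G", ("W", 0), "B"):
            assert generalization(sys_, tag, 1) == pytest.approx(0.0, abs=1e-9)

    def test_rank_one_data_perfect_with_one_mode(self, rng):
        base = rng.normal(size=(1, 4, 3))
        direction = rng.normal(size=(1, 4, 3))
        ts = np.linspace(-1, 1, 8).reshape(-1, 1, 1)
        sys_ = ParticleSystem(base + ts * direction, [4],
                              [f"s{i}" for i in range(8)], ["a"])
        scale = np.abs(sys_.points).max()
        assert generalization(sys_, "G", 1) <= 1e-6 * scale

    def test_matches_naive_reimplementation(self, rng):
        sys_ = random_system(rng, n_subjects=6, counts=(2, 3))
        for tag in ("G", ("W", 1), "B"):
            if tag == "G":
                data = sys_.flattened()
            else:
                dec = decompose(sys_)
                data = dec.between if tag == "B" else dec.within[tag[1]]
            n = data.shape[1]
            for p in (1, 2, 3):
                errs = []
                for i in range(n):  # naive: dense covariance PCA per fold
                    train = np.delete(data, i, axis=1)
                    mu = train.mean(axis=1)
                    tc = train - mu[:, None]
                    lam, u = np.linalg.eigh(tc @ tc.T / (n - 2))
                    u = u[:, np.argsort(lam)[::-1]][:, :p]
                    resid = data[:, i] - mu
                    errs.append(np.linalg.norm(resid - u @ (u.T @ resid)))
                assert generalization(sys_, tag, p) == pytest.approx(
                    float(np.mean(errs)), abs=1e-9
                )

    def test_requires_three_subjects(self, rng):
        sys_ = random_system(rng, n_subjects=2)
        with pytest.raises(ValueError):
            generalization_curve(sys_, "G")


class TestSpecificity:
    def test_degenerate_model_at_training_sample(self):
        training = np.tile(np.arange(4.0)[:, None], (1, 3))
        model = SubspaceModel("G", training[:, 0], np.zeros((4, 0)),
                              np.zeros(0), [1], ["a"])
        assert specificity(model, training, 0, 100, seed=1) == pytest.approx(0.0)

    def test_matches_naive_loop_oracle(self, rng):
        sys_ = random_system(rng, n_subjects=5, counts=(2, 2))
        model = fit_shared_pca(sys_)
        training = sys_.flattened()
        p, t, seed = 2, 50, 9
        got = specificity(model, training, p, t, seed)
        rng2 = np.random.default_rng(seed)
        coeff = rng2.standard_normal((t, p)) * np.sqrt(model.eigenvalues[:p])
        naive = []
        for c in coeff:
            v = model.mean + model.eigenvectors[:, :p] @ c
            naive.append(min(np.linalg.norm(v - training[:, j]) for j in range(5)))
        assert got == pytest.approx(float(np.mean(naive)), abs=1e-9)

    def test_deterministic_given_seed(self, rng):
        sys_ = random_system(rng, n_subjects=5)
        model = fit_shared_pca(sys_)
        a = specificity(model, sys_.flattened(), 2, 1000, seed=4)
        b = specificity(model, sys_.flattened(), 2, 1000, seed=4)
        assert a == b

    def test_monte_carlo_consistency(self, rng):
        sys_ = random_system(rng, n_subjects=5)
        model = fit_shared_pca(sys_)
        tr = sys_.flattened()
        small = specificity(model, tr, 2, 1000, seed=0)
        big = specificity(model, tr, 2, 10000, seed=1)
        # crude SE estimate from the spread of independent small runs
        reps = [specificity(model, tr, 2, 1000, seed=s) for s in range(2, 10)]
        se = np.std(reps)
        assert abs(small - big) < 3 * max(se, 1e-9) + 3 * se


class TestCoverage:
    def test_parallel_squares_full_coverage(self):
        a, b = unit_square(0.0), unit_square(1.0)
        assert coverage_area(a, b) == pytest.approx(1.0)
        assert coverage_area(a, b) == pytest.approx(coverage_oracle(a, b))

    def test_half_offset_squares(self):
        a = unit_square(0.0)
        b = unit_square(1.0, shift=(0.5, 0.0))
        assert coverage_area(a, b) == pytest.approx(0.5)
        assert coverage_area(a, b) == pytest.approx(coverage_oracle(a, b))

    def test_random_meshes_match_oracle(self, rng):
        sphere = ms.SupershapeSpec(0, 2, 2, 2)
        a = ms.build_supershape_mesh(sphere, sphere, 8, 1.0)
        b = ms.SurfaceMesh(
            ms.build_supershape_mesh(sphere, sphere, 8, 1.5).vertices
            + np.array([0.8, 0.0, 0.0]),
            a.faces.copy(),
        )
        assert coverage_area(a, b) == pytest.approx(coverage_oracle(a, b))

    def test_concentric_spheres(self):
        sphere = ms.SupershapeSpec(0, 2, 2, 2)
        inner = ms.build_supershape_mesh(sphere, sphere, 64, 1.0)
        outer = ms.build_supershape_mesh(sphere, sphere, 64, 2.0)
        cov = coverage_area(inner, outer)
        assert abs(cov - 4 * np.pi) / (4 * np.pi) < 0.02

    def test_bounded_by_own_area(self, rng):
        a = unit_square(0.0)
        b = unit_square(1.0, shift=(0.9, 0.9))
        assert coverage_area(a, b) <= a.area + 1e-12

    def test_convex_self_coverage_zero(self):
        sphere = ms.SupershapeSpec(0, 2, 2, 2)
        mesh = ms.build_supershape_mesh(sphere, sphere, 12, 1.0)
        assert coverage_area(mesh, mesh) == pytest.approx(0.0)


class TestScalarMetrics:
    @pytest.mark.parametrize(
        "a_hat,a,expected", [(100.0, 100.0, 0.0), (104.0, 100.0, 0.04), (0.0, 50.0, 1.0)]
    )
    def test_relative_error(self, a_hat, a, expected):
        assert relative_error(a_hat, a) == pytest.approx(expected)

    def test_relative_error_guard(self):
        with pytest.raises(ValueError):
            relative_error(1.0, 0.0)

    def test_dominant_mode_count(self):
        assert dominant_mode_count([0.98, 0.01, 0.01], 0.05) == 1
        assert dominant_mode_count([1.0, 1.0, 1.0, 1.0], 0.05) == 4
        with pytest.raises(ValueError):
            dominant_mode_count([0.0, 0.0])
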
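import numpy as np
import pytest

import mlmoshape as ms
from mlmoshape.entropy import (
    center_columns,
    correspondence_gradient,
    parzen_sigmas,
    sampling_entropy,
    subspace_entropy,
)
from mlmoshape.geometry import closest_points
from mlmoshape.optimizer import initialize_particles, optimize, split_particles


def fd_gradient(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x1, x2 = x.copy(), x.copy()
        x1[i] += eps
        x2[i] -= eps
        g[i] = (f(x1) - f(x2)) / (2 * eps)
    return g


class TestSamplingEntropy:
    def test_two_particles_repel_symmetrically(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        _, g = sampling_entropy(pts, np.array([0.5, 0.5]))
        assert np.allclose(g[0], -g[1])
        assert g[1][0] > 0  # pushes apart along +x

    def test_simplex_symmetry(self):
        # regular tetrahedron: equal gradient magnitudes, zero net force
        pts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        _, g = sampling_entropy(pts, np.full(4, 1.0))
        mags = np.linalg.norm(g, axis=1)
        assert np.allclose(mags, mags[0], rtol=1e-10)
        assert np.allclose(g.sum(axis=0), 0.0, atol=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        pts = rng.normal(size=(10, 3))
        sig = parzen_sigmas(pts, 1e-3)
        _, g = sampling_entropy(pts, sig)
        gfd = fd_gradient(lambda p: sampling_entropy(p, sig)[0], pts)
        assert np.abs(g - gfd).max() / np.abs(gfd).max() < 1e-5

    def test_single_particle_is_inert(self):
        h, g = sampling_entropy(np.zeros((1, 3)), np.array([1.0]))
        assert h == 0.0 and np.allclose(g, 0.0)


class TestSubspaceEntropy:
    def test_degenerate_covariance_hits_regularization_floor(self):
        y = np.zeros((5, 3))
        assert subspace_entropy(y, 0.2) == pytest.approx(0.5 * 5 * np.log(0.2))

    def test_one_row_closed_form(self):
        y = np.array([[-1.0, 1.0]])  # covariance 2/(N-1) = 2
        assert subspace_entropy(y, 0.3) == pytest.approx(0.5 * np.log(2.3))

    def test_dual_equals_primal(self, rng):
        y = center_columns(rng.normal(size=(6, 4)))
        lam = np.clip(np.linalg.eigvalsh(y @ y.T / 3), 0.0, None)
        dense = 0.5 * np.sum(np.log(lam + 0.05))
        assert abs(subspace_entropy(y, 0.05) - dense) < 1e-10
        # tall case exercises the Gram path
        y = center_columns(rng.normal(size=(30, 4)))
        lam = np.clip(np.linalg.eigvalsh(y @ y.T / 3), 0.0, None)
        dense = 0.5 * np.sum(np.log(lam + 0.05))
        assert abs(subspace_entropy(y, 0.05) - dense) < 1e-9

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            subspace_entropy(np.zeros((3, 1)), 0.1)


class TestCorrespondenceGradient:
    def test_zero_matrix_zero_update(self):
        assert np.allclose(correspondence_gradient(np.zeros((4, 3)), 0.1), 0.0)

    def test_matches_finite_differences(self, rng):
        y = center_columns(rng.normal(size=(6, 4)))
        g = correspondence_gradient(y, 0.05)
        gfd = fd_gradient(lambda m: subspace_entropy(m, 0.05), y)
        assert np.abs(g - gfd).max() / np.abs(gfd).max() < 1e-6

    def test_negative_gradient_descends(self, rng):
        y = center_columns(rng.normal(size=(8, 5)))
        g = correspondence_gradient(y, 0.1)
        h0 = subspace_entropy(y, 0.1)
        assert subspace_entropy(y - 1e-4 * g, 0.1) < h0


class TestInitializeAndSplit:
    def test_level_zero_placement(self, small_ensemble):
        subjects, _, _ = small_ensemble
        sys_ = initialize_particles(subjects, [8, 8], seed=0)
        assert sys_.counts == [1, 1]
        for n, subj in enumerate(subjects):
            for k, organ in enumerate(subj.organs):
                p = sys_.organ_points(n, k)[0]
                # on the surface, and within the near-tie band (5%) of the
                # true closest point to the organ centroid
                _, _, d_surf = closest_points(organ, p.reshape(1, 3))
                assert d_surf[0] < 1e-9
                _, _, d_min = closest_points(organ, organ.centroid.reshape(1, 3))
                d_p = np.linalg.norm(p - organ.centroid)
                assert d_p <= d_min[0] * 1.05 + 1e-9

    def test_power_of_two_required(self, small_ensemble):
        subjects, _, _ = small_ensemble
        with pytest.raises(ValueError):
            initialize_particles(subjects, [8, 6], seed=0)
        with pytest.raises(ValueError):
            ms.OptimizerConfig(particles_per_organ=[12])

    def test_split_doubles_and_preserves_parents(self, small_ensemble):
        subjects, _, _ = small_ensemble
        sys0 = initialize_particles(subjects, [4, 4], seed=0)
        sys1 = split_particles(sys0, subjects, seed=3)
        assert sys1.counts == [2, 2]
        for n in range(sys0.n_subjects):
            for k in range(2):
                parents = sys1.organ_points(n, k)[:1]
                assert np.array_equal(parents, sys0.organ_points(n, k))

    def test_split_determinism_and_child_order(self, small_ensemble):
        subjects, _, _ = small_ensemble
        sys0 = initialize_particles(subjects, [4, 4], seed=0)
        a = split_particles(split_particles(sys0, subjects, seed=3), subjects, seed=4)
        b = split_particles(split_particles(sys0, subjects, seed=3), subjects, seed=4)
        assert np.array_equal(a.points, b.points)
        assert a.counts == [4, 4]

    def test_split_per_organ_independent(self, small_ensemble):
        subjects, _, _ = small_ensemble
        sys0 = initialize_particles(subjects, [4, 2], seed=0)
        sys1 = split_particles(sys0, subjects, seed=1, organs=[0])
        assert sys1.counts == [2, 1]


@pytest.fixture(scope="module")
def small_run(small_ensemble):
    subjects, _, _ = small_ensemble
    cfg = ms.OptimizerConfig(
        particles_per_organ=[16, 16], mode="mlmo",
        iterations_per_split_level=6, seed=7,
    )
    system, trace = optimize(subjects, cfg)
    return subjects, cfg, system, trace


class TestOptimize:
    def test_particles_stay_on_surface(self, small_run):
        subjects, cfg, system, _ = small_run
        worst = 0.0
        for n, subj in enumerate(subjects):
            for k, sl in enumerate(system.organ_slices):
                _, _, d = closest_points(subj.organs[k], system.points[n, sl])
                worst = max(worst, d.max())
        assert worst <= cfg.tau_surf

    def test_energy_non_increasing_per_phase(self, small_run):
        _, _, _, trace = small_run
        assert (trace.Q_post <= trace.Q_pre + 1e-9 * trace.Q_pre.abs().clip(1.0)).all()

    def test_determinism(self, small_ensemble, small_run):
        subjects, _, _ = small_ensemble
        _, cfg, system, _ = small_run
        again, _ = optimize(subjects, cfg)
        assert np.array_equal(system.points, again.points)

    def test_particles_spread_without_collisions(self, small_run):
        _, _, system, _ = small_run
        for n in range(system.n_subjects):
            for k in range(system.n_organs):
                pts = system.organ_points(n, k)
                d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
                np.fill_diagonal(d, np.inf)
                assert d.min() > 0.0

    def test_global_with_one_organ_equals_single(self, small_ensemble):
        subjects, _, _ = small_ensemble
        solo = [
            ms.MultiOrganSubject(s.subject_id, [s.organs[0]], [s.organ_labels[0]])
            for s in subjects
        ]
        kw = dict(particles_per_organ=[8], iterations_per_split_level=4, seed=3)
        a, _ = optimize(solo, ms.OptimizerConfig(mode="global", **kw))
        b, _ = optimize(solo, ms.OptimizerConfig(mode="single", **kw))
        assert np.array_equal(a.points, b.points)

    def test_identical_subjects_converge_to_identical_particles(self, small_ensemble):
        subjects, _, _ = small_ensemble
        clones = [
            ms.MultiOrganSubject(f"c{i}", subjects[0].organs, subjects[0].organ_labels)
            for i in range(3)
        ]
        cfg = ms.OptimizerConfig(
            particles_per_organ=[8, 8], mode="global",
            iterations_per_split_level=10, seed=1,
        )
        system, _ = optimize(clones, cfg)
        spread = np.abs(system.points - system.points[0]).max()
        assert spread < 1e-6  # identical inputs leave nothing for shape terms

    def test_requires_three_subjects(self, small_ensemble):
        subjects, _, _ = small_ensemble
        with pytest.raises(ValueError):
            optimize(subjects[:2], ms.OptimizerConfig(particles_per_organ=[4, 4]))
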
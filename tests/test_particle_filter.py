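import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ceustrack import (
    BoundingBox,
    FlowModel,
    candidates,
    init_particles,
    resample,
    similarity,
    weigh_particles,
)
from ceustrack.optical_flow import FlowField
from ceustrack.particle_filter import kernel_weights

FRAME = (64, 64)
TARGET = BoundingBox(24, 24, 12, 12)


class TestInit:
    def test_zero_spread_collapses_to_center(self):
        pset = init_particles(TARGET, FRAME, n=20, spread=0.0)
        assert np.allclose(pset.centers, TARGET.center)
        assert np.allclose(pset.weights, 1 / 20)

    def test_single_particle_has_unit_weight(self):
        pset = init_particles(TARGET, FRAME, n=1)
        assert pset.n == 1 and pset.particles[0].weight == 1.0

    def test_fixed_seed_reproduces_cloud(self):
        a = init_particles(TARGET, FRAME, n=50, seed=9)
        b = init_particles(TARGET, FRAME, n=50, seed=9)
        assert np.array_equal(a.centers, b.centers)

    def test_all_particle_boxes_inside_frame(self):
        pset = init_particles(TARGET, FRAME, n=200, spread=40.0, seed=0)
        assert all(p.region.inside(FRAME) for p in pset.particles)

    def test_oversized_target_rejected(self):
        with pytest.raises(ValueError):
            init_particles(BoundingBox(0, 0, 100, 100), FRAME, n=5)


class TestSimilarity:
    def test_self_similarity_is_one(self):
        assert similarity((3.0, 4.0), (3.0, 4.0)) == pytest.approx(1.0)
        assert similarity((3.0, 4.0), (6.0, 8.0)) == pytest.approx(1.0)  # scale-free

    def test_orthogonal_vectors_score_zero(self):
        assert similarity((1.0, 0.0), (0.0, 5.0)) == pytest.approx(0.0)

    def test_45_degree_example(self):
        assert similarity((1.0, 1.0), (1.0, 0.0)) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_scores_zero(self):
        assert similarity((0.0, 0.0), (1.0, 2.0)) == 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            similarity((np.nan, 0.0), (1.0, 0.0))


class TestWeights:
    def test_two_particle_kernel_hand_values(self):
        w = kernel_weights(np.array([1.0, 0.6]), epsilon=0.2)
        assert w == pytest.approx([0.8808, 0.1192], abs=5e-5)
        # raw weight of the best particle is exp(0)=1, the set maximum
        raw = np.exp(-((np.array([1.0, 0.6]) - 1.0) ** 2) / (2 * 0.2**2))
        assert raw[0] == 1.0 and raw[0] == raw.max()

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_weights_normalize_after_weighting(self, seed):
        rng = np.random.default_rng(seed)
        flow = FlowField(u=rng.normal(size=FRAME), v=rng.normal(size=FRAME))
        pset = init_particles(TARGET, FRAME, n=30, seed=seed)
        model = FlowModel(h=(rng.normal(), rng.normal()), w=1.0)
        weigh_particles(pset, model, flow)
        assert pset.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_particles_get_uniform_weights(self):
        flow = FlowField(u=np.ones(FRAME), v=np.zeros(FRAME))
        pset = init_particles(TARGET, FRAME, n=10, spread=0.0)
        weigh_particles(pset, FlowModel(h=(5.0, 0.0), w=1.0), flow)
        assert np.allclose(pset.weights, 0.1)


class TestResample:
    def _weighted(self, weights, seed=0):
        pset = init_particles(TARGET, FRAME, n=len(weights), spread=10.0, seed=seed)
        for p, w in zip(pset.particles, weights):
            p.weight = w
        return pset

    def test_degenerate_weights_clone_the_winner(self):
        pset = self._weighted([1.0] + [0.0] * 9)
        winner = pset.particles[0].center
        out = resample(pset, seed=1, jitter_sigma=0.0)
        assert np.allclose(out.centers, winner)

    def test_uniform_weights_keep_every_particle_once(self):
        # systematic resampling with equal weights is a permutation-free copy
        pset = self._weighted([0.1] * 10)
        out = resample(pset, seed=2, jitter_sigma=0.0)
        assert np.allclose(np.sort(out.centers, axis=0), np.sort(pset.centers, axis=0))

    def test_fixed_seed_reproduces_resample(self):
        pset = self._weighted(list(np.random.default_rng(3).dirichlet(np.ones(20))))
        a = resample(pset, seed=11)
        b = resample(pset, seed=11)
        assert np.array_equal(a.centers, b.centers)

    def test_weights_reset_to_uniform(self):
        pset = self._weighted([0.5, 0.3, 0.2])
        out = resample(pset, seed=0)
        assert np.allclose(out.weights, 1 / 3)


class TestCandidates:
    def test_all_distinct_particles_returned_for_k_equals_n(self):
        pset = init_particles(TARGET, FRAME, n=8, spread=15.0, seed=4)
        for i, p in enumerate(pset.particles):
            p.weight = (i + 1) / 36
        cands = candidates(pset, k=8)
        assert len(cands) == 8

    def test_k1_returns_argmax_weight(self):
        pset = init_particles(TARGET, FRAME, n=5, spread=15.0, seed=5)
        weights = [0.1, 0.5, 0.2, 0.1, 0.1]
        for p, w in zip(pset.particles, weights):
            p.weight = w
        cands = candidates(pset, k=1)
        assert cands.regions[0] == pset.particles[1].region

    def test_weight_ties_break_to_lower_index(self):
        pset = init_particles(TARGET, FRAME, n=4, spread=15.0, seed=6)
        for p in pset.particles:
            p.weight = 0.25
        cands = candidates(pset, k=2)
        assert cands.regions[0] == pset.particles[0].region
        assert cands.regions[1] == pset.particles[1].region

    def test_near_duplicate_centers_deduplicated(self):
        pset = init_particles(TARGET, FRAME, n=6, spread=0.0)
        for i, p in enumerate(pset.particles):
            p.weight = 1 / 6
        cands = candidates(pset, k=6)
        assert len(cands) == 1  # all at the same center

    def test_k_larger_than_n_rejected(self):
        pset = init_particles(TARGET, FRAME, n=3)
        with pytest.raises(ValueError):
            candidates(pset, k=4)
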
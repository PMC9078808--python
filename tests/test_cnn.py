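import numpy as np
import pytest

from ceustrack import BoundingBox, normalize_patch, train_classifier, classify_candidates
from ceustrack.cnn import first_frame_training_set
from ceustrack.particle_filter import CandidateSet


def _separable_patches(n=16, size=32, seed=0):
    """Bright vs. dark patches: linearly separable by mean intensity."""
    rng = np.random.default_rng(seed)
    bright = 0.8 + 0.05 * rng.standard_normal((n, size, size))
    dark = 0.2 + 0.05 * rng.standard_normal((n, size, size))
    return np.clip(bright, 0, 1), np.clip(dark, 0, 1)


class TestNormalizePatch:
    def test_identity_when_region_matches_out_size(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 255, size=(64, 64))
        patch = normalize_patch(frame, BoundingBox(10, 20, 32, 32), out_size=32)
        assert np.allclose(patch.pixels, frame[10:42, 20:52] / 255.0)

    def test_constant_region_stays_constant(self):
        frame = np.full((40, 40), 200.0)
        patch = normalize_patch(frame, BoundingBox(5, 5, 10, 20))
        assert np.allclose(patch.pixels, 200.0 / 255.0)

    def test_downscale_preserves_mean_of_checkerboard(self):
        board = np.indices((64, 64)).sum(axis=0) % 2 * 255.0
        patch = normalize_patch(board, BoundingBox(0, 0, 64, 64), out_size=32)
        assert patch.pixels.mean() == pytest.approx(board.mean() / 255.0, rel=0.01)

    def test_zero_area_region_rejected(self):
        with pytest.raises(ValueError):
            normalize_patch(np.zeros((8, 8)), BoundingBox(0, 0, 0, 4))


class TestTraining:
    def test_separable_classes_reach_perfect_training_accuracy(self):
        pos, neg = _separable_patches()
        model = train_classifier(pos, neg, epochs=50, seed=0)
        preds = np.concatenate([model.score(pos) > 0.5, model.score(neg) > 0.5])
        labels = np.concatenate([np.ones(len(pos), bool), np.zeros(len(neg), bool)])
        assert np.mean(preds == labels) == 1.0
        assert model.history[-1] < model.history[0]  # loss decreased

    def test_fixed_seed_gives_identical_weights(self):
        pos, neg = _separable_patches(n=4)
        a = train_classifier(pos, neg, epochs=5, seed=7)
        b = train_classifier(pos, neg, epochs=5, seed=7)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_identical_positive_and_negative_pins_accuracy_at_half(self):
        patch = np.full((32, 32), 0.5)
        model = train_classifier(patch[None], patch[None], epochs=30, seed=0)
        # the two samples are indistinguishable: exactly one is classified right
        preds = model.score(np.stack([patch, patch])) > 0.5
        labels = np.array([True, False])
        assert np.mean(preds == labels) == 0.5

    def test_empty_class_rejected(self):
        pos, _ = _separable_patches(n=2)
        with pytest.raises(ValueError):
            train_classifier(pos, np.empty((0, 32, 32)))


@pytest.fixture(scope="module")
def lesion_frame_and_model():
    # dark square lesion on a bright noisy background
    rng = np.random.default_rng(2)
    frame = np.clip(200 + 10 * rng.standard_normal((64, 64)), 0, 255)
    target = BoundingBox(20, 24, 16, 16)
    frame[target.slices()] *= 0.35
    model_rng = np.random.default_rng(3)
    pos, neg = first_frame_training_set(frame, target, model_rng)
    model = train_classifier(pos, neg, epochs=30, seed=model_rng)
    return frame, target, model


class TestClassifyCandidates:

    def test_single_candidate_returned_with_score(self, lesion_frame_and_model):
        frame, target, model = lesion_frame_and_model
        ranked = classify_candidates(model, CandidateSet(regions=[target]), frame)
        assert len(ranked) == 1
        assert 0.0 <= ranked[0][1] <= 1.0

    def test_duplicate_candidates_score_identically(self, lesion_frame_and_model):
        frame, target, model = lesion_frame_and_model
        ranked = classify_candidates(
            model, CandidateSet(regions=[target, target]), frame
        )
        assert ranked[0][1] == ranked[1][1]

    def test_true_lesion_outranks_background(self, lesion_frame_and_model):
        frame, target, model = lesion_frame_and_model
        background = [BoundingBox(2, 2, 16, 16), BoundingBox(44, 40, 16, 16)]
        ranked = classify_candidates(
            model, CandidateSet(regions=background + [target]), frame
        )
        assert ranked[0][0] == target

    def test_scores_are_pure_function_of_pixels(self, lesion_frame_and_model):
        frame, target, model = lesion_frame_and_model
        cands = CandidateSet(regions=[target, BoundingBox(2, 2, 16, 16)])
        a = classify_candidates(model, cands, frame)
        b = classify_candidates(model, cands, frame)
        assert a == b

    def test_empty_candidate_set_rejected(self, lesion_frame_and_model):
        frame, _, model = lesion_frame_and_model
        with pytest.raises(ValueError):
            classify_candidates(model, CandidateSet(regions=[]), frame)
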
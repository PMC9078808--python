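import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ceustrack import BoundingBox, cle, si, toar
from ceustrack.metrics import evaluate
from ceustrack.geometry import Trajectory


def pixel_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Brute-force IoU oracle: explicit pixel-set intersection/union."""
    pa = {(r, c) for r in range(a.row, a.row_stop) for c in range(a.col, a.col_stop)}
    pb = {(r, c) for r in range(b.row, b.row_stop) for c in range(b.col, b.col_stop)}
    if not pa or not pb:
        return 0.0
    return len(pa & pb) / len(pa | pb)


boxes = st.builds(
    BoundingBox,
    row=st.integers(-5, 20),
    col=st.integers(-5, 20),
    height=st.integers(1, 15),
    width=st.integers(1, 15),
)


class TestCLE:
    def test_perfect_prediction_is_zero(self):
        pts = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert cle(pts, pts) == 0.0

    def test_constant_offset_gives_pythagorean_distance(self):
        truth = np.zeros((10, 2))
        pred = truth + np.array([3.0, 4.0])
        assert cle(pred, truth) == pytest.approx(5.0)

    def test_mean_over_mixed_frames(self):
        truth = np.zeros((4, 2))
        pred = np.array([[0, 0], [0, 0], [0, 2], [0, 2]], dtype=float)
        assert cle(pred, truth) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cle(np.zeros((3, 2)), np.zeros((4, 2)))


class TestTOAR:
    def test_identical_boxes(self):
        b = BoundingBox(2, 3, 7, 9)
        assert toar(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert toar(BoundingBox(0, 0, 5, 5), BoundingBox(10, 10, 5, 5)) == 0.0

    def test_half_overlap_example(self):
        a = BoundingBox(0, 0, 10, 10)
        b = BoundingBox(0, 5, 10, 10)
        assert toar(a, b) == pytest.approx(50 / 150)

    def test_zero_area_box_scores_zero(self):
        assert toar(BoundingBox(0, 0, 0, 5), BoundingBox(0, 0, 5, 5)) == 0.0

    @settings(derandomize=True, max_examples=200)
    @given(a=boxes, b=boxes)
    def test_matches_pixel_set_oracle_and_symmetry(self, a, b):
        assert toar(a, b) == pytest.approx(pixel_iou(a, b), abs=1e-12)
        assert toar(a, b) == toar(b, a)

    def test_shrinking_overlap_strictly_decreases_toar(self):
        a = BoundingBox(0, 0, 10, 10)
        values = [toar(a, a.shifted(0, d)) for d in range(0, 10)]
        assert all(x > y for x, y in zip(values, values[1:]))


class TestSI:
    def test_identical_images_score_zero(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(20, 20))
        assert si(img, img) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_intensity_support_scores_one(self):
        assert si(np.zeros((10, 10)), np.full((10, 10), 255)) == pytest.approx(1.0)

    def test_closed_form_bhattacharyya_value(self):
        # H1 uniform over two bins; H2 = {0.8, 0.2}:
        # SI = 1 - (sqrt(0.5*0.8) + sqrt(0.5*0.2)) ~ 0.05132
        img_a = np.array([0] * 50 + [5] * 50)  # bins 0 and 1 (64 bins over 0..255)
        img_b = np.array([0] * 80 + [5] * 20)
        expected = 1 - (np.sqrt(0.5 * 0.8) + np.sqrt(0.5 * 0.2))
        assert si(img_a, img_b) == pytest.approx(expected, abs=1e-12)

    def test_literal_printed_form_is_degenerate_for_identical_histograms(self):
        img = np.array([0] * 50 + [5] * 50)
        # ratio form: 1 - sum(H1*H2)/(sum H1 * sum H2) = 1 - 0.5 here
        assert si(img, img, literal=True) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 256, size=(12, 12))
        b = rng.integers(0, 256, size=(12, 12))
        val = si(a, b)
        assert 0.0 <= val <= 1.0 + 1e-12
        assert val == pytest.approx(si(b, a), abs=1e-12)

    def test_shape_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            si(np.zeros((4, 4)), np.zeros((5, 4)))
        with pytest.raises(ValueError):
            si(np.zeros((0,)), np.zeros((0,)))


class TestEvaluate:
    def test_report_consistency_on_perfect_tracking(self, short_scene):
        frames, truth = short_scene
        traj = Trajectory()
        for b in truth.boxes:
            traj.append(b, 1.0)
        rep = evaluate(traj, truth, frames)
        # truth boxes are integer-quantized; their centers sit within half a
        # pixel per axis of the analytic trajectory
        assert rep.mean_cle <= np.sqrt(0.5)
        assert rep.mean_toar == 1.0
        assert rep.n_frames == len(truth)
        assert np.all(rep.si_per_frame >= 0)
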
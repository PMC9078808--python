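"""Tracking evaluation: center location error, overlap ratio, similarity index.

CLE is the mean Euclidean pixel distance between predicted and true box
centers over a sequence (lower is better). TOAR is the intersection-over-
union of the two pixel areas. SI is one minus the Bhattacharyya coefficient
of the two gray-level histograms, so 0 means identical intensity
distributions and 1 disjoint support (lower is better).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import BoundingBox, box_intersection_area

__all__ = ["EvalReport", "cle", "toar", "si", "evaluate"]

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    mean_cle: float
    mean_toar: float
    mean_si: float
    toar_per_frame: np.ndarray
    si_per_frame: np.ndarray
    n_frames: int

    def to_dict(self) -> dict:
        return {
            "mean_cle": self.mean_cle,
            "mean_toar": self.mean_toar,
            "mean_si": self.mean_si,
            "n_frames": self.n_frames,
        }


def cle(pred_centers, truth_centers) -> float:
    """Mean Euclidean distance (px) between predicted and true centers.

    Accepts (n, 2) arrays, or objects with a ``centers`` attribute
    (Trajectory, GroundTruth).
    """
    a = np.asarray(getattr(pred_centers, "centers", pred_centers), dtype=float)
    b = np.asarray(getattr(truth_centers, "centers", truth_centers), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"trajectory lengths differ: {a.shape} vs {b.shape}")
    return float(np.mean(np.linalg.norm(a - b, axis=1)))


def toar(box_a: BoundingBox, box_b: BoundingBox) -> float:
    """Intersection-over-union of two boxes' pixel areas (0 when disjoint)."""
    if box_a.area == 0 or box_b.area == 0:
        logger.warning("zero-area box in toar; returning 0 by convention")
        return 0.0
    inter = box_intersection_area(box_a, box_b)
    union = box_a.area + box_b.area - inter
    return inter / union


def _histogram(img: np.ndarray, n_bins: int) -> np.ndarray:
    h, _ = np.histogram(np.asarray(img).ravel(), bins=n_bins, range=(0, 256))
    total = h.sum()
    if total == 0:
        raise ValueError("empty image")
    return h / total


def si(img_a: np.ndarray, img_b: np.ndarray, n_bins: int = 64, literal: bool = False) -> float:
    """Histogram dissimilarity between two gray images.

    Default: SI = 1 - sum_P sqrt(H1(P) H2(P)), the Bhattacharyya-coefficient
    form on normalized ``n_bins``-bin histograms of the 8-bit range.
    ``literal=True`` instead evaluates 1 - sum(H1*H2) / (sum(H1) sum(H2)),
    the verbatim ratio form, for comparison (degenerate for normalized
    histograms: the denominator is 1).
    """
    a = np.asarray(img_a)
    b = np.asarray(img_b)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    h1 = _histogram(a, n_bins)
    h2 = _histogram(b, n_bins)
    if literal:
        return float(1.0 - (h1 * h2).sum() / (h1.sum() * h2.sum()))
    return float(1.0 - np.sqrt(h1 * h2).sum())


def evaluate(pred, truth, frames: np.ndarray | None = None, n_bins: int = 64) -> EvalReport:
    """Full per-sequence report: mean CLE, per-frame and mean TOAR and SI.

    SI compares each frame's predicted-box crop against the frame-0
    reference crop (the manually annotated appearance); it requires
    ``frames``. Without frames the SI fields are NaN.
    """
    pred_boxes = pred.boxes
    truth_boxes = truth.boxes
    if len(pred_boxes) != len(truth_boxes):
        raise ValueError("prediction and truth lengths differ")
    n = len(pred_boxes)
    mean_cle = cle(pred, truth)
    toar_pf = np.asarray([toar(p, t) for p, t in zip(pred_boxes, truth_boxes)])
    if frames is not None:
        ref = np.asarray(frames[0])[truth_boxes[0].slices()]
        si_pf = np.asarray(
            [
                si(np.asarray(frames[k])[pred_boxes[k].slices()], ref, n_bins=n_bins)
                for k in range(n)
            ]
        )
    else:
        si_pf = np.full(n, np.nan)
    return EvalReport(
        mean_cle=mean_cle,
        mean_toar=float(toar_pf.mean()),
        mean_si=float(np.nanmean(si_pf)) if frames is not None else float("nan"),
        toar_per_frame=toar_pf,
        si_per_frame=si_pf,
        n_frames=n,
    )
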
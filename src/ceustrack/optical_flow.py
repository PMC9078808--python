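"""Differential optical flow and the temporally maintained region-flow model.

The per-pixel flow is a windowed least-squares (Lucas-Kanade) solve of the
brightness-constancy constraint on Gaussian-presmoothed frames, optionally
refined by a few warp-and-resolve iterations (still the small-displacement
differential estimator; no pyramid). Per-region flow sums and the motion
intensity feed the particle weighting, and the region-flow model is updated
by an exponential moving average with update factor beta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, uniform_filter

from .geometry import BoundingBox

__all__ = ["FlowField", "FlowModel", "compute_flow", "region_flow", "update_model"]


@dataclass
class FlowField:
    """Dense velocity field: u is horizontal (col) px/frame, v vertical (row)."""

    u: np.ndarray
    v: np.ndarray
    frame_index: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape


@dataclass(frozen=True)
class FlowModel:
    """Total region flow h = (sum_m, sum_n) and motion intensity w.

    ``beta`` is the update factor of the exponential moving average: beta = 1
    replaces the model with the current frame's flow, beta = 0 freezes it.
    """

    h: tuple[float, float] = (0.0, 0.0)
    w: float = 0.0
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must be in [0, 1]")
        if self.w < 0:
            raise ValueError("motion intensity w must be nonnegative")


def _lk_step(
    ix: np.ndarray, iy: np.ndarray, it: np.ndarray, window: int, eps: float
) -> tuple[np.ndarray, np.ndarray]:
    """One windowed least-squares solve of the normal equations."""
    sxx = uniform_filter(ix * ix, window)
    sxy = uniform_filter(ix * iy, window)
    syy = uniform_filter(iy * iy, window)
    sxt = uniform_filter(ix * it, window)
    syt = uniform_filter(iy * it, window)
    det = sxx * syy - sxy * sxy
    ok = det > eps
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    du = (-syy * sxt + sxy * syt) * inv_det
    dv = (sxy * sxt - sxx * syt) * inv_det
    return du, dv


def compute_flow(
    frame_prev: np.ndarray,
    frame_next: np.ndarray,
    window: int = 5,
    sigma: float = 1.0,
    iterations: int = 3,
    det_eps: float = 1e-4,
) -> FlowField:
    """Dense Lucas-Kanade flow from ``frame_prev`` to ``frame_next``.

    Parameters
    ----------
    window : side of the square least-squares window (pixels).
    sigma : Gaussian presmoothing applied to both frames.
    iterations : warp-and-resolve refinement steps (1 = plain one-shot LK).
    det_eps : pixels whose normal-equation determinant falls below this get
        zero flow (untextured or border regions).
    """
    a = np.asarray(frame_prev, dtype=float)
    b = np.asarray(frame_next, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("compute_flow expects grayscale frames (use the V channel)")
    if sigma > 0:
        a = gaussian_filter(a, sigma)
        b = gaussian_filter(b, sigma)

    rows, cols = np.mgrid[0 : a.shape[0], 0 : a.shape[1]].astype(float)
    u = np.zeros_like(a)
    v = np.zeros_like(a)
    iy, ix = np.gradient(a)
    for _ in range(max(1, iterations)):
        warped = map_coordinates(b, [rows + v, cols + u], order=1, mode="nearest")
        it = warped - a
        du, dv = _lk_step(ix, iy, it, window, det_eps)
        u += du
        v += dv
    return FlowField(u=u, v=v)


def region_flow(
    flow: FlowField, region: BoundingBox
) -> tuple[float, float, float]:
    """Summed flow components and motion intensity over a box region.

    Returns ``(sum_m, sum_n, w)`` where sum_m sums the horizontal component,
    sum_n the vertical one, and w = sqrt(sum_m^2 + sum_n^2) / z with z the
    region pixel count — the region's mean motion magnitude.
    """
    if region.area == 0:
        raise ValueError("empty region")
    if not region.inside(flow.shape):
        raise ValueError(f"region {region} outside flow field {flow.shape}")
    sl = region.slices()
    sum_m = float(flow.u[sl].sum())
    sum_n = float(flow.v[sl].sum())
    w = float(np.hypot(sum_m, sum_n) / region.area)
    return sum_m, sum_n, w


def update_model(
    model: FlowModel, current: tuple[float, float, float]
) -> FlowModel:
    """Blend the current frame's region flow into the model.

    h_new = h_old * (1 - beta) + beta * h_current; the motion intensity is
    replaced by the current frame's value.
    """
    sum_m, sum_n, w = current
    beta = model.beta
    h = (
        model.h[0] * (1.0 - beta) + beta * sum_m,
        model.h[1] * (1.0 - beta) + beta * sum_n,
    )
    return FlowModel(h=h, w=float(w), beta=beta)
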
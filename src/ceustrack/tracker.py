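"""Per-frame tracking loop: enhance, flow, particle weighting, CNN selection.

Frame 0 carries the manual annotation; the classifier is trained on
augmented crops of it. Every later frame runs: MSRCP enhancement (and HSV
V-channel extraction for RGB input), dense differential flow from the
previous frame, flow-similarity particle weighting against the maintained
region-flow model, candidate extraction, CNN scoring, position selection,
flow-model update, and particle resampling for the next frame. The box size
stays fixed at the annotated size (no scale adaptation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import cnn as cnn_mod
from .enhancement import msrcp_enhance, rgb_to_hsv, DEFAULT_SCALES
from .geometry import BoundingBox, Trajectory
from .optical_flow import FlowModel, compute_flow, region_flow, update_model
from .particle_filter import candidates, init_particles, resample, weigh_particles

__all__ = ["TrackerConfig", "track"]

logger = logging.getLogger(__name__)


@dataclass
class TrackerConfig:
    """Knobs of the tracking loop (defaults chosen for 128 px CEUS-like frames)."""

    # enhancement
    enhance: bool = True
    scales: tuple = DEFAULT_SCALES
    clip_percentiles: tuple = (1.0, 99.0)
    # optical flow
    flow_window: int = 5
    flow_sigma: float = 1.0
    flow_iterations: int = 3
    beta: float = 0.5
    # particle filter
    n_particles: int = 100
    epsilon: float = 0.2
    spread: float | None = None  # None -> half the box diagonal
    jitter_sigma: float = 1.0
    n_candidates: int = 10
    # classifier
    use_cnn: bool = True
    cnn_epochs: int = 20
    cnn_lr: float = 1e-3
    n_pos: int = 32
    n_neg: int = 32
    # stationarity shortcut: hold the box when the mean motion magnitude over
    # the previous box falls below this (px/frame); 0 disables
    hold_threshold: float = 0.02

    @staticmethod
    def from_yaml(path) -> "TrackerConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat = {}
        # accept both flat keys and the documented nested sections
        nested = {
            "enhancement": {"scales": "scales", "clip_percentiles": "clip_percentiles"},
            "flow": {
                "window": "flow_window",
                "sigma": "flow_sigma",
                "iterations": "flow_iterations",
                "beta": "beta",
            },
        }
        for key, val in raw.items():
            if key in nested and isinstance(val, dict):
                for sub, dest in nested[key].items():
                    if sub in val:
                        flat[dest] = val[sub]
            else:
                flat[key] = val
        cfg = TrackerConfig(**flat)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def _value_channel(frame: np.ndarray, config: TrackerConfig) -> np.ndarray:
    """Enhanced intensity (V) channel used for flow and classification."""
    img = np.asarray(frame, dtype=float)
    if config.enhance:
        img = msrcp_enhance(img, scales=config.scales, clip_percentiles=config.clip_percentiles)
    if img.ndim == 3:
        img = rgb_to_hsv(img).v
    return img


def track(
    frames: np.ndarray,
    init_box: BoundingBox,
    config: TrackerConfig | None = None,
    seed: int = 0,
) -> Trajectory:
    """Track the annotated region through a frame stack.

    Parameters
    ----------
    frames : (n_frames, rows, cols[, 3]) stack with uniform shape.
    init_box : manual annotation on frame 0; its size is kept for all frames.
    config : TrackerConfig; defaults used when None.
    seed : drives classifier training and all particle sampling; identical
        (frames, init_box, config, seed) give identical trajectories.
    """
    config = config or TrackerConfig()
    n_frames = len(frames)
    if n_frames < 1:
        raise ValueError("empty sequence")
    shape0 = np.asarray(frames[0]).shape
    frame_shape = shape0[:2]
    if not init_box.inside(frame_shape):
        raise ValueError(f"init box {init_box} outside frame {frame_shape}")

    ss = np.random.SeedSequence(seed)
    rng_cnn, rng_pf = (np.random.default_rng(s) for s in ss.spawn(2))

    traj = Trajectory()
    traj.append(init_box, 1.0)
    if n_frames == 1:
        return traj

    v_prev = _value_channel(frames[0], config)

    classifier = None
    if config.use_cnn:
        pos, neg = cnn_mod.first_frame_training_set(
            v_prev, init_box, rng_cnn, n_pos=config.n_pos, n_neg=config.n_neg
        )
        classifier = cnn_mod.train_classifier(
            pos, neg, epochs=config.cnn_epochs, seed=rng_cnn, lr=config.cnn_lr
        )

    box = init_box
    model = FlowModel(h=(0.0, 0.0), w=0.0, beta=config.beta)
    pset = init_particles(
        box,
        frame_shape,
        n=config.n_particles,
        spread=config.spread,
        epsilon=config.epsilon,
        seed=rng_pf,
    )

    for s in range(1, n_frames):
        frame = np.asarray(frames[s])
        if frame.shape != shape0:
            raise ValueError(f"frame {s} shape {frame.shape} differs from {shape0}")
        v_cur = _value_channel(frame, config)
        flow = compute_flow(
            v_prev,
            v_cur,
            window=config.flow_window,
            sigma=config.flow_sigma,
            iterations=config.flow_iterations,
        )
        prev_rf = region_flow(flow, box)

        if config.hold_threshold > 0 and prev_rf[2] < config.hold_threshold:
            # no evidence of motion over the tracked region: hold position
            traj.append(box, traj.scores[-1])
            model = update_model(model, prev_rf)
            v_prev = v_cur
            continue

        if s == 1:
            # bootstrap the reference flow from the annotated region
            model = FlowModel(h=(prev_rf[0], prev_rf[1]), w=prev_rf[2], beta=config.beta)

        # zero-innovation hypothesis: previous box advanced by the model flow
        area = box.area
        drift = np.array([model.h[1] / area, model.h[0] / area])  # (row, col)
        pred_box = box.shifted(int(round(drift[0])), int(round(drift[1]))).clipped(
            frame_shape
        )

        pset = weigh_particles(pset, model, flow)
        cands = candidates(pset, min(config.n_candidates, pset.n))
        if all(r != pred_box for r in cands.regions):
            cands.regions.append(pred_box)
            cands.weights.append(0.0)

        if classifier is not None:
            ranked = cnn_mod.classify_candidates(classifier, cands, v_cur)
            box, score = ranked[0][0], ranked[0][1]
            if score < 0.5:
                # nothing looks like the lesion: coast on the motion model
                logger.debug("frame %d: best candidate score %.3f; coasting", s, score)
                box = pred_box
                score = next(sc for r, sc, _ in ranked if r == pred_box)
        else:
            box, score = cands.regions[0], float(cands.weights[0])
        traj.append(box, score)

        sel_rf = region_flow(flow, box)
        model = update_model(model, sel_rf)

        # prepare the next frame's particle cloud: resample by weight, then
        # anchor the cloud at the selected position advanced by the mean flow
        pset = resample(pset, seed=rng_pf, jitter_sigma=config.jitter_sigma)
        drift = np.array([model.h[1] / area, model.h[0] / area])  # (row, col)
        ctrs = pset.centers
        offset = np.asarray(box.center) + drift - ctrs.mean(axis=0)
        for p, ctr in zip(pset.particles, ctrs + offset):
            p.center = (float(ctr[0]), float(ctr[1]))
            p.region = BoundingBox.from_center(p.center, *pset.box_size).clipped(
                frame_shape
            )
        v_prev = v_cur

    return traj
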
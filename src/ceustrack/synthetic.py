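"""Synthetic contrast-enhanced-ultrasound-like sequences with known ground truth.

Real CEUS frames of the gastric wall show a bright, speckled tissue background
with the lesion as a darker (hypoechoic) region that drifts with probe and
patient motion. The generator emulates exactly that: a static multiplicative
speckle field for the surrounding tissue, a second speckle field that is
carried along with the lesion (so the lesion interior translates coherently,
as real tissue texture does), a raised-cosine lesion edge, optional global
intensity drift emulating contrast wash-in, and optional per-frame additive
sensor noise. It does not simulate acoustic wave propagation or microbubble
kinetics; see docs/methods.md for what that implies for the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .geometry import BoundingBox

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "generate_sequence",
    "generate_contingency_fixture",
    "to_rgb",
    "write_sequence",
    "load_sequence",
]


@dataclass
class SceneConfig:
    """Parameters of a synthetic lesion scene.

    Attributes
    ----------
    frame_shape : (rows, cols) in pixels.
    n_frames : number of frames to generate.
    lesion_axes : (semi-major, semi-minor) ellipse semi-axes in pixels,
        row axis first.
    lesion_contrast : fraction in [0, 1); lesion mean intensity equals
        background mean times ``1 - lesion_contrast`` (hypoechoic for > 0).
    trajectory : ``"linear"``, ``"sinusoidal"`` or ``"random-walk"``.
    start_center : (row, col) lesion center on frame 0.
    velocity : (row, col) drift in px/frame (linear and sinusoidal).
    amplitude, period : sinusoidal row-oscillation amplitude (px) and
        period (frames).
    step_sigma : random-walk per-frame step standard deviation (px).
    speckle_scale : 0 disables speckle, 1 is fully developed speckle.
    speckle_grain : Gaussian correlation length of the speckle field (px).
    base_intensity : background mean gray level (8-bit scale).
    wash_in : optional per-frame global gain curve (length n_frames);
        emulates contrast-agent wash-in as a multiplicative drift.
    frame_noise : additive per-frame Gaussian sensor noise sigma (gray levels).
    edge_width : raised-cosine lesion edge width (px).
    channels : 1 for grayscale output, 3 replicates the gray frame so the
        RGB/HSV path is exercisable.
    seed : RNG seed; identical seed + config gives bit-identical output.
    """

    frame_shape: tuple[int, int] = (128, 128)
    n_frames: int = 50
    lesion_axes: tuple[float, float] = (10.0, 6.0)
    lesion_contrast: float = 0.4
    trajectory: str = "linear"
    start_center: tuple[float, float] = (40.0, 35.0)
    velocity: tuple[float, float] = (0.4, 0.9)
    amplitude: float = 6.0
    period: float = 25.0
    step_sigma: float = 0.7
    speckle_scale: float = 0.3
    speckle_grain: float = 1.5
    base_intensity: float = 150.0
    wash_in: Sequence[float] | None = None
    frame_noise: float = 1.5
    edge_width: float = 2.0
    channels: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0.0 <= self.lesion_contrast < 1.0):
            raise ValueError("lesion_contrast must be in [0, 1)")
        if self.trajectory not in ("linear", "sinusoidal", "random-walk"):
            raise ValueError(f"unknown trajectory {self.trajectory!r}")
        if self.speckle_scale < 0:
            raise ValueError("speckle_scale must be nonnegative")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        if self.wash_in is not None and len(self.wash_in) != self.n_frames:
            raise ValueError("wash_in must have one gain per frame")

    @property
    def box_size(self) -> tuple[int, int]:
        """Constant ground-truth box size (height, width) covering the lesion."""
        a, b = self.lesion_axes
        return int(2 * np.ceil(a)), int(2 * np.ceil(b))


@dataclass
class GroundTruth:
    """Per-frame true lesion center and bounding box."""

    centers: np.ndarray  # (n_frames, 2) float (row, col)
    boxes: list[BoundingBox] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.boxes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.boxes)),
                "row": [b.row for b in self.boxes],
                "col": [b.col for b in self.boxes],
                "height": [b.height for b in self.boxes],
                "width": [b.width for b in self.boxes],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "GroundTruth":
        df = pd.read_csv(path)
        boxes = [
            BoundingBox(int(r.row), int(r.col), int(r.height), int(r.width))
            for r in df.itertuples(index=False)
        ]
        centers = np.asarray([b.center for b in boxes], dtype=float)
        return GroundTruth(centers=centers, boxes=boxes)


def _trajectory_centers(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(config.n_frames, dtype=float)
    r0, c0 = config.start_center
    vr, vc = config.velocity
    if config.trajectory == "linear":
        rows = r0 + vr * t
        cols = c0 + vc * t
    elif config.trajectory == "sinusoidal":
        rows = r0 + config.amplitude * np.sin(2 * np.pi * t / config.period)
        cols = c0 + vc * t
    else:  # random-walk
        steps = rng.normal(0.0, config.step_sigma, size=(config.n_frames, 2))
        steps[0] = 0.0
        pos = np.cumsum(steps, axis=0)
        rows = r0 + pos[:, 0]
        cols = c0 + pos[:, 1]
    return np.column_stack([rows, cols])


def _speckle_field(
    shape: tuple[int, int], config: SceneConfig, rng: np.random.Generator
) -> np.ndarray:
    """Unit-mean multiplicative speckle: low-pass-filtered squared Gaussian field."""
    if config.speckle_scale == 0:
        return np.ones(shape)
    g = gaussian_filter(rng.standard_normal(shape), config.speckle_grain)
    s = g**2
    s /= s.mean()
    return (1.0 - config.speckle_scale) + config.speckle_scale * s


def _lesion_weight(
    shape: tuple[int, int], center: tuple[float, float], config: SceneConfig
) -> np.ndarray:
    """Smooth in-lesion weight: 1 inside the ellipse, raised-cosine edge, 0 outside."""
    a, b = config.lesion_axes
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    rho = np.sqrt(((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2)
    half = config.edge_width / (2.0 * min(a, b))  # edge half-width, normalized radius
    w = np.clip((1.0 + half - rho) / (2.0 * half), 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * w)


def generate_sequence(config: SceneConfig) -> tuple[np.ndarray, GroundTruth]:
    """Generate a frame stack and its exact ground-truth trajectory.

    Returns
    -------
    frames : uint8 array of shape (n_frames, rows, cols) or (..., 3).
    truth : GroundTruth with analytic centers and constant-size boxes.
    """
    config.validate()
    shape = tuple(config.frame_shape)
    ss = np.random.SeedSequence(config.seed)
    rng_bg, rng_lesion, rng_traj, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    centers = _trajectory_centers(config, rng_traj)
    h, w = config.box_size
    boxes = []
    for k, ctr in enumerate(centers):
        box = BoundingBox.from_center((ctr[0], ctr[1]), h, w)
        if not box.inside(shape):
            raise ValueError(
                f"lesion trajectory leaves the frame at frame {k} "
                f"(box {box}, frame shape {shape})"
            )
        boxes.append(box)
    truth = GroundTruth(centers=centers, boxes=boxes)

    bg = config.base_intensity * _speckle_field(shape, config, rng_bg)
    # Lesion-local texture on a pad larger than the frame so any in-frame
    # lesion position samples valid coordinates.
    pad_shape = (shape[0] * 2, shape[1] * 2)
    lesion_tex = config.base_intensity * _speckle_field(pad_shape, config, rng_lesion)

    gains = (
        np.ones(config.n_frames)
        if config.wash_in is None
        else np.asarray(config.wash_in, dtype=float)
    )

    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    frames = np.empty((config.n_frames,) + shape, dtype=np.uint8)
    for k, ctr in enumerate(centers):
        wmask = _lesion_weight(shape, (ctr[0], ctr[1]), config)
        # sample the lesion texture in lesion-attached coordinates
        coords = np.stack(
            [rr - ctr[0] + pad_shape[0] / 2.0, cc - ctr[1] + pad_shape[1] / 2.0]
        )
        tex = map_coordinates(lesion_tex, coords, order=1, mode="nearest")
        img = bg * (1.0 - wmask) + tex * wmask * (1.0 - config.lesion_contrast)
        img *= gains[k]
        if config.frame_noise > 0:
            img = img + rng_noise.normal(0.0, config.frame_noise, size=shape)
        frames[k] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    if config.channels == 3:
        frames = to_rgb(frames)
    return frames, truth


def to_rgb(frames: np.ndarray) -> np.ndarray:
    """Replicate grayscale frames into 3 identical channels."""
    if frames.ndim == 4:
        return frames
    return np.repeat(frames[..., None], 3, axis=-1)


def write_sequence(frames: np.ndarray, out_dir, prefix: str = "frame") -> list[Path]:
    """Write frames as zero-padded numbered PNG files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(frames) - 1)))
    paths = []
    for k, frame in enumerate(frames):
        p = out / f"{prefix}_{k:0{width}d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def load_sequence(in_dir, pattern: str = "*.png") -> np.ndarray:
    """Load a directory of numbered frames into a stack (lexicographic order)."""
    paths = sorted(Path(in_dir).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no frames matching {pattern!r} in {in_dir}")
    frames = np.stack([iio.imread(p) for p in paths])
    return frames


def generate_contingency_fixture(stage_counts: dict, seed: int | None = None):
    """Build a ContingencyTable fixture from stage -> (gold_n, detected_n) counts.

    ``stage_counts`` may instead carry the keys TP/FN/TN/FP for a 2x2
    resectability layout. Counts are taken verbatim (the seed is accepted for
    interface symmetry with the frame generator; the table is deterministic).
    """
    from .diagnostics import ContingencyTable

    keys = set(stage_counts)
    if keys == {"TP", "FN", "TN", "FP"}:
        return ContingencyTable.from_binary(**{k.lower(): v for k, v in stage_counts.items()})
    rows = []
    for stage, (gold_n, detected_n) in stage_counts.items():
        if gold_n < 0 or detected_n < 0:
            raise ValueError(f"negative counts for stage {stage!r}")
        if detected_n > gold_n:
            raise ValueError(
                f"stage {stage!r}: detected_n ({detected_n}) exceeds gold_n ({gold_n})"
            )
        rows.append((str(stage), int(gold_n), int(detected_n)))
    return ContingencyTable.from_stage_rows(rows)
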
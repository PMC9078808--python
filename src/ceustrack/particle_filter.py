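"""Particle filtering of the lesion position with flow-similarity weights.

Particles carry candidate target boxes; each is weighted by how well the
optical flow summed over its box matches the temporally maintained reference
flow (cosine similarity, Gaussian kernel on the gap to the best particle),
then resampled proportionally to weight with a small jitter to keep the
cloud diverse. The top-weighted distinct particle boxes become the candidate
regions handed to the CNN classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import logging

import numpy as np

from .geometry import BoundingBox
from .optical_flow import FlowField, FlowModel, region_flow

__all__ = [
    "Particle",
    "ParticleSet",
    "CandidateSet",
    "init_particles",
    "similarity",
    "weigh_particles",
    "resample",
    "candidates",
]

logger = logging.getLogger(__name__)


@dataclass
class Particle:
    center: tuple[float, float]  # (row, col)
    region: BoundingBox
    flow_vec: tuple[float, float] = (0.0, 0.0)
    weight: float = 0.0


@dataclass
class ParticleSet:
    particles: list[Particle]
    epsilon: float = 0.2
    frame_index: int = 0
    frame_shape: tuple[int, int] = (0, 0)
    box_size: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if len(self.particles) < 1:
            raise ValueError("need at least one particle")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def n(self) -> int:
        return len(self.particles)

    @property
    def weights(self) -> np.ndarray:
        return np.asarray([p.weight for p in self.particles])

    @property
    def centers(self) -> np.ndarray:
        return np.asarray([p.center for p in self.particles])


@dataclass
class CandidateSet:
    regions: list[BoundingBox]
    weights: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)


def _particle_at(
    center: tuple[float, float],
    box_size: tuple[int, int],
    frame_shape: tuple[int, int],
    weight: float,
) -> Particle:
    box = BoundingBox.from_center(center, *box_size).clipped(frame_shape)
    return Particle(center=center, region=box, weight=weight)


def init_particles(
    target: BoundingBox,
    frame_shape: tuple[int, int],
    n: int = 100,
    spread: float | None = None,
    epsilon: float = 0.2,
    seed: int | np.random.Generator = 0,
) -> ParticleSet:
    """Scatter ``n`` particles around the target box center.

    Centers are drawn from an isotropic Gaussian (sigma = ``spread``,
    defaulting to half the box diagonal) and clipped so every particle box
    stays inside the frame; initial weights are uniform 1/n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not target.inside(frame_shape):
        raise ValueError(f"target {target} does not fit inside frame {frame_shape}")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if spread is None:
        spread = 0.5 * float(np.hypot(target.height, target.width))
    ctr = np.asarray(target.center)
    offsets = rng.normal(0.0, spread, size=(n, 2)) if spread > 0 else np.zeros((n, 2))
    size = (target.height, target.width)
    particles = [
        _particle_at(tuple(ctr + off), size, frame_shape, 1.0 / n) for off in offsets
    ]
    return ParticleSet(
        particles=particles,
        epsilon=epsilon,
        frame_shape=frame_shape,
        box_size=size,
    )


def similarity(reference_flow: Sequence[float], particle_flow: Sequence[float]) -> float:
    """Cosine similarity of two region-flow vectors; 0 if either is zero."""
    a = np.asarray(reference_flow, dtype=float)
    b = np.asarray(particle_flow, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("flow vectors must be finite")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def kernel_weights(scores: np.ndarray, epsilon: float) -> np.ndarray:
    """Gaussian kernel on the gap to the best similarity, normalized to sum 1.

    Raw weight: exp(-(s_i - s_max)^2 / (2 eps^2)). The constant kernel
    prefactor cancels under normalization and is dropped. An all-zero raw
    vector (numerically underflowed) falls back to uniform weights.
    """
    s = np.asarray(scores, dtype=float)
    raw = np.exp(-((s - s.max()) ** 2) / (2.0 * epsilon**2))
    total = raw.sum()
    if total == 0.0 or not np.isfinite(total):
        logger.warning("all particle weights underflowed; falling back to uniform")
        return np.full(s.shape, 1.0 / s.size)
    return raw / total


def weigh_particles(
    pset: ParticleSet, model: FlowModel, flow: FlowField
) -> ParticleSet:
    """Weight each particle by flow similarity to the reference model.

    Each particle's region flow R_k is summed from the dense field; its
    similarity to the model's reference vector h feeds the Gaussian kernel,
    and the kernel outputs are normalized to sum 1.
    """
    scores = np.empty(pset.n)
    for i, p in enumerate(pset.particles):
        sum_m, sum_n, _ = region_flow(flow, p.region)
        p.flow_vec = (sum_m, sum_n)
        scores[i] = similarity(model.h, p.flow_vec)
    for p, w in zip(pset.particles, kernel_weights(scores, pset.epsilon)):
        p.weight = float(w)
    return pset


def resample(
    pset: ParticleSet,
    seed: int | np.random.Generator = 0,
    jitter_sigma: float = 1.0,
) -> ParticleSet:
    """Systematic resampling proportional to weight, preserving n.

    Offspring inherit their parent's center and are jittered by an isotropic
    Gaussian (sigma = ``jitter_sigma``) to restore diversity; weights reset
    to uniform.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    n = pset.n
    w = pset.weights
    w = w / w.sum()
    positions = (rng.random() + np.arange(n)) / n
    cum = np.cumsum(w)
    cum[-1] = 1.0  # guard against roundoff
    parents = np.searchsorted(cum, positions)
    jitter = (
        rng.normal(0.0, jitter_sigma, size=(n, 2)) if jitter_sigma > 0 else np.zeros((n, 2))
    )
    particles = []
    for k, parent in enumerate(parents):
        ctr = np.asarray(pset.particles[parent].center) + jitter[k]
        particles.append(
            _particle_at(tuple(ctr), pset.box_size, pset.frame_shape, 1.0 / n)
        )
    return ParticleSet(
        particles=particles,
        epsilon=pset.epsilon,
        frame_index=pset.frame_index,
        frame_shape=pset.frame_shape,
        box_size=pset.box_size,
    )


def candidates(pset: ParticleSet, k: int = 10) -> CandidateSet:
    """Top-k particles by weight as candidate regions Q_1..Q_k.

    Ties in weight break toward the lower particle index; particles whose
    centers fall within 1 px of an already-selected candidate are skipped
    (duplicates carry no extra information for the classifier).
    """
    if k > pset.n:
        raise ValueError(f"k ({k}) exceeds particle count ({pset.n})")
    order = np.argsort(-pset.weights, kind="stable")  # stable: ties -> lower index
    chosen: list[int] = []
    centers = pset.centers
    for idx in order:
        if len(chosen) == k:
            break
        if any(np.hypot(*(centers[idx] - centers[j])) < 1.0 for j in chosen):
            continue
        chosen.append(int(idx))
    return CandidateSet(
        regions=[pset.particles[i].region for i in chosen],
        weights=[pset.particles[i].weight for i in chosen],
    )
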
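"""Candidate-region classification with a small convolutional network.

The network is deliberately tiny — two 3x3 convolution + max-pool stages, a
64-unit embedding and a 2-way softmax — because its job is per-sequence
appearance discrimination (lesion vs. background of ONE sequence), learned
from augmented crops of the user-annotated first frame, not generic object
recognition. It is implemented directly on numpy (im2col convolutions,
Adam), which keeps training deterministic under a fixed seed and fast on a
single CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .geometry import BoundingBox, box_intersection_area
from .particle_filter import CandidateSet

__all__ = [
    "CandidatePatch",
    "CNNClassifier",
    "normalize_patch",
    "train_classifier",
    "classify_candidates",
    "first_frame_training_set",
]

PATCH_SIZE = 32


@dataclass
class CandidatePatch:
    """Fixed-size normalized patch cut from a candidate region."""

    pixels: np.ndarray  # (out_size, out_size) in [0, 1]
    source: BoundingBox


def normalize_patch(
    frame: np.ndarray, region: BoundingBox, out_size: int = PATCH_SIZE
) -> CandidatePatch:
    """Scale-normalize a region crop to ``out_size`` x ``out_size`` in [0, 1].

    Bilinear resampling; multichannel frames are collapsed to intensity
    first. Intensities are assumed on the 8-bit scale.
    """
    if region.area == 0:
        raise ValueError("zero-area region cannot be normalized")
    img = np.asarray(frame, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    if not region.inside(img.shape):
        raise ValueError(f"region {region} outside frame {img.shape}")
    crop = img[region.slices()]
    if crop.shape != (out_size, out_size):
        crop = resize(
            crop,
            (out_size, out_size),
            order=1,
            anti_aliasing=False,
            preserve_range=True,
        )
    return CandidatePatch(pixels=crop / 255.0, source=region)


# ---------------------------------------------------------------------------
# network internals
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) columns for same-padded 3x3 conv."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    n, c, h, w = x.shape
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (n, c, k, k, h, w), (s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return cols.reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int = 3) -> np.ndarray:
    """Adjoint of _im2col (scatter-add over the k*k shifts)."""
    n, c, h, w = x_shape
    p = k // 2
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
    d = dcols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    return dxp[:, :, p : p + h, p : p + w]


def _pool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    return out, mask


def _unpool(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n, c, h2, _, w2, _ = mask.shape
    return (mask * dout[:, :, :, None, :, None]).reshape(n, c, h2 * 2, w2 * 2)


@dataclass
class CNNClassifier:
    """Two-conv-layer scorer; ``params`` maps names to weight arrays."""

    params: dict = field(default_factory=dict)
    patch_size: int = PATCH_SIZE
    history: list = field(default_factory=list)  # per-epoch training loss

    @staticmethod
    def init(seed: int | np.random.Generator, patch_size: int = PATCH_SIZE):
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        s = patch_size // 4  # after two 2x pools
        flat = 16 * s * s

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        params = {
            "W1": he((8, 9), 9),  # 1 -> 8 channels, 3x3
            "b1": np.zeros(8),
            "W2": he((16, 72), 72),  # 8 -> 16 channels, 3x3
            "b2": np.zeros(16),
            "W3": he((flat, 64), flat),
            "b3": np.zeros(64),
            "W4": he((64, 2), 64),
            "b4": np.zeros(2),
        }
        return CNNClassifier(params=params, patch_size=patch_size)

    # forward -------------------------------------------------------------
    def _forward(self, x: np.ndarray, cache: bool = False):
        p = self.params
        n = x.shape[0]
        x1 = x[:, None, :, :]  # (N,1,H,W)
        c1 = _im2col(x1)
        z1 = (p["W1"] @ c1 + p["b1"][None, :, None]).reshape(n, 8, *x1.shape[2:])
        a1 = np.maximum(z1, 0.0)
        p1, m1 = _pool(a1)
        c2 = _im2col(p1)
        z2 = (p["W2"] @ c2 + p["b2"][None, :, None]).reshape(n, 16, *p1.shape[2:])
        a2 = np.maximum(z2, 0.0)
        p2, m2 = _pool(a2)
        flat = p2.reshape(n, -1)
        z3 = flat @ p["W3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)  # the 64-d feature embedding
        logits = a3 @ p["W4"] + p["b4"]
        if cache:
            return logits, (x1, c1, z1, m1, p1, c2, z2, m2, flat, z3, a3)
        return logits

    def features(self, patches: np.ndarray) -> np.ndarray:
        """64-d embedding of (N, H, W) patches."""
        logits, cache = self._forward(np.asarray(patches, dtype=float), cache=True)
        return cache[10]

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        logits = self._forward(np.asarray(patches, dtype=float))
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def score(self, patches: np.ndarray) -> np.ndarray:
        """Lesion probability in [0, 1] for each patch."""
        return self.predict_proba(patches)[:, 1]

    # backward ------------------------------------------------------------
    def _grads(self, x: np.ndarray, y: np.ndarray):
        p = self.params
        n = x.shape[0]
        logits, (x1, c1, z1, m1, p1, c2, z2, m2, flat, z3, a3) = self._forward(
            x, cache=True
        )
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=1, keepdims=True)
        loss = -np.mean(np.log(probs[np.arange(n), y] + 1e-12))
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n

        g = {}
        g["W4"] = a3.T @ dlogits
        g["b4"] = dlogits.sum(axis=0)
        da3 = dlogits @ p["W4"].T
        dz3 = da3 * (z3 > 0)
        g["W3"] = flat.T @ dz3
        g["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["W3"].T
        dp2 = dflat.reshape(n, 16, self.patch_size // 4, self.patch_size // 4)
        da2 = _unpool(dp2, m2)
        dz2 = da2 * (z2 > 0)
        dz2f = dz2.reshape(n, 16, -1)
        g["W2"] = np.einsum("nfp,ncp->fc", dz2f, c2)
        g["b2"] = dz2f.sum(axis=(0, 2))
        dc2 = np.einsum("fc,nfp->ncp", p["W2"], dz2f)
        dp1 = _col2im(dc2, p1.shape)
        da1 = _unpool(dp1, m1)
        dz1 = da1 * (z1 > 0)
        dz1f = dz1.reshape(n, 8, -1)
        g["W1"] = np.einsum("nfp,ncp->fc", dz1f, c1)
        g["b1"] = dz1f.sum(axis=(0, 2))
        return loss, g


def train_classifier(
    positives: np.ndarray,
    negatives: np.ndarray,
    epochs: int = 30,
    seed: int | np.random.Generator = 0,
    lr: float = 1e-3,
    batch_size: int = 32,
) -> CNNClassifier:
    """Train the candidate scorer on positive/negative patches.

    Parameters
    ----------
    positives, negatives : (N, patch, patch) arrays in [0, 1]; at least one
        sample of each class is required.
    epochs : full passes over the (shuffled) training set; Adam updates.
    seed : controls weight initialization and shuffling; fixed seed gives
        bit-identical final weights.
    """
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.ndim == 2:
        pos = pos[None]
    if neg.ndim == 2:
        neg = neg[None]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one positive and one negative patch")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    model = CNNClassifier.init(rng, patch_size=pos.shape[-1])
    x = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(vv) for k, vv in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(x))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(x), batch_size):
            idx = order[start : start + batch_size]
            loss, grads = model._grads(x[idx], y[idx])
            epoch_loss += loss
            n_batches += 1
            step += 1
            for k, gk in grads.items():
                m[k] = b1 * m[k] + (1 - b1) * gk
                v[k] = b2 * v[k] + (1 - b2) * gk**2
                mhat = m[k] / (1 - b1**step)
                vhat = v[k] / (1 - b2**step)
                model.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        model.history.append(epoch_loss / max(n_batches, 1))
    return model


def classify_candidates(
    model: CNNClassifier, cands: CandidateSet, frame: np.ndarray
) -> list[tuple[BoundingBox, float, float]]:
    """Score candidate regions and return them sorted best-first.

    Returns ``(region, score, particle_weight)`` triples sorted by
    descending score; ties break toward higher particle weight, then lower
    candidate index.
    """
    if len(cands) == 0:
        raise ValueError("empty candidate set")
    patches = np.stack(
        [normalize_patch(frame, r, model.patch_size).pixels for r in cands.regions]
    )
    scores = model.score(patches)
    weights = cands.weights if cands.weights else [0.0] * len(cands)
    order = sorted(
        range(len(cands)), key=lambda i: (-scores[i], -weights[i], i)
    )
    return [(cands.regions[i], float(scores[i]), float(weights[i])) for i in order]


def first_frame_training_set(
    frame: np.ndarray,
    target: BoundingBox,
    rng: np.random.Generator,
    n_pos: int = 32,
    n_neg: int = 32,
    patch_size: int = PATCH_SIZE,
) -> tuple[np.ndarray, np.ndarray]:
    """Augmented positives/negatives from the annotated first frame.

    Positives are jittered copies of the target box with IoU >= 0.7 against
    it; negatives are random same-size boxes with IoU <= 0.3.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    shape = img.shape

    def iou(box: BoundingBox) -> float:
        inter = box_intersection_area(box, target)
        return inter / (box.area + target.area - inter)

    pos, neg = [], []
    max_jit = max(1, int(0.15 * min(target.height, target.width)))
    while len(pos) < n_pos:
        d = rng.integers(-max_jit, max_jit + 1, size=2)
        box = target.shifted(int(d[0]), int(d[1])).clipped(shape)
        if iou(box) >= 0.7:
            pos.append(normalize_patch(img, box, patch_size).pixels)
    while len(neg) < n_neg:
        r = int(rng.integers(0, shape[0] - target.height + 1))
        c = int(rng.integers(0, shape[1] - target.width + 1))
        box = BoundingBox(r, c, target.height, target.width)
        if iou(box) <= 0.3:
            neg.append(normalize_patch(img, box, patch_size).pixels)
    return np.stack(pos), np.stack(neg)
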
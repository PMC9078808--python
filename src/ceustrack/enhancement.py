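"""Frame preprocessing: MSRCP enhancement and RGB -> HSV feature extraction.

MSRCP (multiscale Retinex with chromaticity preservation) runs log-domain
multiscale Retinex on the intensity channel, stretches the result with
simplest-color-balance percentile clipping, and applies the resulting
per-pixel intensity gain to every channel equally so the per-pixel channel
ratios (chromaticity) of the input are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import fourier_gaussian

__all__ = ["HSVImage", "msrcp_enhance", "rgb_to_hsv"]

DEFAULT_SCALES = (15.0, 80.0, 250.0)


@dataclass
class HSVImage:
    """Hue in degrees [0, 360), saturation in [0, 1], value on the input scale."""

    h: np.ndarray
    s: np.ndarray
    v: np.ndarray


def _gaussian_surround(img: np.ndarray, sigma: float) -> np.ndarray:
    """Large-kernel Gaussian blur via FFT with reflective padding.

    The surround scales used by Retinex (up to hundreds of pixels) make
    spatial convolution the bottleneck; the FFT route is exact for the
    periodized signal and the reflect pad suppresses wrap-around.
    """
    pad = int(min(3 * sigma, max(img.shape)))
    padded = np.pad(img, pad, mode="reflect")
    blurred = np.fft.irfftn(
        fourier_gaussian(np.fft.rfftn(padded), sigma, n=padded.shape[-1]),
        s=padded.shape,
        axes=(0, 1),
    )
    return blurred[pad : pad + img.shape[0], pad : pad + img.shape[1]]


def msrcp_enhance(
    frame: np.ndarray,
    scales: Sequence[float] = DEFAULT_SCALES,
    clip_percentiles: tuple[float, float] = (1.0, 99.0),
    out_max: float = 255.0,
) -> np.ndarray:
    """Enhance a grayscale or RGB frame with MSRCP.

    Parameters
    ----------
    frame : (rows, cols) or (rows, cols, 3) array, nonnegative intensities.
    scales : Gaussian surround sigmas in pixels (equal weights).
    clip_percentiles : simplest-color-balance clipping percentiles applied
        to the multiscale Retinex output before range stretching.
    out_max : top of the output intensity range.

    Returns
    -------
    float array of the input shape on [0, out_max]. The per-pixel channel
    ratios of RGB input are preserved (one scalar gain per pixel).
    """
    if len(scales) < 1:
        raise ValueError("at least one surround scale is required")
    img = np.asarray(frame, dtype=float)
    if np.any(img < 0):
        raise ValueError("intensities must be nonnegative")
    rgb = img.ndim == 3
    intensity = img.mean(axis=-1) if rgb else img

    if not intensity.any():  # all-zero image: gain undefined, defined as 1
        return img

    log_i = np.log1p(intensity)
    msr = np.zeros_like(intensity)
    for sigma in scales:
        msr += log_i - np.log1p(_gaussian_surround(intensity, sigma))
    msr /= len(scales)

    lo, hi = np.percentile(msr, clip_percentiles)
    if hi <= lo:  # flat Retinex response (e.g. uniform image): nothing to stretch
        return img
    stretched = np.clip((msr - lo) / (hi - lo), 0.0, 1.0) * out_max

    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(intensity > 0, stretched / intensity, 1.0)
    if rgb:
        # cap the gain so no channel clips, which would break chromaticity
        peak = img.max(axis=-1)
        with np.errstate(divide="ignore"):
            cap = np.where(peak > 0, out_max / peak, 1.0)
        gain = np.minimum(gain, cap)
        return img * gain[..., None]
    return np.clip(img * gain, 0.0, out_max)


def rgb_to_hsv(frame: np.ndarray) -> HSVImage:
    """Convert an RGB frame to the HSV feature space.

    V = max(R, G, B); S = (max - min) / max (0 where max = 0); H follows the
    three conditional branches of the hexcone model, in degrees wrapped to
    [0, 360), with H = 0 by convention where S = 0.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(
            "rgb_to_hsv needs a 3-channel image; for grayscale frames use "
            "synthetic.to_rgb to replicate channels first"
        )
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    v = img.max(axis=-1)
    mn = img.min(axis=-1)
    delta = v - mn

    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(v > 0, delta / v, 0.0)
        h = np.where(
            delta == 0,
            0.0,
            np.select(
                [v == r, v == g],
                [60.0 * (g - b) / delta, 120.0 + 60.0 * (b - r) / delta],
                default=240.0 + 60.0 * (r - g) / delta,
            ),
        )
    h = np.where(h < 0, h + 360.0, h)
    h = np.where(h >= 360.0, h - 360.0, h)
    return HSVImage(h=h, s=s, v=v)
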
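"""Grayscale conversion and the shared preprocessing stage (CLAHE + Gaussian).

Both segmentation engines see the same preprocessed image: contrast-limited
adaptive histogram equalization first, then Gaussian smoothing. CLAHE is
implemented here with OpenCV-style semantics (tile grid, clip limit in
multiples of the uniform bin count, bilinear interpolation of the per-tile
mappings) so that a 1×1 tile grid with a large clip limit reduces exactly to
global histogram equalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .io import Frame


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing stage.

    clahe_clip_limit: histogram clip limit as a multiple of the uniform
        bin height (OpenCV convention); larger means less clipping.
    clahe_tile_grid: (rows, cols) of the CLAHE tile grid.
    gaussian_sigma: smoothing sigma in pixels; 0 disables smoothing.
    enabled: master switch (the gradient baseline can run on raw grayscale).
    """

    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    gaussian_sigma: float = 0.6
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.clahe_clip_limit <= 0:
            raise ValidationError("clahe_clip_limit must be > 0")
        if min(self.clahe_tile_grid) < 1:
            raise ValidationError("clahe_tile_grid dims must be >= 1")
        if self.gaussian_sigma < 0:
            raise ValidationError("gaussian_sigma must be >= 0")


def to_grayscale(frame: Frame | np.ndarray) -> np.ndarray:
    """Convert an RGB frame to grayscale as I = (R + G + B) / 3.

    The division rounds half-up to an integer in [0, 255]; grayscale
    input is returned unchanged.
    """
    px = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if px.ndim == 2:
        return px
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValidationError(f"expected 2D grayscale or H×W×3 RGB, got shape {px.shape}")
    s = px.astype(np.int64).sum(axis=2)
    # floor(s/3 + 1/2) in exact integer arithmetic
    return ((2 * s + 3) // 6).astype(np.uint8)


def equalize_clahe(
    gray: np.ndarray, clip_limit: float = 2.0, tile_grid: tuple[int, int] = (8, 8)
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit image.

    Each tile's 256-bin histogram is clipped at ``clip_limit`` times the
    uniform bin height, the excess is redistributed uniformly, and the
    resulting CDF maps the tile to [0, 255]. Per-pixel output bilinearly
    interpolates the mappings of the four surrounding tile centers.
    """
    gray = _check_gray(gray)
    rows, cols = tile_grid
    h, w = gray.shape
    th = -(-h // rows)  # ceil
    tw = -(-w // cols)
    padded = np.pad(gray, ((0, rows * th - h), (0, cols * tw - w)), mode="reflect")

    area = th * tw
    clip = max(clip_limit * area / 256.0, 1.0)
    luts = np.empty((rows, cols, 256), dtype=np.float64)
    for r in range(rows):
        for c in range(cols):
            tile = padded[r * th : (r + 1) * th, c * tw : (c + 1) * tw]
            hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
            excess = np.maximum(hist - clip, 0.0).sum()
            hist = np.minimum(hist, clip) + excess / 256.0
            cdf = np.cumsum(hist)
            luts[r, c] = np.floor(cdf * (255.0 / area) + 0.5)

    if rows == 1 and cols == 1:
        out = luts[0, 0][padded]
        return out[:h, :w].astype(np.uint8)

    # fractional tile coordinates of each padded pixel relative to tile centers
    fy = (np.arange(rows * th) + 0.5) / th - 0.5
    fx = (np.arange(cols * tw) + 0.5) / tw - 0.5
    r0 = np.clip(np.floor(fy).astype(int), 0, rows - 2) if rows > 1 else np.zeros(rows * th, int)
    c0 = np.clip(np.floor(fx).astype(int), 0, cols - 2) if cols > 1 else np.zeros(cols * tw, int)
    wy = np.clip(fy - r0, 0.0, 1.0) if rows > 1 else np.zeros(rows * th)
    wx = np.clip(fx - c0, 0.0, 1.0) if cols > 1 else np.zeros(cols * tw)
    r1 = np.minimum(r0 + 1, rows - 1)
    c1 = np.minimum(c0 + 1, cols - 1)

    v = padded
    top = (1 - wx)[None, :] * luts[r0[:, None], c0[None, :], v] + wx[None, :] * luts[
        r0[:, None], c1[None, :], v
    ]
    bot = (1 - wx)[None, :] * luts[r1[:, None], c0[None, :], v] + wx[None, :] * luts[
        r1[:, None], c1[None, :], v
    ]
    out = (1 - wy)[:, None] * top + wy[:, None] * bot
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)[:h, :w]


def smooth_gaussian(gray: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with reflective borders; sigma = 0 is the identity."""
    gray = _check_gray(gray)
    if sigma == 0:
        return gray
    blurred = ndimage.gaussian_filter(gray.astype(np.float64), sigma=sigma, mode="reflect")
    return np.clip(np.floor(blurred + 0.5), 0, 255).astype(np.uint8)


def preprocess_frame(gray: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Apply CLAHE then Gaussian smoothing; returns uint8 of the same shape."""
    config = config or PreprocessConfig()
    gray = _check_gray(gray)
    if not config.enabled:
        return gray
    out = equalize_clahe(gray, config.clahe_clip_limit, config.clahe_tile_grid)
    return smooth_gaussian(out, config.gaussian_sigma)


def _check_gray(gray: np.ndarray) -> np.ndarray:
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValidationError(f"expected a 2D grayscale image, got shape {gray.shape}")
    if gray.dtype != np.uint8:
        if gray.min() < 0 or gray.max() > 255:
            raise ValidationError("grayscale intensities must lie in [0, 255]")
        gray = gray.astype(np.uint8)
    return gray
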
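"""Gabor filter bank for oriented-texture detection.

The bank realizes the real (even-cosine) component of the 2D Gabor function

    g(x, y) = (f² / (π γ η)) · exp(−(x′² f² / γ² + y′² f² / η²)) · cos(2π f x′)
    x′ =  x cosθ + y sinθ
    y′ = −x sinθ + y cosθ

sampled on a size×size grid whose axes span [−1, 1], so that the spatial
frequency f is dimensionless: f = 3 means three carrier cycles per kernel
half-width. γ and η set the envelope sharpness along the major and minor
axes. Each kernel is mean-subtracted (DC removal) so a constant image
produces an identically zero response.

Defaults: f = 3.0, 21×21 kernels, orientations 0°/45°/90°/135°, γ = 10,
η = 0.5 — a single-scale, four-orientation set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError

DEFAULT_THETAS = (0.0, 45.0, 90.0, 135.0)


@dataclass(frozen=True)
class GaborBankConfig:
    f: float = 3.0
    size: int = 21
    thetas: tuple[float, ...] = DEFAULT_THETAS
    gamma: float = 10.0
    eta: float = 0.5
    n_scales: int = 1
    combine: str = "max"  # "max" or "sum" of absolute orientation responses

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValidationError("kernel size must be odd and >= 3")
        if self.f <= 0 or self.gamma <= 0 or self.eta <= 0:
            raise ValidationError("f, gamma and eta must all be > 0")
        if not self.thetas:
            raise ValidationError("at least one orientation is required")
        if any(not 0.0 <= t < 180.0 for t in self.thetas):
            raise ValidationError("orientations must lie in [0, 180) degrees")
        if self.combine not in ("max", "sum"):
            raise ValidationError("combine must be 'max' or 'sum'")


@dataclass(frozen=True)
class GaborKernel:
    """A realized convolution kernel: mean-free real Gabor at one orientation."""

    real_part: np.ndarray
    theta: float


def build_gabor_kernel(
    config: GaborBankConfig, theta: float, remove_dc: bool = True
) -> GaborKernel:
    """Evaluate the real Gabor function at one orientation.

    With ``remove_dc`` the kernel is mean-subtracted so its entries sum to
    zero. Before DC removal the center value is exactly f²/(πγη).
    """
    if config.size % 2 == 0:
        raise ValidationError("kernel size must be odd")
    ax = np.linspace(-1.0, 1.0, config.size)
    x, y = np.meshgrid(ax, ax)  # x along columns, y along rows
    t = math.radians(theta)
    xp = x * math.cos(t) + y * math.sin(t)
    yp = -x * math.sin(t) + y * math.cos(t)
    f, g, e = config.f, config.gamma, config.eta
    envelope = np.exp(-((xp**2) * f**2 / g**2 + (yp**2) * f**2 / e**2))
    kernel = (f**2 / (math.pi * g * e)) * envelope * np.cos(2.0 * math.pi * f * xp)
    if remove_dc:
        kernel = kernel - kernel.mean()
    return GaborKernel(real_part=kernel, theta=theta)


def build_bank(config: GaborBankConfig) -> list[GaborKernel]:
    """One kernel per configured orientation, in the order given."""
    return [build_gabor_kernel(config, theta) for theta in config.thetas]


def matched_grating_response(config: GaborBankConfig, amplitude: float = 1.0) -> float:
    """Peak response of a bank kernel to its own carrier grating.

    This is the correlation of the θ = 0 kernel with a cosine grating of the
    kernel's frequency, orientation and phase, scaled by ``amplitude``
    (intensity units). It provides an absolute reference for response
    magnitudes, e.g. to cap the per-frame response normalization gain.
    """
    kernel = build_gabor_kernel(config, 0.0).real_part
    ax = np.linspace(-1.0, 1.0, config.size)
    x, _ = np.meshgrid(ax, ax)
    grating = np.cos(2.0 * math.pi * config.f * x)
    return float(amplitude * np.sum(kernel * grating))


def apply_bank(
    gray: np.ndarray,
    bank: list[GaborKernel],
    combine: str = "max",
    min_scale: float = 0.0,
) -> np.ndarray:
    """Correlate an image with every kernel and fuse the orientation responses.

    Each kernel is correlated with the image under reflective borders; the
    fused response is the pixel-wise maximum (or sum) of the absolute
    orientation responses, rescaled linearly to [0, 255].

    The rescale divisor is ``max(peak response, min_scale)``: with the
    default ``min_scale = 0`` this is plain per-frame peak normalization,
    while a positive ``min_scale`` (in absolute correlation units, see
    :func:`matched_grating_response`) caps the gain so frames containing no
    texture — only sensor noise — are not amplified to full range. An
    all-zero response stays all-zero.
    """
    if not bank:
        raise ValidationError("Gabor bank is empty")
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValidationError(f"expected a 2D image, got shape {gray.shape}")
    responses = [
        np.abs(ndimage.correlate(gray, k.real_part, mode="reflect")) for k in bank
    ]
    if combine == "sum":
        fused = np.sum(responses, axis=0)
    elif combine == "max":
        fused = np.maximum.reduce(responses)
    else:
        raise ValidationError("combine must be 'max' or 'sum'")
    peak = float(fused.max())
    if peak <= 1e-9:  # numerically zero response (e.g. constant image)
        return np.zeros_like(fused)
    scale = max(peak, float(min_scale))
    return fused * (255.0 / scale)
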
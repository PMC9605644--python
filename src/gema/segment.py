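"""Binary cell-mask production.

Two engines are provided:

* the adaptive engine: preprocessed grayscale → Gabor bank response →
  locally adaptive binarization whose offset parameter is scheduled online
  from the CV regression → binary closing (plus an optional dilation);
* the morphological-gradient baseline: preprocessed grayscale → gradient
  (local max − local min under a 5×5 structuring element) → fixed global
  threshold of 25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .control import (
    ControllerState,
    CVPoint,
    coefficient_of_variation,
    update_controller,
)
from .errors import UndefinedCVError, ValidationError
from .gabor import GaborKernel, apply_bank
from .io import Frame, TraceRow
from .metrics import percent_cells
from .preprocess import PreprocessConfig, preprocess_frame, to_grayscale

logger = logging.getLogger(__name__)

GRADIENT_THRESHOLD = 25


@dataclass(frozen=True)
class StructuringElement:
    """A square or disk neighborhood of odd side length."""

    shape: str = "square"
    size: int = 5

    def __post_init__(self) -> None:
        if self.shape not in ("square", "disk"):
            raise ValidationError(f"unknown structuring element shape {self.shape!r}")
        if self.size < 3 or self.size % 2 == 0:
            raise ValidationError("structuring element size must be odd and >= 3")

    def footprint(self) -> np.ndarray:
        if self.shape == "square":
            return np.ones((self.size, self.size), dtype=bool)
        from skimage.morphology import disk

        return disk((self.size - 1) // 2).astype(bool)


@dataclass(frozen=True)
class GemaParams:
    """Parameters of the adaptive engine.

    threshold_c is the scheduled offset in [5, 11]: a pixel is foreground
    iff its Gabor response exceeds the local (Gaussian-weighted) mean by
    more than threshold_c. adaptive_block_size is the local window side
    (must exceed a cell diameter). min_texture_amplitude caps the response
    normalization gain: it is the smallest texture contrast (intensity
    units) treated as signal rather than sensor noise (0 disables the cap).
    """

    adaptive_block_size: int = 101
    threshold_c: int = 8
    closing_se: StructuringElement = field(default_factory=lambda: StructuringElement("square", 7))
    dilation_se: StructuringElement | None = None
    adaptive_method: str = "gaussian"  # or "mean" (uniform local mean)
    cv_source: str = "preprocessed"  # or "raw"
    min_texture_amplitude: float = 25.0

    def __post_init__(self) -> None:
        if self.adaptive_block_size < 3 or self.adaptive_block_size % 2 == 0:
            raise ValidationError("adaptive_block_size must be odd and >= 3")
        if not 5 <= self.threshold_c <= 11:
            raise ValidationError("threshold_c must lie in [5, 11]")
        if self.adaptive_method not in ("gaussian", "mean"):
            raise ValidationError("adaptive_method must be 'gaussian' or 'mean'")
        if self.cv_source not in ("preprocessed", "raw"):
            raise ValidationError("cv_source must be 'preprocessed' or 'raw'")


def morphological_gradient(gray: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Dilation minus erosion: per-pixel local max − local min (reflective border)."""
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValidationError(f"expected a 2D image, got shape {gray.shape}")
    fp = se.footprint()
    hi = ndimage.maximum_filter(gray, footprint=fp, mode="reflect")
    lo = ndimage.minimum_filter(gray, footprint=fp, mode="reflect")
    return (hi.astype(np.int64) - lo.astype(np.int64)).astype(np.int64)


def segment_gradient(
    frame: Frame,
    preprocess_config: PreprocessConfig | None = None,
    se: StructuringElement = StructuringElement("square", 5),
    threshold: int = GRADIENT_THRESHOLD,
) -> np.ndarray:
    """Morphological-gradient baseline: gradient > threshold (strict)."""
    gray = to_grayscale(frame)
    gray = preprocess_frame(gray, preprocess_config)
    grad = morphological_gradient(gray, se)
    return (grad > threshold).astype(np.uint8)


def adaptive_binarize(response: np.ndarray, params: GemaParams) -> np.ndarray:
    """Locally adaptive binarization of a [0, 255] response image.

    A pixel is foreground iff response − local mean > threshold_c, where the
    local mean is Gaussian-weighted (sd = block_size / 6, support clipped at
    the block) or uniform, under reflective borders. Ties go to background,
    so a constant response yields an empty mask.
    """
    response = np.asarray(response, dtype=np.float64)
    if response.ndim != 2:
        raise ValidationError(f"expected a 2D response, got shape {response.shape}")
    block = params.adaptive_block_size
    if block % 2 == 0:
        raise ValidationError("adaptive_block_size must be odd")
    if params.adaptive_method == "gaussian":
        sigma = block / 6.0
        radius = (block - 1) // 2
        local = ndimage.gaussian_filter(
            response, sigma=sigma, mode="reflect", truncate=radius / sigma
        )
    else:
        local = ndimage.uniform_filter(response, size=block, mode="reflect")
    return (response - local > params.threshold_c).astype(np.uint8)


def morph_postprocess(
    mask: np.ndarray,
    closing_se: StructuringElement,
    dilation_se: StructuringElement | None = None,
) -> np.ndarray:
    """Binary closing then (optionally) dilation.

    Border handling pads dilation with background and erosion with
    foreground, so closing is extensive (mask ⊆ closing(mask)) up to the
    image boundary and idempotent.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValidationError(f"expected a 2D mask, got shape {mask.shape}")
    fp = closing_se.footprint()
    out = ndimage.binary_dilation(mask, structure=fp, border_value=0)
    out = ndimage.binary_erosion(out, structure=fp, border_value=1)
    if dilation_se is not None:
        out = ndimage.binary_dilation(out, structure=dilation_se.footprint(), border_value=0)
    return out.astype(np.uint8)


def segment_gema(
    frame: Frame,
    controller_state: ControllerState,
    preprocess_config: PreprocessConfig | None,
    bank: list[GaborKernel],
    params: GemaParams,
    bank_reference_response: float = 0.0,
) -> tuple[np.ndarray | None, ControllerState, TraceRow | None]:
    """Run one frame through the adaptive pipeline.

    Steps: grayscale → preprocess → CV → controller update (schedules the
    threshold offset) → Gabor response → adaptive binarization → closing +
    dilation. Returns (mask, updated state, trace row).

    ``bank_reference_response`` is the absolute response a unit-amplitude
    matched grating produces (see :func:`gema.gabor.matched_grating_response`);
    together with ``params.min_texture_amplitude`` it caps the response
    normalization gain. A frame with undefined CV (zero mean) is skipped:
    the state is returned unchanged and mask/row are ``None``.
    """
    gray = to_grayscale(frame)
    pre = preprocess_frame(gray, preprocess_config)
    cv_image = pre if params.cv_source == "preprocessed" else gray
    try:
        cv = coefficient_of_variation(cv_image)
    except UndefinedCVError:
        logger.warning("frame %d (%s): undefined CV, skipped", frame.index, frame.source_name)
        return None, controller_state, None

    state = update_controller(controller_state, CVPoint(frame.index, cv))
    scheduled = replace(params, threshold_c=state.current_threshold)
    min_scale = params.min_texture_amplitude * bank_reference_response
    response = apply_bank(pre, bank, min_scale=min_scale)
    mask = adaptive_binarize(response, scheduled)
    mask = morph_postprocess(mask, params.closing_se, params.dilation_se)
    row = TraceRow(
        frame=frame.index,
        filename=frame.source_name,
        cv=cv,
        threshold=state.current_threshold,
        percent_cells=percent_cells(mask),
    )
    return mask, state, row
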
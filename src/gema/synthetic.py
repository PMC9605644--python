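"""Seeded synthetic time-lapse sequences with exact ground truth.

Emulates brightfield sequences of adherent MCF7-like cells in a
microfluidic chamber: elliptical cell patches carrying granular band-pass
texture on a noisy background dotted with static out-of-focus debris, with
the covered fraction ramping monotonically toward confluence (growth) or
down during drug-induced apoptosis. The rendering encodes the optical
features the segmentation method depends on:

* cell bodies are granular (band-pass noise at a few-pixel grain scale)
  and slightly brighter than the background — texture, not a sharp
  outline, is what distinguishes cell from background;
* the outer few pixels of every cell are optically faint (thin spread
  margins), although the gold-standard mask includes them, as a human
  annotator's polygon would;
* crowded monolayers flatten: per-cell contrast falls with the covered
  fraction, which is why the frame's coefficient of variation drops again
  as the culture approaches confluence.

Cell placements persist across frames: growth adds cells to a fixed pool
in order, apoptosis removes the most recently added ones, so textures are
temporally coherent. Ground-truth masks are exact unions of the rendered
ellipses. Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import Frame, write_image, write_mask

COVERAGE_TOL = 0.02  # per-frame target must be hit within ±2 percentage points


@dataclass(frozen=True)
class SyntheticConfig:
    height: int = 256
    width: int = 256
    n_frames: int = 20
    kind: str = "growth"  # or "apoptosis"
    coverage_start: float = 0.1
    coverage_end: float = 0.9
    cell_radius_range: tuple[float, float] = (12.0, 30.0)
    cell_texture_contrast: float = 70.0
    texture_wavelength_range: tuple[float, float] = (3.0, 4.5)
    edge_softness_px: float = 4.0
    faint_margin_px: float = 5.0
    confluence_flattening: float = 0.8  # fractional contrast loss at full coverage
    background_level: float = 120.0
    noise_sd: float = 3.0
    debris_count: int = 40
    debris_radius_range: tuple[float, float] = (4.0, 10.0)
    debris_contrast: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ConfigError("image dimensions must be >= 8")
        if self.kind not in ("growth", "apoptosis"):
            raise ConfigError(f"kind must be 'growth' or 'apoptosis', got {self.kind!r}")
        for c in (self.coverage_start, self.coverage_end):
            if not 0.0 <= c <= 1.0:
                raise ConfigError("coverage fractions must lie in [0, 1]")
        if self.kind == "growth" and not self.coverage_start < self.coverage_end:
            raise ConfigError("growth requires coverage_start < coverage_end")
        if self.kind == "apoptosis" and not self.coverage_start > self.coverage_end:
            raise ConfigError("apoptosis requires coverage_start > coverage_end")
        rmin, rmax = self.cell_radius_range
        if not 0 < rmin <= rmax:
            raise ConfigError("cell_radius_range must satisfy 0 < min <= max")
        if rmax > min(self.height, self.width):
            raise ConfigError("cell radius exceeds image size: coverage targets unreachable")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class _Cell:
    cy: float
    cx: float
    ry: float
    rx: float
    angle: float  # ellipse rotation, radians
    wavelength: float  # dominant texture grain scale, px
    tex_seed: int  # per-cell seed so texture is identical in every frame


def _sample_cell(config: SyntheticConfig, rng: np.random.Generator) -> _Cell:
    rmin, rmax = config.cell_radius_range
    lmin, lmax = config.texture_wavelength_range
    return _Cell(
        cy=rng.uniform(0, config.height),
        cx=rng.uniform(0, config.width),
        ry=rng.uniform(rmin, rmax),
        rx=rng.uniform(rmin, rmax),
        angle=rng.uniform(0, math.pi),
        wavelength=rng.uniform(lmin, lmax),
        tex_seed=int(rng.integers(0, 2**31)),
    )


@lru_cache(maxsize=512)
def _cell_texture_cached(tex_seed: int, wavelength: float, height: int, width: int) -> np.ndarray:
    return _compute_cell_texture(tex_seed, wavelength, height, width)


def _cell_texture(cell: _Cell, height: int, width: int) -> np.ndarray:
    """Granular (broadband band-pass noise) texture field, zero mean, unit sd.

    Real brightfield cell bodies show isotropic granularity rather than an
    oriented grating, so the texture is white noise band-passed around the
    cell's grain scale (difference of Gaussians), clipped at ±2 sd. Cached:
    a cell keeps the identical texture in every frame of a sequence.
    """
    return _cell_texture_cached(cell.tex_seed, cell.wavelength, height, width)


def _compute_cell_texture(tex_seed: int, wavelength: float, height: int, width: int) -> np.ndarray:
    from scipy import ndimage as _ndi

    rng = np.random.default_rng(tex_seed)
    white = rng.standard_normal((height, width))
    field = _ndi.gaussian_filter(white, wavelength / 6.0) - _ndi.gaussian_filter(
        white, wavelength / 3.0
    )
    sd = field.std()
    if sd > 0:
        field = field / sd
    return np.clip(field, -2.0, 2.0)


def _cell_rho(cell: _Cell, height: int, width: int) -> np.ndarray:
    """Normalized elliptical radius of every pixel (1.0 on the boundary)."""
    yy, xx = np.mgrid[0:height, 0:width]
    dy = yy - cell.cy
    dx = xx - cell.cx
    u = dx * math.cos(cell.angle) + dy * math.sin(cell.angle)
    v = -dx * math.sin(cell.angle) + dy * math.cos(cell.angle)
    return np.sqrt((u / cell.rx) ** 2 + (v / cell.ry) ** 2)


def _cell_mask(cell: _Cell, height: int, width: int) -> np.ndarray:
    return _cell_rho(cell, height, width) <= 1.0


def _build_pool(
    config: SyntheticConfig, rng: np.random.Generator, needed: float
) -> tuple[list[_Cell], list[np.ndarray], list[float]]:
    """Sample cells until the cumulative union coverage reaches ``needed``.

    Returns the pool, the cumulative union masks and coverages after each
    added cell (index k = first k+1 cells).
    """
    n_px = config.height * config.width
    cells: list[_Cell] = []
    cum_masks: list[np.ndarray] = []
    coverages: list[float] = []
    union = np.zeros((config.height, config.width), dtype=bool)
    for _ in range(100_000):
        if coverages and coverages[-1] >= needed:
            break
        cell = _sample_cell(config, rng)
        union = union | _cell_mask(cell, config.height, config.width)
        cells.append(cell)
        cum_masks.append(union.copy())
        coverages.append(union.sum() / n_px)
    else:
        raise ConfigError(f"could not reach coverage {needed} with the configured cells")
    return cells, cum_masks, coverages


def _sample_debris(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Static out-of-focus debris field added to the chamber background.

    Real microfluidic chambers carry dust, dead-cell fragments and PDMS
    imperfections: smooth dim blobs that persist across the sequence and
    belong to the background in the gold standard. They are spectrally
    below the cell-texture band (no sharp edges, no fine granularity).
    """
    field = np.zeros((config.height, config.width), dtype=np.float64)
    rmin, rmax = config.debris_radius_range
    yy, xx = np.mgrid[0 : config.height, 0 : config.width]
    for _ in range(config.debris_count):
        cy = rng.uniform(0, config.height)
        cx = rng.uniform(0, config.width)
        r = rng.uniform(rmin, rmax)
        amp = rng.uniform(-1.0, 1.0) * config.debris_contrast
        field += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * (r / 2.0) ** 2))
    return field


def _render(
    config: SyntheticConfig,
    cells: Sequence[_Cell],
    mask: np.ndarray,
    rng: np.random.Generator,
    index: int,
    name: str,
    debris: np.ndarray | None = None,
    coverage: float = 0.0,
) -> Frame:
    img = np.full((config.height, config.width), config.background_level, dtype=np.float64)
    if debris is not None:
        img = img + debris
    # contact inhibition flattens crowded monolayers, reducing their optical
    # contrast; per-cell contrast falls linearly with the covered fraction
    c = config.cell_texture_contrast * (1.0 - config.confluence_flattening * coverage)
    # cells spread thin at their margins: the pattern tapers smoothly to the
    # background over ~edge_softness_px so boundaries carry no sharp step
    acc_w = np.zeros_like(img)
    for cell in cells:
        rho = _cell_rho(cell, config.height, config.width)
        r_eff = min(cell.rx, cell.ry)
        if config.edge_softness_px > 0 or config.faint_margin_px > 0:
            # thin spread margins are nearly invisible: the pattern is zero in
            # the outer faint_margin_px band of the cell (still cell in the
            # gold mask) and ramps up over the next edge_softness_px
            d = ((1.0 - rho) * r_eff - config.faint_margin_px) / max(
                config.edge_softness_px, 1e-9
            )
            w = np.clip(d, 0.0, 1.0)
            w = w * w * (3.0 - 2.0 * w)  # smoothstep
        else:
            w = (rho <= 1.0).astype(np.float64)
        tex = c * (0.7 + 0.35 * _cell_texture(cell, config.height, config.width))
        takeover = w > acc_w
        blended = (1.0 - w) * img + w * (config.background_level + tex)
        img[takeover] = blended[takeover]
        acc_w = np.maximum(acc_w, w)
    img = img + rng.normal(0.0, config.noise_sd, img.shape)
    pixels = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return Frame(pixels=pixels, index=index, source_name=name)


def generate_frame(
    config: SyntheticConfig,
    target_coverage: float,
    rng: np.random.Generator | None = None,
    index: int = 0,
) -> tuple[Frame, np.ndarray]:
    """Generate one frame whose cell coverage is within ±2 points of target.

    Targets of exactly 0 and 1 are honored exactly (no cells / full cover).
    """
    if not 0.0 <= target_coverage <= 1.0:
        raise ConfigError("target_coverage must lie in [0, 1]")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    shape = (config.height, config.width)
    debris = _sample_debris(config, rng)
    if target_coverage == 0.0:
        frame = _render(
            config, [], np.zeros(shape, bool), rng, index, f"synthetic_{index:04d}.png",
            debris=debris,
        )
        return frame, np.zeros(shape, dtype=np.uint8)
    if target_coverage == 1.0:
        big = _Cell(
            cy=shape[0] / 2, cx=shape[1] / 2,
            ry=float(sum(shape)), rx=float(sum(shape)),
            angle=0.0,
            wavelength=float(np.mean(config.texture_wavelength_range)),
            tex_seed=int(rng.integers(0, 2**31)),
        )
        mask = np.ones(shape, dtype=np.uint8)
        frame = _render(
            config, [big], mask.astype(bool), rng, index, f"synthetic_{index:04d}.png",
            debris=debris, coverage=1.0,
        )
        return frame, mask
    cells, cum_masks, coverages = _build_pool(config, rng, min(target_coverage + COVERAGE_TOL, 1.0))
    k = int(np.argmin(np.abs(np.asarray(coverages) - target_coverage)))
    frame = _render(
        config, cells[: k + 1], cum_masks[k], rng, index, f"synthetic_{index:04d}.png",
        debris=debris, coverage=float(coverages[k]),
    )
    return frame, cum_masks[k].astype(np.uint8)


def coverage_schedule(config: SyntheticConfig) -> np.ndarray:
    """Monotone logistic ramp from coverage_start to coverage_end."""
    u = np.linspace(0.0, 1.0, config.n_frames)
    raw = 1.0 / (1.0 + np.exp(-6.0 * (u - 0.5)))
    ramp = (raw - raw[0]) / (raw[-1] - raw[0])
    return config.coverage_start + (config.coverage_end - config.coverage_start) * ramp


def generate_sequence(
    config: SyntheticConfig,
) -> tuple[list[tuple[Frame, np.ndarray]], list[float]]:
    """Generate a coherent time-lapse sequence with exact ground truth.

    Returns ([(frame, mask), ...], true_coverage) where true_coverage is the
    realized (not target) covered fraction per frame. Growth sequences add
    cells monotonically; apoptosis sequences remove them in reverse order.
    """
    if config.n_frames < 2:
        raise ConfigError("a sequence needs n_frames >= 2")
    rng = np.random.default_rng(config.seed)
    debris = _sample_debris(config, rng)
    targets = coverage_schedule(config)
    max_needed = min(float(targets.max()) + COVERAGE_TOL, 1.0)
    cells, cum_masks, coverages = _build_pool(config, rng, max_needed)
    cov_arr = np.asarray(coverages)

    # one noise field per frame, drawn in frame order for determinism
    pairs: list[tuple[Frame, np.ndarray]] = []
    truth: list[float] = []
    for i, target in enumerate(targets):
        k = int(np.argmin(np.abs(cov_arr - target)))
        frame = _render(
            config, cells[: k + 1], cum_masks[k], rng, i, f"synthetic_{i:04d}.png",
            debris=debris, coverage=float(cov_arr[k]),
        )
        pairs.append((frame, cum_masks[k].astype(np.uint8)))
        truth.append(float(cov_arr[k]))
    return pairs, truth


def write_sequence(config: SyntheticConfig, out_dir: str | Path) -> Path:
    """Write frames, masks and a manifest CSV for a generated sequence.

    Layout: ``frames/synthetic_NNNN.png``, ``masks/synthetic_NNNN.png``
    (values {0, 255}) and ``manifest.csv`` (frame, filename, true_coverage).
    """
    out_dir = Path(out_dir)
    frames_dir = out_dir / "frames"
    masks_dir = out_dir / "masks"
    frames_dir.mkdir(parents=True, exist_ok=True)
    masks_dir.mkdir(parents=True, exist_ok=True)
    pairs, truth = generate_sequence(config)
    records = []
    for (frame, mask), cov in zip(pairs, truth):
        write_image(frame, frames_dir / frame.source_name)
        write_mask(mask, masks_dir / frame.source_name)
        records.append(
            {"frame": frame.index, "filename": frame.source_name, "true_coverage": cov}
        )
    pd.DataFrame.from_records(records).to_csv(
        out_dir / "manifest.csv", index=False, float_format="%.6g"
    )
    return out_dir
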
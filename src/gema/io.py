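"""Image, annotation and trace I/O.

Reads time-lapse frames (PNG/JPEG/TIFF, 8- or 16-bit), parses VGG Image
Annotator (VIA) JSON polygon annotations into gold-standard binary masks,
and round-trips per-frame trace tables as CSV.

Coordinate convention throughout: x = column, y = row, 0-based, origin at
the top-left pixel center — the convention VIA uses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from PIL import Image, UnidentifiedImageError

from .errors import FormatError, ImageIOError, ValidationError

_PIL_SUFFIXES = {".png", ".jpg", ".jpeg"}
_TIFF_SUFFIXES = {".tif", ".tiff"}

TRACE_COLUMNS = ("frame", "filename", "cv", "threshold", "percent_cells")


@dataclass(frozen=True)
class Frame:
    """One time-lapse image with its position in the sequence.

    ``pixels`` is H×W (grayscale) or H×W×3 (RGB) uint8.
    """

    pixels: np.ndarray
    index: int
    source_name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError(f"frame pixels must be H×W or H×W×3, got shape {px.shape}")
        if px.ndim == 3 and px.shape[2] != 3:
            raise ValidationError(f"color frames must have 3 channels, got {px.shape[2]}")
        if self.index < 0:
            raise ValidationError("frame index must be non-negative")
        if px.min() < 0 or px.max() > 255:
            raise ValidationError("frame intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class PolygonAnnotation:
    """An ordered polygon outlining one annotated cell region."""

    vertices: tuple[tuple[float, float], ...]
    label: str = "cell"

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ValidationError(f"polygon needs >= 3 vertices, got {len(verts)}")
        object.__setattr__(self, "vertices", verts)


@dataclass(frozen=True)
class TraceRow:
    """Per-frame record emitted by a segmentation engine."""

    frame: int
    filename: str
    cv: float
    threshold: int
    percent_cells: float


@dataclass
class ExperimentTrace:
    """Ordered per-frame trace of CV, scheduled threshold and percent cells.

    The threshold column holds whatever the engine used: the scheduled
    integer in [5, 11] for the adaptive engine, the fixed gradient
    threshold (25) for the baseline.
    """

    rows: list[TraceRow] = field(default_factory=list)

    def append(self, row: TraceRow) -> None:
        if self.rows and row.frame <= self.rows[-1].frame:
            raise ValidationError(
                f"trace rows must have strictly increasing frame index: "
                f"{row.frame} after {self.rows[-1].frame}"
            )
        if not 0.0 <= row.percent_cells <= 100.0:
            raise ValidationError(f"percent_cells out of [0, 100]: {row.percent_cells}")
        self.rows.append(row)

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([row.__dict__ for row in self.rows], columns=TRACE_COLUMNS)


def read_image(path: str | Path, index: int = 0) -> Frame:
    """Read a PNG/JPEG/TIFF image into a :class:`Frame`.

    16-bit inputs are rescaled linearly by the dtype maximum (not the
    per-image maximum, which would distort CV across a sequence).
    Grayscale images stay 2D.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        try:
            arr = tifffile.imread(path)
        except FileNotFoundError:
            raise ImageIOError(f"cannot read image: {path}") from None
        except Exception as exc:  # tifffile raises assorted errors on corrupt input
            raise ImageIOError(f"cannot read image: {path}: {exc}") from exc
    elif suffix in _PIL_SUFFIXES:
        try:
            with Image.open(path) as img:
                if img.mode not in ("L", "I;16", "I", "RGB"):
                    img = img.convert("RGB")
                arr = np.asarray(img)
        except FileNotFoundError:
            raise ImageIOError(f"cannot read image: {path}") from None
        except (UnidentifiedImageError, OSError, SyntaxError, ValueError, AttributeError) as exc:
            # PIL surfaces truncated/corrupt files through assorted exception types
            raise ImageIOError(f"cannot decode image: {path}: {exc}") from exc
    else:
        raise FormatError(f"unsupported image format {suffix!r}: {path}")
    return Frame(pixels=_to_uint8(arr), index=index, source_name=path.name)


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return np.floor(arr.astype(np.float64) * (255.0 / 65535.0) + 0.5).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return np.floor(arr.astype(np.float64) * (255.0 / info.max) + 0.5).astype(np.uint8)
    raise FormatError(f"unsupported pixel dtype {arr.dtype}")


def write_image(frame_or_pixels: Frame | np.ndarray, path: str | Path) -> None:
    """Write a frame (or raw uint8 array) losslessly as PNG/TIFF."""
    px = frame_or_pixels.pixels if isinstance(frame_or_pixels, Frame) else frame_or_pixels
    px = np.asarray(px, dtype=np.uint8)
    path = Path(path)
    try:
        if path.suffix.lower() in _TIFF_SUFFIXES:
            tifffile.imwrite(path, px)
        else:
            Image.fromarray(px).save(path)
    except OSError as exc:
        raise ImageIOError(f"cannot write image: {path}: {exc}") from exc


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as a {0, 255} PNG."""
    mask = np.asarray(mask)
    write_image((mask > 0).astype(np.uint8) * 255, path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG back to a {0, 1} uint8 array."""
    frame = read_image(path)
    px = frame.pixels
    if px.ndim == 3:
        px = px[:, :, 0]
    return (px > 127).astype(np.uint8)


# ---------------------------------------------------------------------------
# VIA annotations


def read_via_annotations(path: str | Path, image_name: str) -> list[PolygonAnnotation]:
    """Parse a VIA JSON export and return the polygons recorded for one image.

    Both circulating dialects are accepted: the full project file (regions
    under the ``_via_img_metadata`` key) and the plain region export (a
    top-level dict keyed by ``filename + size``). Rectangles become their
    4 corners; circles and ellipses are approximated by 32-gons. An image
    name absent from the file yields an empty list.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except FileNotFoundError:
        raise ImageIOError(f"cannot read annotation file: {path}") from None
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed VIA JSON: {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise FormatError(f"malformed VIA JSON (expected object): {path}")

    metadata = payload.get("_via_img_metadata", payload)
    annotations: list[PolygonAnnotation] = []
    for entry in metadata.values():
        if not isinstance(entry, dict) or entry.get("filename") != image_name:
            continue
        for region in entry.get("regions", []):
            poly = _region_to_polygon(region)
            if poly is not None:
                annotations.append(poly)
    return annotations


def _region_to_polygon(region: dict) -> PolygonAnnotation | None:
    shape = region.get("shape_attributes", {})
    attrs = region.get("region_attributes", {})
    label = next((str(v) for v in attrs.values() if isinstance(v, str) and v), "cell")
    name = shape.get("name")
    if name in ("polygon", "polyline"):
        verts = tuple(zip(shape["all_points_x"], shape["all_points_y"]))
    elif name == "rect":
        x, y = shape["x"], shape["y"]
        w, h = shape["width"], shape["height"]
        verts = ((x, y), (x + w, y), (x + w, y + h), (x, y + h))
    elif name in ("circle", "ellipse"):
        cx, cy = shape["cx"], shape["cy"]
        rx = shape.get("rx", shape.get("r"))
        ry = shape.get("ry", shape.get("r"))
        rot = math.radians(shape.get("theta", 0.0))
        ts = np.linspace(0.0, 2.0 * math.pi, 32, endpoint=False)
        xs = cx + rx * np.cos(ts) * math.cos(rot) - ry * np.sin(ts) * math.sin(rot)
        ys = cy + rx * np.cos(ts) * math.sin(rot) + ry * np.sin(ts) * math.cos(rot)
        verts = tuple(zip(xs, ys))
    else:
        return None
    return PolygonAnnotation(vertices=verts, label=label)


def rasterize_polygons(
    annotations: Iterable[PolygonAnnotation], height: int, width: int
) -> np.ndarray:
    """Rasterize the union of filled polygons onto a binary mask.

    Pixel-inclusion rule: a pixel is foreground iff its center (integer
    coordinate (x, y)) lies inside or on the boundary of any polygon.
    """
    if height < 1 or width < 1:
        raise ValidationError("mask dimensions must be >= 1")
    mask = np.zeros((height, width), dtype=np.uint8)
    for ann in annotations:
        if len(ann.vertices) < 3:
            raise ValidationError("cannot rasterize a polygon with < 3 vertices")
        poly = shapely.Polygon(ann.vertices)
        x0, y0, x1, y1 = poly.bounds
        c0 = max(0, math.floor(x0))
        c1 = min(width - 1, math.ceil(x1))
        r0 = max(0, math.floor(y0))
        r1 = min(height - 1, math.ceil(y1))
        if c0 > c1 or r0 > r1:
            continue
        cols = np.arange(c0, c1 + 1)
        rows = np.arange(r0, r1 + 1)
        xx, yy = np.meshgrid(cols, rows)
        # intersects == inside-or-on-boundary for points
        inside = shapely.intersects_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
        mask[r0 : r1 + 1, c0 : c1 + 1] |= inside.astype(np.uint8)
    return mask


# ---------------------------------------------------------------------------
# Trace CSV


def write_trace(trace: ExperimentTrace, path: str | Path) -> None:
    """Write a trace as CSV (header ``frame,filename,cv,threshold,percent_cells``)."""
    if len(trace) == 0:
        raise ValidationError("refusing to write an empty trace")
    df = trace.to_dataframe()
    try:
        df.to_csv(path, index=False, float_format="%.8g")
    except OSError as exc:
        raise ImageIOError(f"cannot write trace: {path}: {exc}") from exc


def read_trace(path: str | Path) -> ExperimentTrace:
    """Read a trace CSV written by :func:`write_trace`."""
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise ImageIOError(f"cannot read trace: {path}") from None
    trace = ExperimentTrace()
    for rec in df.itertuples(index=False):
        trace.append(
            TraceRow(
                frame=int(rec.frame),
                filename=str(rec.filename),
                cv=float(rec.cv),
                threshold=int(rec.threshold),
                percent_cells=float(rec.percent_cells),
            )
        )
    return trace


def sorted_image_paths(directory: str | Path) -> list[Path]:
    """Image files in a directory, natural-sorted by filename."""
    directory = Path(directory)
    paths = [
        p
        for p in directory.iterdir()
        if p.suffix.lower() in (_PIL_SUFFIXES | _TIFF_SUFFIXES) and p.is_file()
    ]
    return sorted(paths, key=_natural_key)


def _natural_key(path: Path) -> tuple:
    import re

    parts = re.split(r"(\d+)", path.name)
    return tuple(int(p) if p.isdigit() else p for p in parts)
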
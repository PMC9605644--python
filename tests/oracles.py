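"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain loops over pixels or
vertices, sharing no code path with the library implementation.
"""

from __future__ import annotations

import numpy as np


def point_in_polygon(x: float, y: float, vertices) -> bool:
    """Ray casting with an explicit on-segment check; boundary counts inside."""
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # on-segment: collinear and within the bounding box
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12:
            if min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 and (
                min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12
            ):
                return True
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < x_cross:
                inside = not inside
    return inside


def rasterize(vertices_list, height: int, width: int) -> np.ndarray:
    mask = np.zeros((height, width), dtype=np.uint8)
    for r in range(height):
        for c in range(width):
            if any(point_in_polygon(c, r, verts) for verts in vertices_list):
                mask[r, c] = 1
    return mask


def global_hist_equalize(gray: np.ndarray) -> np.ndarray:
    """Classic histogram equalization by per-pixel rank counting."""
    flat = gray.ravel()
    n = flat.size
    out = np.empty_like(flat)
    for i, v in enumerate(flat):
        out[i] = int(np.floor(255.0 * np.count_nonzero(flat <= v) / n + 0.5))
    return out.reshape(gray.shape)


def _reflect_index(i: int, n: int) -> int:
    # scipy's "reflect" mode: (d c b a | a b c d | d c b a)
    period = 2 * n
    i = i % period
    if i < 0:
        i += period
    return i if i < n else period - 1 - i


def window_values(img: np.ndarray, r: int, c: int, half_h: int, half_w: int):
    h, w = img.shape
    vals = []
    for dr in range(-half_h, half_h + 1):
        for dc in range(-half_w, half_w + 1):
            vals.append(img[_reflect_index(r + dr, h), _reflect_index(c + dc, w)])
    return vals


def morphological_gradient(img: np.ndarray, size: int) -> np.ndarray:
    half = size // 2
    out = np.zeros(img.shape, dtype=np.int64)
    h, w = img.shape
    for r in range(h):
        for c in range(w):
            vals = window_values(img, r, c, half, half)
            out[r, c] = int(max(vals)) - int(min(vals))
    return out


def binary_dilation(mask: np.ndarray, size: int) -> np.ndarray:
    """Square-SE dilation; outside the image counts as background."""
    half = size // 2
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            hit = False
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                        hit = True
            out[r, c] = 1 if hit else 0
    return out


def binary_erosion(mask: np.ndarray, size: int) -> np.ndarray:
    """Square-SE erosion; outside the image counts as foreground."""
    half = size // 2
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            ok = True
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc]:
                        ok = False
            out[r, c] = 1 if ok else 0
    return out


def binary_closing(mask: np.ndarray, size: int) -> np.ndarray:
    return binary_erosion(binary_dilation(mask, size), size)


def gaussian_local_mean(img: np.ndarray, block: int) -> np.ndarray:
    """Gaussian-weighted local mean, sd = block/6, truncated at the block."""
    sigma = block / 6.0
    half = (block - 1) // 2
    offs = np.arange(-half, half + 1)
    w1 = np.exp(-0.5 * (offs / sigma) ** 2)
    w1 = w1 / w1.sum()
    h, w = img.shape
    out = np.zeros(img.shape, dtype=np.float64)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for i, dr in enumerate(offs):
                for j, dc in enumerate(offs):
                    acc += (
                        w1[i]
                        * w1[j]
                        * img[_reflect_index(r + dr, h), _reflect_index(c + dc, w)]
                    )
            out[r, c] = acc
    return out


def ols_grid_search(xs, ys, m_range=(-10.0, 10.0), b_range=(-10.0, 10.0)):
    """Minimize squared error by coarse grid + Nelder-Mead polish.

    The squared-error surface is an elongated quadratic valley in (m, b);
    a pure axis-aligned grid refinement converges too slowly along the
    valley, so a derivative-free simplex search finishes the job. No
    normal equations are used anywhere.
    """
    from scipy.optimize import minimize

    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)

    def sse(p):
        return float(((ys - (p[0] * xs + p[1])) ** 2).sum())

    ms = np.linspace(*m_range, 41)
    bs = np.linspace(*b_range, 41)
    errs = ((ys[None, None, :] - (ms[:, None, None] * xs + bs[None, :, None])) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmin(errs), errs.shape)
    res = minimize(
        sse, x0=[ms[i], bs[j]], method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 10_000},
    )
    return float(res.x[0]), float(res.x[1])
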
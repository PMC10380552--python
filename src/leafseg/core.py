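"""Shared raster primitives: scans, contours, tiles, connectivity, units.

Conventions used throughout the package:

* coordinates are ``(row, col)``, 0-based, origin at the top-left;
* binary masks are boolean numpy arrays, foreground ``True`` (written to
  disk as single-channel PNGs with 0/255);
* contours derived from masks are stored counter-clockwise (as displayed,
  with the row axis pointing down);
* connectivity defaults to 8, which is what makes one-pixel-wide diagonal
  vein runs a single component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

MM_PER_INCH = 25.4

_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


class NoObjectFoundError(ValueError):
    """Raised when a rough segmentation finds no foreground object."""


class MultipleComponentsError(ValueError):
    """Raised when a single-component mask is required but not given."""


@dataclass
class LeafScan:
    """An RGB leaf scan plus the resolution metadata needed for units."""

    pixels: np.ndarray  # (H, W, 3) uint8 or float in [0, 1]
    dpi: float = 300.0
    sample_id: str = ""

    def __post_init__(self):
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        if self.pixels.size == 0:
            raise ValueError("empty raster")

    def as_float(self) -> np.ndarray:
        px = self.pixels
        if px.dtype == np.uint8:
            return px.astype(np.float32) / 255.0
        return px.astype(np.float32)


@dataclass
class Contour:
    points: np.ndarray  # (N, 2) int array of (row, col)
    closed: bool = True

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Tile:
    pixels: np.ndarray  # (S, S, C) float32 in [0, 1]
    center: tuple[int, int]
    pad_mask: np.ndarray = field(default=None)  # (S, S) bool, True = padded


def px_to_physical(length_px: float, dpi: float) -> float:
    """Convert a pixel length to millimetres (one pixel spans 25.4/dpi mm)."""
    if dpi <= 0:
        raise ValueError("dpi must be positive")
    if np.any(np.asarray(length_px) < 0):
        raise ValueError("length must be non-negative")
    return length_px * MM_PER_INCH / dpi


def rough_foreground(scan: LeafScan) -> np.ndarray:
    """Otsu-threshold rough segmentation: darker-than-threshold pixels,
    largest connected component kept.

    On white-background scans this grabs the leaf together with its petiole
    (plus shading artifacts), which is all the tracer needs for a starting
    location.
    """
    gray = scan.as_float().mean(axis=2)
    thr = threshold_otsu(gray)
    fg = gray < thr
    if not fg.any():
        raise NoObjectFoundError("no object found by automatic thresholding")
    count, labels = connected_components(fg, connectivity=8)
    if count == 0:
        raise NoObjectFoundError("no object found by automatic thresholding")
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(sizes.argmax()) + 1)


def extract_tile(image: np.ndarray, center: tuple[int, int], size: int,
                 pad_value=1.0) -> Tile:
    """Crop a ``size x size`` tile with the center pixel at ``(S/2, S/2)``.

    Out-of-bounds pixels are filled with ``pad_value`` (scanner white by
    default) and flagged in ``pad_mask``. uint8 inputs are rescaled to
    [0, 1]; float inputs are assumed to already be normalized.
    """
    if size % 2:
        raise ValueError("tile size must be even")
    h, w = image.shape[:2]
    r, c = int(center[0]), int(center[1])
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"tile center {center} outside image bounds")
    if image.dtype == np.uint8:
        img = image.astype(np.float32) / 255.0
    else:
        img = np.asarray(image, dtype=np.float32)  # view when already f32
    if img.ndim == 2:
        img = img[..., None]
    nch = img.shape[2]
    half = size // 2
    r0, c0 = r - half, c - half
    pad_value = np.broadcast_to(np.asarray(pad_value, dtype=np.float32), (nch,))
    pixels = np.empty((size, size, nch), dtype=np.float32)
    pixels[...] = pad_value
    pad_mask = np.ones((size, size), dtype=bool)
    sr0, sr1 = max(r0, 0), min(r0 + size, h)
    sc0, sc1 = max(c0, 0), min(c0 + size, w)
    if sr0 < sr1 and sc0 < sc1:
        tr0, tc0 = sr0 - r0, sc0 - c0
        pixels[tr0:tr0 + (sr1 - sr0), tc0:tc0 + (sc1 - sc0)] = img[sr0:sr1, sc0:sc1]
        pad_mask[tr0:tr0 + (sr1 - sr0), tc0:tc0 + (sc1 - sc0)] = False
    return Tile(pixels=pixels, center=(r, c), pad_mask=pad_mask)


def connected_components(mask: np.ndarray, connectivity: int = 8):
    """Label foreground components; returns ``(count, labels)``."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    labels, count = ndimage.label(mask, structure=struct)
    return count, labels


# Moore neighborhood in clockwise order starting from "west".
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1),
          (0, 1), (1, 1), (1, 0), (1, -1)]
_MOORE_INDEX = {d: i for i, d in enumerate(_MOORE)}


def _signed_area(points: np.ndarray) -> float:
    r = points[:, 0].astype(float)
    c = points[:, 1].astype(float)
    # Shoelace with x = col, y = -row so that "counter-clockwise as
    # displayed" corresponds to positive area.
    return 0.5 * float(np.sum(c * -np.roll(r, -1) - np.roll(c, -1) * -r))


def mask_to_contour(mask: np.ndarray) -> Contour:
    """Ordered closed walk of the outer boundary (Moore neighbor tracing).

    Requires a single 8-connected component; consecutive points are within
    Chebyshev distance 1 and the stored orientation is counter-clockwise.
    """
    count, _ = connected_components(mask, connectivity=8)
    if count == 0:
        raise NoObjectFoundError("empty mask has no contour")
    if count > 1:
        raise MultipleComponentsError(
            f"mask has {count} components; select one before tracing")
    rows, cols = np.nonzero(mask)
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))
    if mask.sum() == 1:
        return Contour(points=np.array([start]), closed=True)

    h, w = mask.shape

    def fg(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    # Backtrack starts west of the start pixel (background by construction
    # of the lexicographic minimum). The walk is a deterministic map on
    # (pixel, backtrack) states, so the first repeated state closes the
    # boundary cycle exactly.
    cur = start
    back_dir = (0, -1)
    points = [start]
    seen = {(cur, back_dir): 0}
    while True:
        k0 = _MOORE_INDEX[back_dir]
        nxt = None
        for i in range(1, 9):
            d = _MOORE[(k0 + i) % 8]
            cand = (cur[0] + d[0], cur[1] + d[1])
            if fg(cand):
                nxt = cand
                prev_d = _MOORE[(k0 + i - 1) % 8]
                back_dir = (prev_d[0] + cur[0] - nxt[0],
                            prev_d[1] + cur[1] - nxt[1])
                break
        if nxt is None:  # isolated pixel (handled above) — safety net
            break
        state = (nxt, back_dir)
        if state in seen:
            points = points[seen[state]:]
            break
        seen[state] = len(points)
        points.append(nxt)
        cur = nxt
    pts = np.array(points, dtype=np.int64)
    if _signed_area(pts) < 0:
        pts = pts[::-1].copy()
    return Contour(points=pts, closed=True)


def fill_contour(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Fill a closed contour: boundary pixels plus all interior pixels."""
    if not contour.closed:
        raise ValueError("cannot fill an open contour")
    from skimage.draw import line

    mask = np.zeros(shape, dtype=bool)
    pts = np.asarray(contour.points)
    n = len(pts)
    if n == 0:
        return mask
    for i in range(n):
        r0, c0 = pts[i]
        r1, c1 = pts[(i + 1) % n]
        rr, cc = line(int(r0), int(c0), int(r1), int(c1))
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[ok], cc[ok]] = True
    return ndimage.binary_fill_holes(mask)


def save_mask(path, mask: np.ndarray) -> None:
    from PIL import Image

    Image.fromarray((mask.astype(np.uint8)) * 255).save(path)


def load_mask(path) -> np.ndarray:
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("L"))
    return arr >= 128


def save_image(path, image: np.ndarray) -> None:
    from PIL import Image

    if image.dtype != np.uint8:
        image = np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(image).save(path)


def load_image(path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path).convert("RGB"))
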
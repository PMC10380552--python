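"""Trait extraction from leaf, vein and petiole masks.

Leaf morphology (area, perimeter, circularity, solidity, mean color), vein
architecture (skeleton length, local diameters from the Euclidean distance
transform, diameter classes, vein density) and petiole geometry (rotated
bounding-rectangle length, central-diameter width, area, solid-of-revolution
volume), all converted to physical units from the scan DPI.

Vein diameter classes follow the convention of (a) < 0.25 mm,
(b) 0.25-0.80 mm and (c) >= 0.80 mm, approximating third-, second- and
first-order veins; class (b) owns its lower edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.morphology import convex_hull_image, skeletonize

from .core import (LeafScan, connected_components, mask_to_contour,
                   px_to_physical)

__all__ = [
    "TraitRecord", "NoPetioleError", "leaf_morphology", "vein_traits",
    "petiole_extract", "petiole_measurements", "extract_traits",
    "skeleton_length", "CLASS_EDGES_MM",
]

CLASS_EDGES_MM = (0.25, 0.80)


class NoPetioleError(ValueError):
    """Raised when no vein pixels exist outside the leaf segmentation."""


@dataclass
class TraitRecord:
    """One row of named measurements in physical units for one sample.

    ``None`` means missing (e.g. petiole traits when no petiole was found);
    missing values serialize to empty CSV cells.
    """

    sample_id: str = ""
    leaf_area_cm2: float | None = None
    leaf_perimeter_cm: float | None = None
    circularity: float | None = None
    solidity: float | None = None
    mean_red: float | None = None
    mean_green: float | None = None
    mean_blue: float | None = None
    mean_hue: float | None = None
    mean_saturation: float | None = None
    mean_brightness: float | None = None
    vein_total_length_mm: float | None = None
    vein_mean_diameter_mm: float | None = None
    vein_area_mm2: float | None = None
    vein_length_class_a_mm: float | None = None
    vein_length_class_b_mm: float | None = None
    vein_length_class_c_mm: float | None = None
    vein_area_class_a_mm2: float | None = None
    vein_area_class_b_mm2: float | None = None
    vein_area_class_c_mm2: float | None = None
    vein_density: float | None = None
    petiole_length_mm: float | None = None
    petiole_width_mm: float | None = None
    petiole_area_mm2: float | None = None
    petiole_volume_mm3: float | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
          (0, 1), (1, -1), (1, 0), (1, 1)]
# Each undirected edge counted once: scan half of the directions.
_HALF_NEIGH = [(0, 1), (1, -1), (1, 0), (1, 1)]


def _pixel_length_weights(skel: np.ndarray) -> np.ndarray:
    """Per-pixel share of skeleton arc length.

    Every pair of 8-adjacent skeleton pixels contributes an edge of length
    1 or sqrt(2), split evenly between its two endpoints, so the weights
    sum exactly to the total skeleton length.
    """
    w = np.zeros(skel.shape, dtype=np.float64)
    idx = np.argwhere(skel)
    lookup = skel.astype(bool)
    h, ww = skel.shape
    for dr, dc in _HALF_NEIGH:
        length = np.sqrt(dr * dr + dc * dc)
        rr = idx[:, 0] + dr
        cc = idx[:, 1] + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < ww)
        hit = ok.copy()
        hit[ok] = lookup[rr[ok], cc[ok]]
        half = 0.5 * length
        np.add.at(w, (idx[hit, 0], idx[hit, 1]), half)
        np.add.at(w, (rr[hit], cc[hit]), half)
    return w


def skeleton_length(skel: np.ndarray) -> float:
    """Arc length of a skeleton: sum of 8-adjacency edges (1 or sqrt 2)."""
    return float(_pixel_length_weights(skel).sum())


def _contour_perimeter(mask: np.ndarray) -> float:
    pts = mask_to_contour(mask).points
    if len(pts) < 2:
        return float(len(pts))
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def leaf_morphology(leaf_mask: np.ndarray, scan: LeafScan) -> TraitRecord:
    """Area, perimeter, circularity, solidity and mean color of the lamina.

    Perimeter is the boundary-walk arc length (sqrt 2 for diagonal steps);
    color means are taken over leaf-mask pixels only, petiole excluded.
    """
    if not leaf_mask.any():
        raise ValueError("empty leaf mask")
    count, _ = connected_components(leaf_mask)
    if count != 1:
        raise ValueError(f"leaf mask must be a single component, got {count}")
    mm = px_to_physical(1.0, scan.dpi)
    area_px = float(leaf_mask.sum())
    perim_px = _contour_perimeter(leaf_mask)
    area_cm2 = area_px * mm * mm / 100.0
    perim_cm = perim_px * mm / 10.0
    circ = 4.0 * np.pi * area_px / perim_px ** 2 if perim_px > 0 else 1.0
    hull = convex_hull_image(leaf_mask)
    solidity = area_px / float(hull.sum())
    img = scan.as_float()
    rgb = img[leaf_mask]
    hsv = rgb2hsv(rgb[None, :, :])[0]
    return TraitRecord(
        sample_id=scan.sample_id,
        leaf_area_cm2=area_cm2, leaf_perimeter_cm=perim_cm,
        circularity=float(circ), solidity=float(solidity),
        mean_red=float(rgb[:, 0].mean()), mean_green=float(rgb[:, 1].mean()),
        mean_blue=float(rgb[:, 2].mean()), mean_hue=float(hsv[:, 0].mean()),
        mean_saturation=float(hsv[:, 1].mean()),
        mean_brightness=float(hsv[:, 2].mean()))


def vein_traits(vein_mask: np.ndarray, leaf_mask: np.ndarray,
                dpi: float) -> TraitRecord:
    """Vein architecture traits from the veins inside the leaf body.

    The mask is skeletonized; length comes from skeleton adjacency arcs and
    the local diameter at each skeleton pixel is twice the Euclidean
    distance transform. Diameter classes partition the skeleton pixels, so
    per-class lengths sum exactly to the total.
    """
    if vein_mask.shape != leaf_mask.shape:
        raise ValueError("mask shapes differ")
    mm = px_to_physical(1.0, dpi)
    vin = vein_mask & leaf_mask
    rec = TraitRecord()
    leaf_px = float(leaf_mask.sum())
    if not vin.any():
        rec.vein_total_length_mm = 0.0
        rec.vein_mean_diameter_mm = 0.0
        rec.vein_area_mm2 = 0.0
        for cls in "abc":
            setattr(rec, f"vein_length_class_{cls}_mm", 0.0)
            setattr(rec, f"vein_area_class_{cls}_mm2", 0.0)
        rec.vein_density = 0.0
        return rec
    skel = skeletonize(vin)
    edt = ndimage.distance_transform_edt(vin)
    weights = _pixel_length_weights(skel)
    sk_px = skel & (weights > 0)
    # Isolated single-pixel skeletons still carry their own length of 1.
    lone = skel & (weights == 0)
    weights[lone] = 1.0
    diam_mm = 2.0 * edt * mm
    d = diam_mm[skel]
    wt = weights[skel]
    total_len_mm = float(wt.sum()) * mm
    mean_diam = float(d.mean()) if d.size else 0.0
    area_mm2 = float(vin.sum()) * mm * mm
    lo, hi = CLASS_EDGES_MM
    cls_a = d < lo
    cls_b = (d >= lo) & (d < hi)
    cls_c = d >= hi
    len_cls = [float(wt[c].sum()) * mm for c in (cls_a, cls_b, cls_c)]
    # Area split in proportion to local cylinder area (diameter x length).
    dw = d * wt
    denom = float(dw.sum())
    if denom > 0:
        area_cls = [area_mm2 * float(dw[c].sum()) / denom
                    for c in (cls_a, cls_b, cls_c)]
    else:
        area_cls = [0.0, 0.0, 0.0]
    rec.vein_total_length_mm = total_len_mm
    rec.vein_mean_diameter_mm = mean_diam
    rec.vein_area_mm2 = area_mm2
    (rec.vein_length_class_a_mm, rec.vein_length_class_b_mm,
     rec.vein_length_class_c_mm) = len_cls
    (rec.vein_area_class_a_mm2, rec.vein_area_class_b_mm2,
     rec.vein_area_class_c_mm2) = area_cls
    rec.vein_density = float(vin.sum()) / leaf_px if leaf_px else 0.0
    return rec


def petiole_extract(vein_mask: np.ndarray,
                    leaf_mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected component of vein pixels outside the leaf."""
    outside = vein_mask & ~leaf_mask
    if not outside.any():
        raise NoPetioleError("no vein pixels outside the leaf segmentation")
    count, labels = connected_components(outside)
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(sizes.argmax()) + 1)


def _ordered_skeleton_path(skel: np.ndarray) -> np.ndarray | None:
    """Order a (near-)path skeleton from one endpoint to the other."""
    idx = {tuple(p) for p in np.argwhere(skel)}
    if not idx:
        return None
    deg = {}
    for p in idx:
        deg[p] = sum(((p[0] + dr, p[1] + dc) in idx) for dr, dc in _NEIGH)
    ends = [p for p, d in deg.items() if d == 1]
    start = min(ends) if ends else min(idx)
    path = [start]
    visited = {start}
    cur = start
    while True:
        nxt = None
        for dr, dc in _NEIGH:
            q = (cur[0] + dr, cur[1] + dc)
            if q in idx and q not in visited:
                nxt = q
                break
        if nxt is None:
            break
        path.append(nxt)
        visited.add(nxt)
        cur = nxt
    return np.array(path, dtype=int)


def petiole_measurements(petiole_mask: np.ndarray, dpi: float):
    """(length mm, width mm, area mm2, volume mm3) of a petiole mask.

    Length is the longer side of the minimum-area rotated bounding
    rectangle. Width averages twice the distance transform over the central
    20% of the medial axis (arc-length positions 0.4-0.6), matching how a
    caliper is placed at the middle of the petiole. Volume stacks local
    cylinder slices pi*(d/2)^2 along the skeleton.
    """
    if not petiole_mask.any():
        raise ValueError("empty petiole mask")
    from shapely.geometry import MultiPoint

    mm = px_to_physical(1.0, dpi)
    pts = np.argwhere(petiole_mask)
    rect = MultiPoint([(float(c), float(r)) for r, c in pts]) \
        .minimum_rotated_rectangle
    if rect.geom_type == "Polygon":
        xy = np.asarray(rect.exterior.coords)
        sides = np.hypot(*np.diff(xy, axis=0).T)
        length_px = float(sides.max())
    else:  # degenerate (line or point)
        length_px = float(rect.length)
    length_mm = (length_px + 1.0) * mm  # pixel centers -> pixel extents

    area_mm2 = float(petiole_mask.sum()) * mm * mm
    skel = skeletonize(petiole_mask)
    edt = ndimage.distance_transform_edt(petiole_mask)
    path = _ordered_skeleton_path(skel)
    width_mm = None
    volume_mm3 = None
    if path is not None and len(path) >= 2:
        steps = np.hypot(*np.diff(path, axis=0).T)
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        frac = cum / cum[-1] if cum[-1] > 0 else cum
        central = (frac >= 0.4) & (frac <= 0.6)
        if central.any():
            d_central = 2.0 * edt[path[central, 0], path[central, 1]]
            width_mm = float(d_central.mean()) * mm
        d_all = 2.0 * edt[path[:, 0], path[:, 1]] * mm
        ds = np.empty(len(path))
        ds[0] = steps[0] / 2
        ds[-1] = steps[-1] / 2
        if len(path) > 2:
            ds[1:-1] = (steps[:-1] + steps[1:]) / 2
        volume_mm3 = float((np.pi * (d_all / 2.0) ** 2 * ds * mm).sum())
    return length_mm, width_mm, area_mm2, volume_mm3


def extract_traits(scan: LeafScan, leaf_mask: np.ndarray,
                   vein_mask: np.ndarray) -> TraitRecord:
    """Full trait record for one sample from its scan and two masks."""
    rec = leaf_morphology(leaf_mask, scan)
    vt = vein_traits(vein_mask, leaf_mask, scan.dpi)
    for f in fields(TraitRecord):
        v = getattr(vt, f.name)
        if v is not None and f.name != "sample_id":
            setattr(rec, f.name, v)
    try:
        pmask = petiole_extract(vein_mask, leaf_mask)
        length, width, area, volume = petiole_measurements(pmask, scan.dpi)
        rec.petiole_length_mm = length
        rec.petiole_width_mm = width
        rec.petiole_area_mm2 = area
        rec.petiole_volume_mm3 = volume
    except NoPetioleError:
        pass
    return rec
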
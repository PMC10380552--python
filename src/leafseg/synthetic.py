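"""Seedable synthetic leaf-scan generator with exact ground truth.

Emulates the relevant properties of high-resolution flatbed leaf scans: a
near-white scanner background, a single serrated green lamina with
heterogeneous hue and brightness, one connected branching vein tree whose
local diameters taper from the midrib outwards, a petiole protruding below
the lamina, and optional scan artifacts (fold lines, a vertical white
stripe from a failing scanner pixel, dust specks, blur patches).

The lamina outline is a low-order random Fourier perturbation of an ellipse
plus a signed triangular serration term, evaluated in polar coordinates
around the lamina center, so every pixel test and every "true" trait is
computed from the same analytic curve. Artifacts perturb only the rendered
image; ground-truth masks are always clean. All randomness flows from the
single seed in :class:`LeafGenParams` through spawned generators, so equal
parameters give bit-identical samples and increasing ``vein_branch_depth``
only ever adds vein segments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk

from .core import MM_PER_INCH

ARTIFACTS = ("fold", "white_stripe", "dust", "blur")


@dataclass(frozen=True)
class LeafGenParams:
    """Generative parameters for one synthetic leaf scan.

    Defaults correspond to a full 300-DPI flatbed scan (3510 x 2550 px)
    of a mature poplar-like leaf. ``genotype_effect`` is a dimensionless
    additive shift on the vein-density driver trait used by the population
    generator.
    """

    seed: int = 0
    canvas_size: tuple[int, int] = (3510, 2550)
    lamina_scale: float = 900.0          # semi-axis along rows, px
    aspect: float = 0.72                 # semi-minor / semi-major
    fourier_amplitude: float = 0.03      # relative low-order shape noise
    serration_amplitude: float = 8.0     # px, signed triangular term
    serration_count: int = 80            # teeth around the outline
    vein_branch_depth: int = 3           # 0 = midrib only
    vein_base_width: float = 12.0        # midrib diameter at the base, px
    vein_contrast: float = 0.22          # vein minus lamina brightness
    petiole_length: float = 470.0        # px of arc length
    petiole_width: float = 24.0          # px diameter
    artifact_flags: frozenset = frozenset()
    genotype_effect: float = 0.0
    dpi: float = 300.0
    margin: int = 32                     # required clearance to the canvas edge


@dataclass
class SyntheticSample:
    image: np.ndarray            # (H, W, 3) float32 in [0, 1]
    leaf_mask: np.ndarray        # lamina only (no petiole)
    vein_mask: np.ndarray        # vein tree inside the leaf + petiole outside
    petiole_mask: np.ndarray
    params: LeafGenParams
    true_traits: dict = field(default_factory=dict)
    sample_id: str = ""
    genotype_id: str = ""


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


def _resample_polyline(pts: np.ndarray, spacing: float = 0.5):
    """Dense arc-length resampling; returns positions and arc fractions."""
    seg = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        return pts[:1], np.zeros(1)
    s = np.linspace(0.0, total, max(int(total / spacing) + 1, 2))
    r = np.interp(s, cum, pts[:, 0])
    c = np.interp(s, cum, pts[:, 1])
    return np.stack([r, c], axis=1), s / total


def _stamp_polyline(mask: np.ndarray, pts: np.ndarray, w0: float, w1: float):
    """Rasterize a polyline with linearly tapering width (stamped disks)."""
    samples, frac = _resample_polyline(pts)
    widths = w0 + (w1 - w0) * frac
    for (r, c), wd in zip(samples, widths):
        rr, cc = draw_disk((r, c), max(wd / 2.0, 0.7), shape=mask.shape)
        mask[rr, cc] = True


class _LaminaShape:
    """Analytic polar outline r(theta) about the lamina center.

    theta = 0 points down (toward the petiole attachment), increasing
    toward the positive column axis.
    """

    def __init__(self, params: LeafGenParams, rng: np.random.Generator):
        a = params.lamina_scale
        b = params.aspect * a
        self.a, self.b = a, b
        orders = np.array([2, 3, 4])
        self.amp = rng.uniform(0.0, params.fourier_amplitude, size=3)
        self.phase = rng.uniform(0.0, 2 * np.pi, size=3)
        self.orders = orders
        self.serr_amp = params.serration_amplitude
        self.serr_count = params.serration_count

    def radius(self, theta: np.ndarray) -> np.ndarray:
        a, b = self.a, self.b
        base = a * b / np.sqrt((b * np.cos(theta)) ** 2
                               + (a * np.sin(theta)) ** 2)
        mod = 1.0 + sum(A * np.cos(k * theta + p) for A, k, p in
                        zip(self.amp, self.orders, self.phase))
        r = base * mod
        if self.serr_amp > 0 and self.serr_count > 0:
            phase = (self.serr_count * theta / (2 * np.pi)) % 1.0
            tri = 4.0 * np.abs(phase - 0.5) - 1.0
            r = r + self.serr_amp * tri
        return r

    def max_radius(self) -> float:
        th = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        return float(self.radius(th).max())

    def extents(self) -> tuple[float, float, float]:
        """(rows up, rows down, cols either side) reach from the center."""
        th = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        r = self.radius(th)
        rows = r * np.cos(th)   # theta = 0 points down (toward petiole)
        cols = r * np.sin(th)
        return (float(-rows.min()), float(rows.max()),
                float(np.abs(cols).max()))

    def area_perimeter(self) -> tuple[float, float]:
        th = np.linspace(0, 2 * np.pi, 8192, endpoint=False)
        r = self.radius(th)
        dth = 2 * np.pi / len(th)
        area = 0.5 * float((r ** 2).sum()) * dth
        dr = np.gradient(r, dth)
        perim = float(np.sqrt(r ** 2 + dr ** 2).sum()) * dth
        return area, perim


def _value_noise(shape: tuple[int, int], rng: np.random.Generator,
                 cells: int = 9) -> np.ndarray:
    """Smooth value noise in [-1, 1] from an upsampled random grid."""
    grid = rng.standard_normal((cells, cells))
    zoom = (shape[0] / cells, shape[1] / cells)
    n = ndimage.zoom(grid, zoom, order=3)[:shape[0], :shape[1]]
    m = np.abs(n).max()
    return n / m if m > 0 else n


def _spawn_children(shape: _LaminaShape, center: np.ndarray,
                    parent_pts: np.ndarray, parent_w0: float,
                    parent_w1: float, rng: np.random.Generator,
                    n_pairs: int) -> list[tuple[np.ndarray, float, float]]:
    """Spawn one level of child vein polylines off a parent polyline."""

    def inside_frac(p: np.ndarray) -> float:
        d = p - center
        rho = np.hypot(*d)
        theta = np.arctan2(d[1], d[0])
        return rho / max(shape.radius(np.array([theta]))[0], 1e-9)

    out = []
    samples, _ = _resample_polyline(parent_pts, spacing=2.0)
    ts = np.linspace(0.18, 0.85, n_pairs) + rng.uniform(-0.03, 0.03, n_pairs)
    ts = np.clip(ts, 0.05, 0.95)
    for t in ts:
        idx = int(t * (len(samples) - 1))
        p0 = samples[idx]
        tangent = samples[min(idx + 1, len(samples) - 1)] - samples[max(idx - 1, 0)]
        tn = tangent / max(np.hypot(*tangent), 1e-9)
        for side in (-1.0, 1.0):
            ang = np.deg2rad(rng.uniform(45.0, 65.0)) * side
            ca, sa = np.cos(ang), np.sin(ang)
            d = np.array([tn[0] * ca - tn[1] * sa, tn[0] * sa + tn[1] * ca])
            bend = rng.uniform(-1.0, 1.0)
            # Bisect for the analytic boundary along direction d.
            lo, hi = 0.0, 2.2 * shape.a
            for _ in range(20):
                mid = 0.5 * (lo + hi)
                if inside_frac(p0 + mid * d) < 1.0:
                    lo = mid
                else:
                    hi = mid
            length = 0.78 * lo
            if length < 4.0:
                continue
            wid0 = max(0.55 * (parent_w0 + (parent_w1 - parent_w0) * t), 1.4)
            wid1 = max(0.25 * wid0, 1.0)
            normal = np.array([-d[1], d[0]])
            pts = np.stack([p0,
                            p0 + 0.5 * length * d + 0.15 * length * bend * normal,
                            p0 + length * d])
            out.append((pts, wid0, wid1))
    return out


def generate_leaf(params: LeafGenParams) -> SyntheticSample:
    """Render one synthetic leaf scan with exact ground-truth masks."""
    h, w = params.canvas_size
    if not 0 <= params.vein_branch_depth <= 5:
        raise ValueError("vein_branch_depth must be in [0, 5]")
    ss = np.random.SeedSequence(params.seed)
    # Fixed spawn order so each sub-generator is independent of unrelated
    # parameters (e.g. deeper vein trees reuse identical shallow levels).
    (ss_shape, ss_midrib, *ss_levels, ss_color, ss_art) = ss.spawn(3 + 6)
    rng_shape = np.random.default_rng(ss_shape)

    shape = _LaminaShape(params, rng_shape)
    up, down, sideways = shape.extents()
    cx = w / 2.0
    cy = (h - params.petiole_length) / 2.0
    if (cy - up < params.margin or cx - sideways < params.margin
            or cx + sideways > w - params.margin
            or cy + down + params.petiole_length > h - params.margin):
        raise ValueError(
            "canvas too small for lamina_scale/petiole_length with the "
            "required margin")
    center = np.array([cy, cx])

    rows, cols = np.mgrid[0:h, 0:w]
    dr = rows - cy
    dc = cols - cx
    rho = np.hypot(dr, dc)
    theta = np.arctan2(dc, dr)
    leaf_mask = rho <= shape.radius(theta)

    # --- vein tree -------------------------------------------------------
    rng_mid = np.random.default_rng(ss_midrib)
    base_pt = np.array([cy + shape.radius(np.array([0.0]))[0] * 0.985, cx])
    apex_pt = np.array([cy - shape.radius(np.array([np.pi]))[0] * 0.92, cx])
    t = np.linspace(0.0, 1.0, 24)
    wiggle = 0.02 * shape.a * np.sin(np.pi * t * rng_mid.uniform(1.5, 2.5)
                                     + rng_mid.uniform(0, 2 * np.pi))
    midrib = (base_pt[None, :] * (1 - t[:, None])
              + apex_pt[None, :] * t[:, None])
    midrib[:, 1] += wiggle * np.sin(np.pi * t)  # pinned at both ends
    w0 = params.vein_base_width
    w1 = max(0.18 * w0, 1.0)
    # Breadth-first branch growth with one generator per level: level k is
    # drawn identically whatever the total depth, so deeper trees are strict
    # supersets of shallower ones (skeleton length grows monotonically).
    polylines = [(midrib, w0, w1)]
    parents = polylines
    for level in range(params.vein_branch_depth):
        rng_lvl = np.random.default_rng(ss_levels[level])
        n_pairs = max(5 - 2 * level, 2)
        children = []
        for pts, a0, a1 in parents:
            children += _spawn_children(shape, center, pts, a0, a1,
                                        rng_lvl, n_pairs)
        polylines = polylines + children
        parents = children

    vein_raster = np.zeros((h, w), dtype=bool)
    for pts, a0, a1 in polylines:
        _stamp_polyline(vein_raster, pts, a0, a1)

    # --- petiole ---------------------------------------------------------
    drift = rng_mid.uniform(-0.12, 0.12) * params.petiole_length
    pet_pts = np.stack([
        base_pt - np.array([2.0, 0.0]),  # overlap the lamina attachment
        base_pt + np.array([0.5 * params.petiole_length, 0.5 * drift]),
        base_pt + np.array([params.petiole_length, drift]),
    ])
    pet_raster = np.zeros((h, w), dtype=bool)
    _stamp_polyline(pet_raster, pet_pts, params.petiole_width,
                    0.85 * params.petiole_width)
    petiole_mask = pet_raster & ~leaf_mask
    vein_mask = (vein_raster & leaf_mask) | petiole_mask

    # --- render ----------------------------------------------------------
    rng_col = np.random.default_rng(ss_color)
    image = np.empty((h, w, 3), dtype=np.float32)
    bg_noise = _value_noise((h, w), rng_col, cells=7)
    bg = np.clip(0.965 + 0.02 * bg_noise, 0.93, 1.0).astype(np.float32)
    image[...] = bg[..., None]

    lam_noise = _value_noise((h, w), rng_col, cells=11)
    base_rgb = np.array([0.33, 0.52, 0.29], dtype=np.float32)
    lam = base_rgb[None, :] * (1.0 + 0.16 * lam_noise[leaf_mask, None])
    image[leaf_mask] = np.clip(lam, 0.05, 0.85)
    vein_rgb = np.clip(base_rgb + params.vein_contrast, 0.0, 0.88)
    vein_px = vein_mask | petiole_mask
    image[vein_px] = vein_rgb[None, :] * (
        1.0 + 0.06 * lam_noise[vein_px, None])
    image = np.clip(image, 0.0, 1.0)

    image = _apply_artifacts(image, leaf_mask, params,
                             np.random.default_rng(ss_art))

    # --- analytic truth --------------------------------------------------
    area_px2, perim_px = shape.area_perimeter()
    mm = MM_PER_INCH / params.dpi
    vein_len_px = sum(_polyline_length(p) for p, _, _ in polylines)
    true_traits = {
        "leaf_area_cm2": area_px2 * mm * mm / 100.0,
        "leaf_perimeter_cm": perim_px * mm / 10.0,
        "vein_total_length_mm": vein_len_px * mm,
        "petiole_length_px": _polyline_length(pet_pts),
        "petiole_length_mm": _polyline_length(pet_pts) * mm,
        "petiole_width_mm": params.petiole_width * mm,
        "vein_density_driver": params.genotype_effect,
    }
    return SyntheticSample(image=image, leaf_mask=leaf_mask,
                           vein_mask=vein_mask, petiole_mask=petiole_mask,
                           params=params, true_traits=true_traits,
                           sample_id=f"synthetic_{params.seed}")


def _apply_artifacts(image: np.ndarray, leaf_mask: np.ndarray,
                     params: LeafGenParams,
                     rng: np.random.Generator) -> np.ndarray:
    """Perturb only the rendered image; ground-truth masks stay clean."""
    flags = set(params.artifact_flags)
    unknown = flags - set(ARTIFACTS)
    if unknown:
        raise ValueError(f"unknown artifact flags: {sorted(unknown)}")
    h, w = leaf_mask.shape
    img = image
    rows_any = np.nonzero(leaf_mask.any(axis=1))[0]
    if "fold" in flags and len(rows_any):
        # A dark crease across the lamina.
        from skimage.draw import line

        r = int(rng.uniform(rows_any[0] + 5, rows_any[-1] - 5))
        cols_r = np.nonzero(leaf_mask[r])[0]
        if len(cols_r):
            r2 = int(np.clip(r + rng.integers(-20, 20), 0, h - 1))
            rr, cc = line(r, int(cols_r[0]), r2, int(cols_r[-1]))
            for off in (-1, 0, 1):
                ro = np.clip(rr + off, 0, h - 1)
                img[ro, cc] *= 0.55
    if "white_stripe" in flags:
        c0 = int(w / 2 + rng.integers(-w // 8, w // 8))
        width = max(2, int(round(w * 0.002)))
        img[:, c0:c0 + width] = 0.985
    if "dust" in flags:
        n = 20
        rr = rng.integers(0, h, n)
        cc = rng.integers(0, w, n)
        for r, c in zip(rr, cc):
            if leaf_mask[r, c]:
                continue
            dd, cc2 = draw_disk((int(r), int(c)),
                                float(rng.uniform(1.0, 3.0)), shape=(h, w))
            img[dd, cc2] = rng.uniform(0.15, 0.4)
    if "blur" in flags and len(rows_any):
        r = int(rng.uniform(rows_any[0], rows_any[-1]))
        cols_r = np.nonzero(leaf_mask[r])[0]
        if len(cols_r):
            c = int(rng.choice(cols_r))
            rad = int(0.15 * min(h, w))
            r0, r1 = max(r - rad, 0), min(r + rad, h)
            c0, c1 = max(c - rad, 0), min(c + rad, w)
            patch = ndimage.gaussian_filter(img[r0:r1, c0:c1], (2.5, 2.5, 0))
            img[r0:r1, c0:c1] = patch
    return np.clip(img, 0.0, 1.0)


def small_leaf_params(seed: int = 0, canvas_size: tuple[int, int] = (256, 192),
                      **overrides) -> LeafGenParams:
    """Desk-scale parameters: the default leaf shrunk ~9x for fast tests.

    Relative geometry (lamina/canvas ratio, petiole proportions, vein
    widths as a fraction of lamina size) follows the full-scale defaults.
    """
    scale = canvas_size[0] / 3510.0
    base = dict(
        seed=seed,
        canvas_size=canvas_size,
        lamina_scale=900.0 * scale,
        serration_amplitude=max(8.0 * scale * 4, 0.0),  # keep teeth visible
        serration_count=32,
        vein_branch_depth=2,
        vein_base_width=max(12.0 * scale * 3, 3.0),
        petiole_length=470.0 * scale,
        petiole_width=max(24.0 * scale * 3, 5.0),
        margin=24,
    )
    base.update(overrides)
    return LeafGenParams(**base)


def generate_population(n: int, base: LeafGenParams, n_genotypes: int,
                        clones_per_genotype: int, sigma_G: float,
                        sigma_E: float, seed: int,
                        render: bool = True) -> list[SyntheticSample]:
    """Clonally replicated population with a heritable vein-density driver.

    Genotype effects are N(0, sigma_G^2); clone (environmental) noise is
    N(0, sigma_E^2). The per-sample trait is their sum, stored both as the
    ``genotype_effect`` generative parameter and in ``true_traits``. With
    ``render=False`` only parameters and analytic traits are produced,
    which is what variance-component simulations need.
    """
    if n != n_genotypes * clones_per_genotype:
        raise ValueError("n must equal n_genotypes * clones_per_genotype")
    if sigma_G < 0 or sigma_E < 0:
        raise ValueError("variance components must be non-negative")
    rng = np.random.default_rng(seed)
    g_eff = rng.normal(0.0, sigma_G, size=n_genotypes)
    samples = []
    for j in range(n_genotypes):
        for k in range(clones_per_genotype):
            e = rng.normal(0.0, sigma_E)
            trait = float(g_eff[j] + e)
            child_seed = int(rng.integers(0, 2 ** 31 - 1))
            params = dataclasses.replace(
                base, seed=child_seed, genotype_effect=trait,
                # The driver nudges vein geometry so rendered images
                # respond to genotype, clamped to stay rasterizable.
                vein_base_width=float(np.clip(
                    base.vein_base_width * (1.0 + 0.05 * trait),
                    1.5, 3.0 * base.vein_base_width)),
            )
            if render:
                s = generate_leaf(params)
            else:
                s = SyntheticSample(image=None, leaf_mask=None,
                                    vein_mask=None, petiole_mask=None,
                                    params=params)
                mm = MM_PER_INCH / params.dpi
                s.true_traits = {"vein_density_driver": trait,
                                 "petiole_length_mm":
                                     base.petiole_length * mm}
            s.true_traits["vein_density_driver"] = trait
            s.sample_id = f"g{j:04d}_c{k:02d}"
            s.genotype_id = f"g{j:04d}"
            samples.append(s)
    return samples
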
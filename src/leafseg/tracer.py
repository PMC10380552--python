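"""Boundary-tracing leaf segmenter.

A small encoder CNN looks at a tile centered on the leaf boundary (RGB plus
an overlay of the recently traced path) and regresses the next ``N`` pixel
positions along the contour as displacements from the tile center. At
inference the first few predicted pixels are committed, the tile re-centers
at the end of the committed path, and the loop runs until the trace returns
to within a small radius of its own earlier contour, at which point the
loop is closed and filled.

The regression loss is a weighted mean squared error whose weights decay
smoothly from ~2 at the tile center to ~1 at the tile edge, so the model is
penalised most where its predictions are actually committed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from skimage.draw import line as draw_line

from . import nn
from .core import (Contour, LeafScan, Tile, extract_tile, fill_contour,
                   mask_to_contour, rough_foreground)

__all__ = [
    "TraceLossConfig", "TracerConfig", "TracerTrainConfig", "AugmentConfig",
    "trace_weights", "weighted_mse", "make_trace_target",
    "build_tracer_dataset", "TracerNet", "OracleTracer", "train_tracer",
    "trace_leaf", "TracingDivergedError", "small_tracer_config",
]


class TracingDivergedError(RuntimeError):
    """Raised when tracing hits the iteration cap without closing the loop.

    Carries the partial committed path in ``partial_path``.
    """

    def __init__(self, msg: str, partial_path: np.ndarray):
        super().__init__(msg)
        self.partial_path = partial_path


def trace_weights(N: int, alpha: float | None = None,
                  beta: float = -4.0) -> np.ndarray:
    """Displacement-index weights ``w_i = 1 + (1 - tanh(alpha*i + beta))/2``.

    ``i`` runs 1..N. With the defaults ``alpha = 8/N`` and ``beta = -4`` the
    weights decrease smoothly from ~2 (tile center) to ~1 (tile edge), with
    the midpoint ``i = N/2`` at exactly 1.5.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if alpha is None:
        alpha = 8.0 / N
    i = np.arange(1, N + 1, dtype=np.float64)
    return 1.0 + (1.0 - np.tanh(alpha * i + beta)) / 2.0


def weighted_mse(pred: np.ndarray, target: np.ndarray,
                 weights: np.ndarray) -> float:
    """``(1/N) * sum_i w_i * ||y_i - yhat_i||^2`` over (row, col) pairs."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape or pred.shape[-1] != len(weights):
        raise ValueError("shape mismatch between pred, target and weights")
    sq = ((pred - target) ** 2).sum(axis=-2)  # sum over the (row, col) axis
    return float(np.mean((weights * sq).sum(axis=-1) / pred.shape[-1]))


def _weighted_mse_grad(pred, target, weights):
    """Batch loss and gradient wrt pred for training."""
    n = pred.shape[-1]
    diff = pred - target
    sq = (diff ** 2).sum(axis=1)
    loss = float(np.mean((weights * sq).sum(axis=-1) / n))
    grad = (2.0 / (n * pred.shape[0])) * weights[None, None, :] * diff
    return loss, grad.astype(pred.dtype)


@dataclass(frozen=True)
class TraceLossConfig:
    N: int = 128
    beta: float = -4.0

    @property
    def alpha(self) -> float:
        return 8.0 / self.N

    @property
    def weights(self) -> np.ndarray:
        return trace_weights(self.N, self.alpha, self.beta)


@dataclass(frozen=True)
class TracerConfig:
    """Architecture plus tracing-loop parameters.

    ``block_widths`` lists the channel width of each conv block; max pooling
    is applied after every block except the last, so the head sees spatial
    size ``tile_size / 2**(len(block_widths) - 1)``.
    """

    tile_size: int = 256
    n_displacements: int = 128
    block_widths: tuple = (16, 32, 64, 96, 128, 160, 192)
    overlay_len: int = 256          # committed pixels drawn into channel 4
    step_commit: int = 32           # predicted pixels committed per iteration
    burn_in: int = 10               # initial iterations whose pixels are dropped
    closure_radius: float = 10.0    # px; distance that closes the loop
    guard_factor: int = 2           # ignore last guard_factor*step_commit px

    @property
    def head_spatial(self) -> int:
        return self.tile_size // (2 ** (len(self.block_widths) - 1))


def small_tracer_config() -> TracerConfig:
    """Desk-scale tracer: 64-px tiles, 3 conv blocks, 32 displacements."""
    return TracerConfig(tile_size=64, n_displacements=32,
                        block_widths=(8, 16, 32), overlay_len=64,
                        step_commit=8, burn_in=5, closure_radius=6.0,
                        guard_factor=4)


class TracerNet:
    """Encoder CNN: residual conv blocks with pooling, linear dense head."""

    def __init__(self, config: TracerConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        widths = config.block_widths
        cin = 4
        self.blocks = []
        self.pools = []
        for i, w in enumerate(widths):
            self.blocks.append(nn.ResidualConvBlock(cin, w, rng))
            cin = w
            if i < len(widths) - 1:
                self.pools.append(nn.MaxPool2d())
        nin = config.head_spatial ** 2 * widths[-1]
        self.head = nn.Dense(nin, 2 * config.n_displacements, rng)

    def params(self):
        out = []
        for b in self.blocks:
            out += b.params()
        return out + self.head.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s = self.config.tile_size
        if x.ndim != 4 or x.shape[1:] != (s, s, 4):
            raise ValueError(f"expected (B, {s}, {s}, 4) input, got {x.shape}")
        y = x
        for i, blk in enumerate(self.blocks):
            y = blk.forward(y, train)
            if i < len(self.pools):
                y = self.pools[i].forward(y, train)
        out = self.head.forward(y, train)
        return out.reshape(x.shape[0], 2, self.config.n_displacements)

    def backward(self, dout: np.ndarray) -> None:
        dy = self.head.backward(dout.reshape(dout.shape[0], -1))
        for i in range(len(self.blocks) - 1, -1, -1):
            if i < len(self.pools):
                dy = self.pools[i].backward(dy)
            dy = self.blocks[i].backward(dy)

    def predict(self, tile: Tile) -> np.ndarray:
        return self.forward(tile.pixels[None], train=False)[0]

    # -- serialization ----------------------------------------------------
    def _state_arrays(self):
        arrays = {}
        for i, p in enumerate(self.params()):
            arrays[f"p{i}"] = p.v
        j = 0
        for b in self.blocks:
            for bn in b.bn:
                arrays[f"rm{j}"] = bn.running_mean
                arrays[f"rv{j}"] = bn.running_var
                j += 1
        return arrays

    def save(self, path) -> None:
        np.savez(path, __config__=np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8),
            **self._state_arrays())

    def _load_arrays(self, data) -> None:
        for i, p in enumerate(self.params()):
            p.v[...] = data[f"p{i}"]
        j = 0
        for b in self.blocks:
            for bn in b.bn:
                bn.running_mean[...] = data[f"rm{j}"]
                bn.running_var[...] = data[f"rv{j}"]
                j += 1

    @classmethod
    def load(cls, path) -> "TracerNet":
        data = np.load(path)
        cfg = json.loads(bytes(data["__config__"]).decode())
        cfg["block_widths"] = tuple(cfg["block_widths"])
        model = cls(TracerConfig(**cfg))
        model._load_arrays(data)
        return model

    def copy_state(self):
        return [p.v.copy() for p in self.params()], [
            (bn.running_mean.copy(), bn.running_var.copy())
            for b in self.blocks for bn in b.bn]

    def set_state(self, state):
        values, stats = state
        for p, v in zip(self.params(), values):
            p.v[...] = v
        for bn, (rm, rv) in zip(
                [bn for b in self.blocks for bn in b.bn], stats):
            bn.running_mean[...] = rm
            bn.running_var[...] = rv


# ---------------------------------------------------------------------------
# training targets
# ---------------------------------------------------------------------------

def _contour_arclengths(points: np.ndarray, direction: int,
                        start_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Contour points reordered from start in the given direction, plus
    cumulative arc length (steps of 1 or sqrt(2))."""
    pts = points if direction == 1 else points[::-1]
    s = start_index if direction == 1 else len(points) - 1 - start_index
    pts = np.roll(pts, -s, axis=0)
    steps = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    return pts, cum


def sample_contour_displacements(contour: Contour, start_index: int,
                                 direction: int, N: int,
                                 tile_size: int) -> np.ndarray:
    """N displacements at equal arc-length spacing from the tile center to
    where the contour first exits the tile (targets clamp at the exit)."""
    pts, cum = _contour_arclengths(np.asarray(contour.points), direction,
                                   start_index)
    center = pts[0].astype(np.float64)
    half = tile_size // 2
    cheb = np.abs(pts - center).max(axis=1)
    outside = np.nonzero(cheb > half - 1)[0]
    end_idx = int(outside[0]) if len(outside) else len(pts) - 1
    L = cum[end_idx]
    if L <= 0:
        disp = np.zeros((2, N))
        return disp
    s = np.linspace(L / N, L, N)
    r = np.interp(s, cum[:end_idx + 1], pts[:end_idx + 1, 0])
    c = np.interp(s, cum[:end_idx + 1], pts[:end_idx + 1, 1])
    disp = np.stack([r - center[0], c - center[1]])
    return np.round(disp)


def make_trace_target(image: np.ndarray, contour: Contour, start_index: int,
                      direction: int, N: int, tile_size: int,
                      overlay_len: int = 256,
                      center_offset: tuple[int, int] = (0, 0)):
    """Build one training tile (RGB + traced-path overlay) and its target.

    The overlay channel marks the ``overlay_len`` contour pixels *behind*
    the start point (the already-traced path, ending at the tile center);
    targets are the displacements of the next N contour samples ahead.
    """
    pts = np.asarray(contour.points)
    P = len(pts)
    if P < N:
        raise ValueError(f"contour with {P} points is shorter than N={N}")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    h, w = image.shape[:2]
    r0, c0 = pts[start_index]
    center = (int(np.clip(r0 + center_offset[0], 0, h - 1)),
              int(np.clip(c0 + center_offset[1], 0, w - 1)))
    back = (start_index - direction * np.arange(0, min(overlay_len, P - 1))) % P
    tile = _tile_with_overlay(image, pts[back], center, tile_size)
    disp = sample_contour_displacements(contour, start_index, direction, N,
                                        tile_size)
    disp = disp + np.array([[r0 - center[0]], [c0 - center[1]]], dtype=float)
    return tile, disp


def _tile_with_overlay(image: np.ndarray, overlay_pts: np.ndarray,
                       center: tuple[int, int], tile_size: int) -> Tile:
    """RGB tile plus a path-overlay channel painted directly into the crop
    (avoids materialising a full-image overlay raster per sample)."""
    tile = extract_tile(image, center, tile_size, pad_value=1.0)
    overlay = np.zeros((tile_size, tile_size, 1), dtype=np.float32)
    if len(overlay_pts):
        half = tile_size // 2
        rel = np.asarray(overlay_pts, dtype=int) - \
            (np.asarray(center, dtype=int) - half)
        ok = ((rel[:, 0] >= 0) & (rel[:, 0] < tile_size)
              & (rel[:, 1] >= 0) & (rel[:, 1] < tile_size))
        overlay[rel[ok, 0], rel[ok, 1], 0] = 1.0
    return Tile(pixels=np.concatenate([tile.pixels, overlay], axis=2),
                center=tile.center, pad_mask=tile.pad_mask)


@dataclass(frozen=True)
class AugmentConfig:
    rot90: bool = True
    flips: bool = True
    jitter_px: int = 8
    color: float = 0.15
    overlay_truncate_prob: float = 0.25


def _apply_rot_flip(tile_px: np.ndarray, disp: np.ndarray, k: int,
                    flip: bool):
    """Exact spatial augmentation for even-sized tiles.

    With the center pixel stored at index (S/2, S/2), a 90-degree rotation
    via ``np.rot90`` shifts the center by one pixel; displacements are
    transformed with the matching off-by-one terms so tile and target stay
    consistent.
    """
    dr, dc = disp[0], disp[1]
    px = tile_px
    for _ in range(k % 4):
        px = np.rot90(px, 1, axes=(0, 1))
        dr, dc = -dc - 1, dr.copy()
    if flip:
        px = px[::-1]
        dr = -dr - 1
    return np.ascontiguousarray(px), np.stack([dr, dc])


class TracerDataset:
    """Lazy tile dataset over (image, leaf mask) pairs.

    One potential target exists per contour pixel per direction; batches are
    drawn on the fly with augmentation so epochs see fresh views.
    """

    def __init__(self, samples, config: TracerConfig,
                 augment: AugmentConfig = AugmentConfig()):
        self.config = config
        self.augment = augment
        self.images = []
        self.contours = []
        for image, mask in samples:
            img = image.astype(np.float32) / 255.0 if image.dtype == np.uint8 \
                else image.astype(np.float32)
            self.images.append(img)
            self.contours.append(mask_to_contour(mask))

    @property
    def n_images(self) -> int:
        return len(self.images)

    def __len__(self) -> int:
        return sum(2 * len(c) for c in self.contours)

    def sample_batch(self, rng: np.random.Generator, batch_size: int,
                     image_ids=None, augment: bool = True):
        cfg, aug = self.config, self.augment
        if image_ids is None:
            image_ids = np.arange(self.n_images)
        tiles = np.empty((batch_size, cfg.tile_size, cfg.tile_size, 4),
                         dtype=np.float32)
        targets = np.empty((batch_size, 2, cfg.n_displacements),
                           dtype=np.float32)
        for b in range(batch_size):
            i = int(rng.choice(image_ids))
            contour = self.contours[i]
            start = int(rng.integers(len(contour)))
            direction = int(rng.choice([-1, 1]))
            off = (0, 0)
            if augment and aug.jitter_px > 0:
                off = tuple(rng.integers(-aug.jitter_px, aug.jitter_px + 1,
                                         size=2))
            # Occasionally truncate the path overlay so the model also
            # learns to continue from a short trace, which is what the
            # first inference iterations present. A floor keeps direction
            # identifiable (an empty overlay has no unique continuation).
            ov_len = cfg.overlay_len
            if (augment and aug.overlay_truncate_prob > 0
                    and rng.random() < aug.overlay_truncate_prob):
                ov_len = int(rng.integers(max(cfg.overlay_len // 4, 8),
                                          cfg.overlay_len + 1))
            tile, disp = make_trace_target(
                self.images[i], contour, start, direction,
                cfg.n_displacements, cfg.tile_size, ov_len, off)
            px = tile.pixels
            if augment:
                k = int(rng.integers(4)) if aug.rot90 else 0
                flip = bool(rng.integers(2)) if aug.flips else False
                px, disp = _apply_rot_flip(px, disp, k, flip)
                if aug.color > 0:
                    gain = rng.uniform(1 - aug.color, 1 + aug.color, size=3)
                    px = px.copy()
                    px[..., :3] = np.clip(px[..., :3] * gain, 0.0, 1.0)
            tiles[b] = px
            targets[b] = disp
        return tiles, targets


def build_tracer_dataset(samples, config: TracerConfig,
                         augment: AugmentConfig = AugmentConfig()):
    """One training target per contour pixel per direction, lazily built."""
    return TracerDataset(samples, config, augment)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TracerTrainConfig:
    epochs: int = 1000
    batch_size: int = 256
    batches_per_epoch: int = 50
    lr: float = 1e-3
    lr_decay_at: float = 0.7       # fraction of epochs after which lr drops
    lr_decay_factor: float = 0.3
    patience: int = 20
    val_fraction: float = 0.2
    n_val_batches: int = 4
    seed: int = 0


def train_tracer(dataset: TracerDataset, config: TracerTrainConfig,
                 net_config: TracerConfig | None = None):
    """Train with Adam and early stopping on an image-level split.

    Images are split 80/20 into train/validation; the best-validation
    checkpoint is returned together with the loss history (which includes
    the constant zero-displacement baseline for reference).
    """
    if dataset.n_images < 2:
        raise ValueError("need at least 2 images for an image-level split")
    net_config = net_config or dataset.config
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    perm = rng.permutation(dataset.n_images)
    n_val = max(1, int(round(config.val_fraction * dataset.n_images)))
    val_ids, train_ids = perm[:n_val], perm[n_val:]
    if len(train_ids) == 0:
        raise ValueError("empty training split")

    model = TracerNet(net_config, seed=config.seed)
    weights = trace_weights(net_config.n_displacements).astype(np.float32)
    opt = nn.Adam(model.params(), lr=config.lr)

    # Fixed, unaugmented validation batches.
    val_rng = np.random.default_rng(np.random.SeedSequence(config.seed + 1))
    val_sets = [dataset.sample_batch(val_rng, config.batch_size, val_ids,
                                     augment=False)
                for _ in range(config.n_val_batches)]

    def val_loss():
        tot = 0.0
        for tiles, targets in val_sets:
            pred = model.forward(tiles, train=False)
            tot += weighted_mse(pred, targets, weights)
        return tot / len(val_sets)

    baseline = np.mean([weighted_mse(np.zeros_like(t), t, weights)
                        for _, t in val_sets])
    history = {"train_loss": [], "val_loss": [],
               "baseline_val_loss": float(baseline)}
    best, best_state, since_best = np.inf, model.copy_state(), 0
    decay_epoch = int(config.lr_decay_at * config.epochs)
    for epoch in range(config.epochs):
        if epoch == decay_epoch and config.lr_decay_factor < 1.0:
            opt.lr *= config.lr_decay_factor
        tr = 0.0
        for _ in range(config.batches_per_epoch):
            tiles, targets = dataset.sample_batch(rng, config.batch_size,
                                                  train_ids)
            pred = model.forward(tiles, train=True)
            loss, dpred = _weighted_mse_grad(pred, targets, weights)
            opt.zero_grad()
            model.backward(dpred)
            opt.step()
            tr += loss
        vl = val_loss()
        history["train_loss"].append(tr / config.batches_per_epoch)
        history["val_loss"].append(vl)
        if vl < best:
            best, best_state, since_best = vl, model.copy_state(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.set_state(best_state)
    history["best_val_loss"] = float(best)
    return model, history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

class OracleTracer:
    """Plug-in stand-in for a trained tracer that reads a known contour.

    Used to validate the tracing loop itself: at each call it locates the
    nearest ground-truth contour point to the tile center and emits the true
    displacements ahead of it. Synthetic by construction; not a model.
    """

    def __init__(self, contour: Contour, config: TracerConfig,
                 direction: int = 1):
        self.contour = contour
        self.config = config
        self.direction = direction

    def predict(self, tile: Tile) -> np.ndarray:
        pts = np.asarray(self.contour.points)
        center = np.asarray(tile.center)
        idx = int(np.argmin(((pts - center) ** 2).sum(axis=1)))
        disp = sample_contour_displacements(
            self.contour, idx, self.direction, self.config.n_displacements,
            self.config.tile_size)
        return disp + (pts[idx] - center)[:, None]


def _commit_pixels(center, pred, n_commit, shape):
    """Rasterize the first predicted displacements into an 8-connected path."""
    pts = np.round(np.asarray(center, dtype=float)[:, None] + pred).astype(int)
    pts[0] = np.clip(pts[0], 0, shape[0] - 1)
    pts[1] = np.clip(pts[1], 0, shape[1] - 1)
    path = []
    prev = (int(center[0]), int(center[1]))
    for k in range(min(n_commit, pts.shape[1])):
        tgt = (int(pts[0, k]), int(pts[1, k]))
        rr, cc = draw_line(prev[0], prev[1], tgt[0], tgt[1])
        for r, c in zip(rr[1:], cc[1:]):
            path.append((int(r), int(c)))
        prev = tgt
    return path


def trace_leaf(model, scan: LeafScan, config: TracerConfig,
               max_iter: int | None = None):
    """Iteratively trace the leaf boundary and fill it into a mask.

    Starts at the topmost pixel of the Otsu rough segmentation; each
    iteration commits the first ``step_commit`` predicted pixels and
    re-centers there. Pixels from the first ``burn_in`` iterations are
    discarded; closure is tested only against contour pixels older than
    ``guard_factor * step_commit`` steps.
    """
    img = scan.as_float()
    h, w = img.shape[:2]
    rough = rough_foreground(scan)
    perimeter_estimate = 2 * (rough.any(axis=1).sum() + rough.any(axis=0).sum())
    if max_iter is None:
        max_iter = max(4 * int(perimeter_estimate / config.step_commit), 50)

    # The rough segmentation provides the starting location (its topmost
    # boundary pixel) and the initial trace direction: a short stretch of
    # its boundary behind the start seeds the path-overlay channel so the
    # first prediction has an unambiguous way to continue.
    rough_contour = mask_to_contour(rough)
    rpts = rough_contour.points
    start_idx = int(np.lexsort((rpts[:, 1], rpts[:, 0]))[0])
    center = (int(rpts[start_idx, 0]), int(rpts[start_idx, 1]))
    boot_len = min(max(config.overlay_len // 2, config.step_commit),
                   len(rpts) - 1)
    boot_idx = (start_idx - np.arange(boot_len, 0, -1)) % len(rpts)
    bootstrap = [(int(r), int(c)) for r, c in rpts[boot_idx]]

    committed: list[tuple[int, int]] = []   # full path (incl. burn-in)
    overlay_pts = list(bootstrap)
    stored_start = None                     # index into committed
    guard = config.guard_factor * config.step_commit
    closing_line = None
    match_idx = None

    for iteration in range(max_iter):
        tile = _tile_with_overlay(img, np.array(overlay_pts, dtype=int),
                                  center, config.tile_size)
        pred = model.predict(tile)
        new_px = _commit_pixels(center, pred, config.step_commit, (h, w))
        if not new_px:
            raise TracingDivergedError(
                "model predicted no forward movement",
                np.array(committed, dtype=int))
        if iteration == config.burn_in:
            stored_start = len(committed)
        committed.extend(new_px)
        # The overlay shows the recent path; bootstrap pixels age out as
        # committed path accumulates.
        overlay_pts = (bootstrap + committed)[-config.overlay_len:]
        center = committed[-1]
        # Closure test against stored contour older than the guard window.
        if stored_start is not None:
            stored = committed[stored_start:]
            old = stored[:max(len(stored) - guard, 0)]
            if old:
                arr_old = np.array(old, dtype=int)
                d2 = ((arr_old - np.array(center)) ** 2).sum(axis=1)
                j = int(np.argmin(d2))
                if d2[j] <= config.closure_radius ** 2:
                    match_idx = j
                    rr, cc = draw_line(center[0], center[1],
                                       int(arr_old[j, 0]), int(arr_old[j, 1]))
                    closing_line = list(zip(rr[1:-1].tolist(),
                                            cc[1:-1].tolist()))
                    break
    else:
        raise TracingDivergedError(
            f"no closure within {max_iter} iterations",
            np.array(committed, dtype=int))

    stored = committed[stored_start:]
    loop = stored[match_idx:] + (closing_line or [])
    # Deduplicate consecutive repeats while keeping order.
    pts = [loop[0]]
    for p in loop[1:]:
        if p != pts[-1]:
            pts.append(p)
    contour = Contour(points=np.array(pts, dtype=int), closed=True)
    mask = fill_contour(contour, (h, w))
    return contour, mask
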
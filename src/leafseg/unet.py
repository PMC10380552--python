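"""U-Net baseline with overlapping tile-grid inference.

The encoder is identical to the corresponding few-shot model's encoder; the
decoder mirrors its widths in reverse, upsampling with 2x2 transposed
convolutions and concatenating the pre-pooling encoder activations at each
resolution (skip connections). A final 1x1 convolution with a sigmoid gives
per-pixel foreground probabilities.

Whole images are predicted on a uniform grid of tiles overlapping by half
the tile size; per-pixel probabilities are averaged across tiles and then
thresholded (fixed 0.5 for the leaf task; connectivity-minimising threshold
for veins, shared with the grower).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .core import LeafScan, extract_tile
from .grower import (GrowLossConfig, ProbabilityAccumulator, _focal_grad,
                     focal_loss, select_threshold, DEFAULT_THRESHOLD_GRID)

__all__ = [
    "UNetConfig", "UNet", "TileGrid", "build_tile_grid", "predict_tiled",
    "unet_threshold", "UNetDataset", "build_unet_dataset", "train_unet",
    "UNetTrainConfig", "small_unet_config",
]


@dataclass(frozen=True)
class UNetConfig:
    tile_size: int = 128
    block_widths: tuple = (32, 64, 96, 128, 160, 192)


def small_unet_config(tile_size: int = 32) -> UNetConfig:
    return UNetConfig(tile_size=tile_size, block_widths=(8, 16, 32))


class UNet:
    """Encoder-decoder with skip connections, NHWC numpy implementation."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        widths = config.block_widths
        cin = 3
        self.enc_blocks = []
        self.pools = []
        for i, w in enumerate(widths):
            self.enc_blocks.append(nn.ResidualConvBlock(cin, w, rng))
            cin = w
            if i < len(widths) - 1:
                self.pools.append(nn.MaxPool2d())
        self.ups = []
        self.dec_blocks = []
        for i in range(len(widths) - 2, -1, -1):
            self.ups.append(nn.ConvTranspose2d(cin, widths[i], rng))
            self.dec_blocks.append(
                nn.ResidualConvBlock(2 * widths[i], widths[i], rng))
            cin = widths[i]
        self.final = nn.Conv2d(widths[0], 1, 1, rng)
        self._cache = None

    def params(self):
        out = []
        for b in self.enc_blocks + self.dec_blocks:
            out += b.params()
        for u in self.ups:
            out += u.params()
        return out + self.final.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s = self.config.tile_size
        if x.ndim != 4 or x.shape[1:] != (s, s, 3):
            raise ValueError(f"expected (B, {s}, {s}, 3) input, got {x.shape}")
        skips = []
        y = x
        for i, blk in enumerate(self.enc_blocks):
            y = blk.forward(y, train)
            if i < len(self.pools):
                skips.append(y)
                y = self.pools[i].forward(y, train)
        for up, blk, skip in zip(self.ups, self.dec_blocks,
                                 reversed(skips)):
            y = up.forward(y, train)
            y = np.concatenate([skip, y], axis=-1)
            y = blk.forward(y, train)
        logits = self.final.forward(y, train)[..., 0]
        probs = nn.sigmoid(logits)
        if train:
            self._cache = probs
        return probs

    def backward_from_prob_grad(self, dprob: np.ndarray) -> None:
        probs = self._cache
        dlogits = (dprob * probs * (1.0 - probs))[..., None]
        dy = self.final.backward(dlogits)
        nskips = len(self.ups)
        # Decoder stages run shallow-last, so backprop visits them in
        # reverse (shallowest first); dskips[i] then matches skips[i].
        dskips = []
        for up, blk in zip(reversed(self.ups), reversed(self.dec_blocks)):
            dy = blk.backward(dy)
            cskip = dy.shape[-1] - up.cout
            dskips.append(dy[..., :cskip])
            dy = up.backward(dy[..., cskip:])
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            if i < nskips:
                dy = self.pools[i].backward(dy) + dskips[i]
            dy = self.enc_blocks[i].backward(dy)

    def predict_batch(self, tiles: np.ndarray) -> np.ndarray:
        return self.forward(tiles, train=False)

    # -- serialization ------------------------------------------------------
    def _bns(self):
        return [bn for b in self.enc_blocks + self.dec_blocks for bn in b.bn]

    def save(self, path) -> None:
        arrays = {f"p{i}": p.v for i, p in enumerate(self.params())}
        for j, bn in enumerate(self._bns()):
            arrays[f"rm{j}"] = bn.running_mean
            arrays[f"rv{j}"] = bn.running_var
        np.savez(path, __config__=np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8),
            **arrays)

    @classmethod
    def load(cls, path) -> "UNet":
        data = np.load(path)
        cfg = json.loads(bytes(data["__config__"]).decode())
        cfg["block_widths"] = tuple(cfg["block_widths"])
        model = cls(UNetConfig(**cfg))
        for i, p in enumerate(model.params()):
            p.v[...] = data[f"p{i}"]
        for j, bn in enumerate(model._bns()):
            bn.running_mean[...] = data[f"rm{j}"]
            bn.running_var[...] = data[f"rv{j}"]
        return model

    def copy_state(self):
        return ([p.v.copy() for p in self.params()],
                [(bn.running_mean.copy(), bn.running_var.copy())
                 for bn in self._bns()])

    def set_state(self, state):
        values, stats = state
        for p, v in zip(self.params(), values):
            p.v[...] = v
        for bn, (rm, rv) in zip(self._bns(), stats):
            bn.running_mean[...] = rm
            bn.running_var[...] = rv


# ---------------------------------------------------------------------------
# tiled inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TileGrid:
    tile_size: int
    stride: int
    tile_centers: tuple  # of (row, col)


def build_tile_grid(shape: tuple[int, int], tile_size: int,
                    stride: int | None = None) -> TileGrid:
    """Uniform overlapping grid; the last row/column is flush with the
    image edge so every pixel is covered."""
    h, w = shape
    if stride is None:
        stride = tile_size // 2
    if h < tile_size or w < tile_size:
        raise ValueError("image smaller than the tile size")

    def starts(n):
        s = list(range(0, n - tile_size + 1, stride))
        if s[-1] != n - tile_size:
            s.append(n - tile_size)
        return s

    half = tile_size // 2
    centers = tuple((r0 + half, c0 + half)
                    for r0 in starts(h) for c0 in starts(w))
    return TileGrid(tile_size=tile_size, stride=stride, tile_centers=centers)


def predict_tiled(model, scan: LeafScan, grid: TileGrid,
                  batch_size: int = 64) -> ProbabilityAccumulator:
    """Predict every grid tile and average probabilities per pixel."""
    img = scan.as_float()
    h, w = img.shape[:2]
    acc = ProbabilityAccumulator.zeros((h, w))
    s = grid.tile_size
    half = s // 2
    centers = list(grid.tile_centers)
    for i in range(0, len(centers), batch_size):
        chunk = centers[i:i + batch_size]
        tiles = np.stack([extract_tile(img, c, s).pixels for c in chunk])
        probs = model.predict_batch(tiles)
        for (r, c), p in zip(chunk, probs):
            r0, c0 = r - half, c - half
            acc.prob_sum[r0:r0 + s, c0:c0 + s] += p
            acc.visit_count[r0:r0 + s, c0:c0 + s] += 1
    return acc


def unet_threshold(acc: ProbabilityAccumulator, task: str,
                   grid=DEFAULT_THRESHOLD_GRID):
    """Leaf task: fixed 0.5. Vein task: connectivity-minimising threshold."""
    if task == "leaf":
        return 0.5, acc.mean() >= 0.5
    if task == "vein":
        return select_threshold(acc, grid)
    raise ValueError("task must be 'leaf' or 'vein'")


# ---------------------------------------------------------------------------
# dataset + training
# ---------------------------------------------------------------------------

class UNetDataset:
    """Tiles sampled from anywhere in the leaf, with full-tile mask targets."""

    def __init__(self, samples, config: UNetConfig, task: str = "vein",
                 color_aug: float = 0.15):
        self.config = config
        self.task = task
        self.color_aug = color_aug
        self.images = []
        self.targets = []
        self.center_pools = []
        for image, target_mask, leaf_mask in samples:
            img = image.astype(np.float32) / 255.0 \
                if image.dtype == np.uint8 else image.astype(np.float32)
            self.images.append(img)
            self.targets.append(target_mask.astype(np.float32))
            self.center_pools.append(np.argwhere(leaf_mask))

    @property
    def n_images(self) -> int:
        return len(self.images)

    def sample_batch(self, rng: np.random.Generator, batch_size: int,
                     image_ids=None, augment: bool = True):
        cfg = self.config
        if image_ids is None:
            image_ids = np.arange(self.n_images)
        s = cfg.tile_size
        tiles = np.empty((batch_size, s, s, 3), dtype=np.float32)
        targets = np.empty((batch_size, s, s), dtype=np.float32)
        valid = np.empty((batch_size, s, s), dtype=bool)
        for b in range(batch_size):
            i = int(rng.choice(image_ids))
            pool = self.center_pools[i]
            r, c = pool[int(rng.integers(len(pool)))]
            tile = extract_tile(self.images[i], (r, c), s)
            ttile = extract_tile(self.targets[i][..., None], (r, c), s,
                                 pad_value=0.0)
            px, tg, vd = tile.pixels, ttile.pixels[..., 0], ~tile.pad_mask
            if augment:
                k = int(rng.integers(4))
                px, tg, vd = (np.rot90(a, k, axes=(0, 1))
                              for a in (px, tg, vd))
                if rng.integers(2):
                    px, tg, vd = px[::-1], tg[::-1], vd[::-1]
                if self.color_aug > 0:
                    gain = rng.uniform(1 - self.color_aug,
                                       1 + self.color_aug, size=3)
                    px = np.clip(px * gain, 0.0, 1.0)
            tiles[b] = np.ascontiguousarray(px)
            targets[b] = np.ascontiguousarray(tg)
            valid[b] = np.ascontiguousarray(vd)
        return tiles, targets, valid


def build_unet_dataset(samples, config: UNetConfig, task: str = "vein",
                       color_aug: float = 0.15) -> UNetDataset:
    return UNetDataset(samples, config, task, color_aug)


@dataclass(frozen=True)
class UNetTrainConfig:
    epochs: int = 1000
    batch_size: int = 512   # half the grower batch at full scale
    batches_per_epoch: int = 20
    lr: float = 1e-3
    lr_decay_at: float = 0.7
    lr_decay_factor: float = 0.3
    patience: int = 20
    val_fraction: float = 0.25
    n_val_batches: int = 2
    seed: int = 0


def train_unet(dataset: UNetDataset, config: UNetTrainConfig,
               loss: GrowLossConfig = GrowLossConfig(mode="bce"),
               net_config: UNetConfig | None = None):
    """Per-pixel loss over the tile; padded pixels are masked out."""
    if dataset.n_images < 2:
        raise ValueError("need at least 2 images for an image-level split")
    net_config = net_config or dataset.config
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    perm = rng.permutation(dataset.n_images)
    n_val = max(1, int(round(config.val_fraction * dataset.n_images)))
    val_ids, train_ids = perm[:n_val], perm[n_val:]
    if len(train_ids) == 0:
        raise ValueError("empty training split")

    model = UNet(net_config, seed=config.seed)
    # Prior-probability initialisation of the output bias: start the
    # foreground probability at the empirical class rate, which keeps the
    # focal variant's early gradients informative and its maps calibrated.
    n_fg = sum(float(t.sum()) for t in dataset.targets)
    n_all = sum(len(p) for p in dataset.center_pools)
    prior = float(np.clip(n_fg / max(n_all, 1), 1e-3, 1 - 1e-3))
    model.final.b.v[0] = np.log(prior / (1.0 - prior))
    opt = nn.Adam(model.params(), lr=config.lr)
    val_rng = np.random.default_rng(np.random.SeedSequence(config.seed + 1))
    val_sets = [dataset.sample_batch(val_rng, config.batch_size, val_ids,
                                     augment=False)
                for _ in range(config.n_val_batches)]

    def masked_loss_grad(probs, targets, valid, train):
        l, g = _focal_grad(probs, targets, loss)
        scale = probs.size / max(valid.sum(), 1)
        l_masked = float((np.where(valid,
                                   focal_loss(probs, targets, loss),
                                   0.0)).sum() / max(valid.sum(), 1))
        if not train:
            return l_masked, None
        g = np.where(valid, g, 0.0) * scale
        return l_masked, g.astype(np.float32)

    def val_loss():
        tot = 0.0
        for tiles, targets, valid in val_sets:
            probs = model.forward(tiles, train=False)
            l, _ = masked_loss_grad(probs, targets, valid, train=False)
            tot += l
        return tot / len(val_sets)

    history = {"train_loss": [], "val_loss": []}
    best, best_state, since_best = np.inf, model.copy_state(), 0
    decay_epoch = int(config.lr_decay_at * config.epochs)
    for epoch in range(config.epochs):
        if epoch == decay_epoch and config.lr_decay_factor < 1.0:
            opt.lr *= config.lr_decay_factor
        tr = 0.0
        for _ in range(config.batches_per_epoch):
            tiles, targets, valid = dataset.sample_batch(
                rng, config.batch_size, train_ids)
            probs = model.forward(tiles, train=True)
            l, dp = masked_loss_grad(probs, targets, valid, train=True)
            opt.zero_grad()
            model.backward_from_prob_grad(dp)
            opt.step()
            tr += l
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
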
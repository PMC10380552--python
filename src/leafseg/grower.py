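"""Region-growing vein segmenter.

A small encoder CNN classifies the center pixel of an RGB tile and its
eight neighbors as vein or lamina (a 3x3x2 softmax output). Inference is a
flood-fill: seed pixels inside the leaf are classified, positively
classified neighbors join the frontier, and every pixel's probabilities
are averaged over however many times its neighborhood is visited. The final
mask is the averaged-probability threshold that minimises the number of
8-connected components (the vasculature is one network, so fewer fragments
means a more biologically plausible segmentation).

Training uses focal loss by default (class-imbalance aware: vein pixels are
rare and hard pixels dominate the gradient); plain binary cross-entropy is
available for comparison and equals the focal loss with gamma=0, alpha=0.5,
rescaled by 2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .core import LeafScan, Tile, connected_components, extract_tile

__all__ = [
    "GrowLossConfig", "GrowerConfig", "GrowerTrainConfig",
    "ProbabilityAccumulator", "focal_loss", "build_grower_dataset",
    "GrowerNet", "OracleGrower", "train_grower", "grow_veins",
    "select_threshold", "small_grower_config", "DEFAULT_THRESHOLD_GRID",
]

_EPS = 1e-7

DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


@dataclass(frozen=True)
class GrowLossConfig:
    alpha: float = 0.25
    gamma: float = 2.0
    mode: str = "focal"  # "focal" | "bce"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.mode not in ("focal", "bce"):
            raise ValueError("mode must be 'focal' or 'bce'")

    def effective(self) -> tuple[float, float, float]:
        """(alpha, gamma, scale): bce == focal(gamma=0, alpha=0.5) * 2."""
        if self.mode == "bce":
            return 0.5, 0.0, 2.0
        return self.alpha, self.gamma, 1.0


def focal_loss(p, y, config: GrowLossConfig = GrowLossConfig()):
    """Per-element focal loss.

    ``-alpha * (1-p)^gamma * log(p)`` where the true class is vein (y=1),
    ``-(1-alpha) * p^gamma * log(1-p)`` otherwise. Probabilities are clamped
    to [eps, 1-eps] so log never sees 0. Accepts scalars or arrays.
    """
    alpha, gamma, scale = config.effective()
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    y = np.asarray(y)
    pos = -alpha * (1.0 - p) ** gamma * np.log(p)
    neg = -(1.0 - alpha) * p ** gamma * np.log(1.0 - p)
    out = scale * np.where(y == 1, pos, neg)
    return out if out.ndim else float(out)


def _focal_grad(p, y, config: GrowLossConfig):
    """Mean loss and d(loss)/d(p) for training (same clamping as above)."""
    alpha, gamma, scale = config.effective()
    p = np.clip(p, _EPS, 1.0 - _EPS)
    q = 1.0 - p
    logp, logq = np.log(p), np.log(q)
    n = p.size
    pos_l = -alpha * q ** gamma * logp
    neg_l = -(1.0 - alpha) * p ** gamma * logq
    loss = scale * float(np.where(y == 1, pos_l, neg_l).mean())
    if gamma == 0.0:
        dpos = -alpha / p
        dneg = (1.0 - alpha) / q
    else:
        dpos = alpha * (gamma * q ** (gamma - 1.0) * logp - q ** gamma / p)
        dneg = -(1.0 - alpha) * (gamma * p ** (gamma - 1.0) * logq
                                 - p ** gamma / q)
    grad = scale * np.where(y == 1, dpos, dneg) / n
    return loss, grad.astype(np.float32)


@dataclass(frozen=True)
class GrowerConfig:
    """Architecture and growing-loop parameters.

    The encoder is the tracer encoder minus its first block (the tiles are
    half the size), ending in a dense head reshaped to 3x3x2 with a
    per-pixel softmax over the two classes.
    """

    tile_size: int = 128
    block_widths: tuple = (32, 64, 96, 128, 160, 192)
    n_seeds: int = 10000
    enqueue_threshold: float = 0.5   # instantaneous prob that grows the front
    batch_size: int = 512            # frontier tiles predicted per wave

    @property
    def head_spatial(self) -> int:
        return self.tile_size // (2 ** (len(self.block_widths) - 1))


def small_grower_config(n_seeds: int = 300) -> GrowerConfig:
    """Desk-scale grower: 32-px tiles, 3 conv blocks."""
    return GrowerConfig(tile_size=32, block_widths=(8, 16, 32),
                        n_seeds=n_seeds, batch_size=512)


class GrowerNet:
    """Encoder CNN emitting 3x3x2 softmax class probabilities."""

    def __init__(self, config: GrowerConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        widths = config.block_widths
        cin = 3
        self.blocks = []
        self.pools = []
        for i, w in enumerate(widths):
            self.blocks.append(nn.ResidualConvBlock(cin, w, rng))
            cin = w
            if i < len(widths) - 1:
                self.pools.append(nn.MaxPool2d())
        nin = config.head_spatial ** 2 * widths[-1]
        self.head = nn.Dense(nin, 18, rng)
        self._cache_probs = None

    def params(self):
        out = []
        for b in self.blocks:
            out += b.params()
        return out + self.head.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s = self.config.tile_size
        if x.ndim != 4 or x.shape[1:] != (s, s, 3):
            raise ValueError(f"expected (B, {s}, {s}, 3) input, got {x.shape}")
        y = x
        for i, blk in enumerate(self.blocks):
            y = blk.forward(y, train)
            if i < len(self.pools):
                y = self.pools[i].forward(y, train)
        logits = self.head.forward(y, train).reshape(-1, 3, 3, 2)
        probs = nn.softmax(logits, axis=-1)
        if train:
            self._cache_probs = probs
        return probs

    def backward_from_vein_grad(self, dvein: np.ndarray) -> None:
        """Backprop from d(loss)/d(p_vein) through the softmax pair."""
        probs = self._cache_probs
        pv = probs[..., 1]
        dz1 = dvein * pv * (1.0 - pv)
        dlogits = np.stack([-dz1, dz1], axis=-1)
        dy = self.head.backward(dlogits.reshape(dlogits.shape[0], -1))
        for i in range(len(self.blocks) - 1, -1, -1):
            if i < len(self.pools):
                dy = self.pools[i].backward(dy)
            dy = self.blocks[i].backward(dy)

    def predict(self, tile: Tile) -> np.ndarray:
        return self.forward(tile.pixels[None], train=False)[0]

    def predict_batch(self, tiles: np.ndarray) -> np.ndarray:
        return self.forward(tiles, train=False)

    # -- serialization (same scheme as the tracer) --------------------------
    def _bns(self):
        return [bn for b in self.blocks for bn in b.bn]

    def save(self, path) -> None:
        arrays = {f"p{i}": p.v for i, p in enumerate(self.params())}
        for j, bn in enumerate(self._bns()):
            arrays[f"rm{j}"] = bn.running_mean
            arrays[f"rv{j}"] = bn.running_var
        np.savez(path, __config__=np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8),
            **arrays)

    @classmethod
    def load(cls, path) -> "GrowerNet":
        data = np.load(path)
        cfg = json.loads(bytes(data["__config__"]).decode())
        cfg["block_widths"] = tuple(cfg["block_widths"])
        model = cls(GrowerConfig(**cfg))
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


class OracleGrower:
    """Plug-in classifier that reads the ground-truth vein mask.

    Validates the growing loop and threshold selection independently of any
    training. Synthetic by construction; not a model.
    """

    def __init__(self, vein_mask: np.ndarray):
        self.vein_mask = vein_mask

    def predict_batch_at(self, centers: np.ndarray) -> np.ndarray:
        h, w = self.vein_mask.shape
        out = np.zeros((len(centers), 3, 3), dtype=np.float32)
        for i, (r, c) in enumerate(centers):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and self.vein_mask[rr, cc]:
                        out[i, dr + 1, dc + 1] = 1.0
        return out


# ---------------------------------------------------------------------------
# dataset + training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowerAugment:
    rot90: bool = True
    flips: bool = True
    color: float = 0.08
    blur_prob: float = 0.1
    blur_sigma: float = 1.0


class GrowerDataset:
    """Center-pixel tile dataset: every vein pixel is a positive center,
    plus up to ``neg_ratio`` times as many leaf-interior negatives."""

    def __init__(self, samples, config: GrowerConfig, neg_ratio: float = 10.0,
                 augment: GrowerAugment = GrowerAugment(), seed: int = 0):
        if neg_ratio > 10.0:
            raise ValueError("neg_ratio must be <= 10")
        self.config = config
        self.augment = augment
        self.images = []
        self.vein_masks = []
        self.centers = []   # per image: (n, 3) array of (r, c, label)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        for image, vein_mask, leaf_mask in samples:
            img = image.astype(np.float32) / 255.0 \
                if image.dtype == np.uint8 else image.astype(np.float32)
            vin = vein_mask & leaf_mask
            pos = np.argwhere(vin)
            interior = np.argwhere(leaf_mask & ~vin)
            n_neg = int(round(neg_ratio * len(pos)))
            if n_neg > len(interior):
                warnings.warn("leaf interior smaller than requested "
                              "negatives; sampling all available")
                n_neg = len(interior)
            neg = interior[rng.choice(len(interior), size=n_neg,
                                      replace=False)]
            cent = np.concatenate([
                np.column_stack([pos, np.ones(len(pos), dtype=int)]),
                np.column_stack([neg, np.zeros(len(neg), dtype=int)])])
            self.images.append(img)
            self.vein_masks.append(vin)
            self.centers.append(cent)

    @property
    def n_images(self) -> int:
        return len(self.images)

    def __len__(self) -> int:
        return sum(len(c) for c in self.centers)

    def _target_patch(self, i: int, r: int, c: int) -> np.ndarray:
        m = self.vein_masks[i]
        h, w = m.shape
        out = np.zeros((3, 3), dtype=np.float32)
        r0, r1 = max(r - 1, 0), min(r + 2, h)
        c0, c1 = max(c - 1, 0), min(c + 2, w)
        out[r0 - (r - 1):r0 - (r - 1) + (r1 - r0),
            c0 - (c - 1):c0 - (c - 1) + (c1 - c0)] = m[r0:r1, c0:c1]
        return out

    def sample_batch(self, rng: np.random.Generator, batch_size: int,
                     image_ids=None, augment: bool = True):
        cfg, aug = self.config, self.augment
        if image_ids is None:
            image_ids = np.arange(self.n_images)
        s = cfg.tile_size
        tiles = np.empty((batch_size, s, s, 3), dtype=np.float32)
        targets = np.empty((batch_size, 3, 3), dtype=np.float32)
        for b in range(batch_size):
            i = int(rng.choice(image_ids))
            r, c, _ = self.centers[i][int(rng.integers(len(self.centers[i])))]
            tile = extract_tile(self.images[i], (r, c), s)
            px = tile.pixels
            tgt = self._target_patch(i, r, c)
            if augment:
                # np.rot90/flip of an even-sized tile move the center pixel
                # by one; roll it back so the 3x3 labels stay centered (the
                # wrapped border row is far from the receptive center).
                if aug.rot90:
                    k = int(rng.integers(4))
                    px = np.rot90(px, k, axes=(0, 1))
                    if k == 1:
                        px = np.roll(px, 1, axis=0)
                    elif k == 2:
                        px = np.roll(px, (1, 1), axis=(0, 1))
                    elif k == 3:
                        px = np.roll(px, 1, axis=1)
                    tgt = np.rot90(tgt, k)
                if aug.flips and rng.integers(2):
                    px = np.roll(px[::-1], 1, axis=0)
                    tgt = tgt[::-1]
                if aug.color > 0:
                    gain = rng.uniform(1 - aug.color, 1 + aug.color, size=3)
                    px = np.clip(px * gain, 0.0, 1.0)
                if aug.blur_prob > 0 and rng.random() < aug.blur_prob:
                    from scipy.ndimage import gaussian_filter
                    px = gaussian_filter(px, (aug.blur_sigma,
                                              aug.blur_sigma, 0))
            tiles[b] = np.ascontiguousarray(px)
            targets[b] = np.ascontiguousarray(tgt)
        return tiles, targets


def build_grower_dataset(samples, config: GrowerConfig,
                         neg_ratio: float = 10.0,
                         augment: GrowerAugment = GrowerAugment(),
                         seed: int = 0) -> GrowerDataset:
    return GrowerDataset(samples, config, neg_ratio, augment, seed)


@dataclass(frozen=True)
class GrowerTrainConfig:
    epochs: int = 1000
    batch_size: int = 1024
    batches_per_epoch: int = 20
    lr: float = 1e-3
    lr_decay_at: float = 0.7
    lr_decay_factor: float = 0.3
    grad_clip: float = 5.0          # global-norm clip; 0 disables
    patience: int = 20
    val_fraction: float = 0.25
    n_val_batches: int = 2
    seed: int = 0


def train_grower(dataset: GrowerDataset, config: GrowerTrainConfig,
                 loss: GrowLossConfig = GrowLossConfig(),
                 net_config: GrowerConfig | None = None):
    """Adam + early stopping on an image-level split; best checkpoint wins.

    ``loss.mode`` selects focal or BCE so the two objectives can be compared
    on identical data and identical initialisation (the seed fixes both).
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

    model = GrowerNet(net_config, seed=config.seed)
    # Prior-probability initialisation of the class logits: start the vein
    # probability at the empirical positive rate instead of 0.5, which
    # keeps the early focal gradients informative.
    n_pos = sum(int(c[:, 2].sum()) for c in dataset.centers)
    prior = np.clip(n_pos / max(len(dataset), 1), 1e-3, 1 - 1e-3)
    model.head.b.v[1::2] = np.log(prior / (1.0 - prior))
    opt = nn.Adam(model.params(), lr=config.lr)
    val_rng = np.random.default_rng(np.random.SeedSequence(config.seed + 1))
    val_sets = [dataset.sample_batch(val_rng, config.batch_size, val_ids,
                                     augment=False)
                for _ in range(config.n_val_batches)]

    def val_loss():
        tot = 0.0
        for tiles, targets in val_sets:
            pv = model.forward(tiles, train=False)[..., 1]
            l, _ = _focal_grad(pv, targets, loss)
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
            tiles, targets = dataset.sample_batch(rng, config.batch_size,
                                                  train_ids)
            pv = model.forward(tiles, train=True)[..., 1]
            l, dpv = _focal_grad(pv, targets, loss)
            opt.zero_grad()
            model.backward_from_vein_grad(dpv)
            nn.clip_global_norm(opt.params, config.grad_clip)
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


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityAccumulator:
    """Running per-pixel sum and visit count of vein probabilities."""

    prob_sum: np.ndarray
    visit_count: np.ndarray

    @classmethod
    def zeros(cls, shape) -> "ProbabilityAccumulator":
        return cls(np.zeros(shape, dtype=np.float64),
                   np.zeros(shape, dtype=np.int64))

    def add(self, rows, cols, probs) -> None:
        np.add.at(self.prob_sum, (rows, cols), probs)
        np.add.at(self.visit_count, (rows, cols), 1)

    def mean(self) -> np.ndarray:
        out = np.zeros_like(self.prob_sum)
        v = self.visit_count > 0
        out[v] = self.prob_sum[v] / self.visit_count[v]
        return out


_OFFSETS = np.array([(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)])


def grow_veins(model, scan: LeafScan, leaf_mask: np.ndarray,
               config: GrowerConfig, seed: int = 0) -> ProbabilityAccumulator:
    """Flood-fill inference: classify, average, grow until the front dies.

    Seeds are sampled uniformly without replacement from leaf-interior
    pixels. Each pixel becomes a center at most once; every prediction's
    nine probabilities are accumulated, and 8-neighbors whose instantaneous
    vein probability exceeds ``config.enqueue_threshold`` join the frontier
    if they lie inside the leaf and were never centers. Termination is
    guaranteed because the center set is finite.
    """
    if not leaf_mask.any():
        raise ValueError("leaf mask is empty")
    h, w = leaf_mask.shape
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    interior = np.argwhere(leaf_mask)
    n_seeds = config.n_seeds
    if n_seeds > len(interior):
        warnings.warn("requested more seeds than leaf-interior pixels; "
                      "using all of them")
        n_seeds = len(interior)
    seeds = interior[rng.choice(len(interior), size=n_seeds, replace=False)]

    img = scan.as_float()
    acc = ProbabilityAccumulator.zeros((h, w))
    was_center = np.zeros((h, w), dtype=bool)
    queued = np.zeros((h, w), dtype=bool)
    frontier = []
    for r, c in seeds:
        if not queued[r, c]:
            queued[r, c] = True
            frontier.append((int(r), int(c)))

    oracle_mode = hasattr(model, "predict_batch_at")
    s = config.tile_size
    while frontier:
        batch = frontier[:config.batch_size]
        frontier = frontier[config.batch_size:]
        centers = np.array(batch, dtype=int)
        was_center[centers[:, 0], centers[:, 1]] = True
        if oracle_mode:
            pv = model.predict_batch_at(centers)
        else:
            tiles = np.empty((len(centers), s, s, 3), dtype=np.float32)
            for i, (r, c) in enumerate(centers):
                tiles[i] = extract_tile(img, (r, c), s).pixels
            pv = model.predict_batch(tiles)[..., 1]
        # Accumulate all nine probabilities per prediction.
        pts = centers[:, None, :] + _OFFSETS[None, :, :]
        rr = pts[..., 0].ravel()
        cc = pts[..., 1].ravel()
        pp = pv.reshape(len(centers), 9).ravel()
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        acc.add(rr[ok], cc[ok], pp[ok])
        # Grow the frontier.
        grow = ok & (pp > config.enqueue_threshold)
        gr, gc = rr[grow], cc[grow]
        inside = leaf_mask[gr, gc] & ~was_center[gr, gc] & ~queued[gr, gc]
        for r, c in zip(gr[inside], gc[inside]):
            queued[r, c] = True
            frontier.append((int(r), int(c)))
    return acc


def select_threshold(acc: ProbabilityAccumulator,
                     grid=DEFAULT_THRESHOLD_GRID):
    """Pick the averaged-probability threshold minimising component count.

    Empty masks are assigned +inf components so the selector cannot win by
    predicting nothing; ties break toward the smaller threshold.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    if not np.all((np.asarray(grid) > 0) & (np.asarray(grid) < 1)):
        raise ValueError("thresholds must lie in (0, 1)")
    if not (acc.visit_count > 0).any():
        raise ValueError("accumulator is empty")
    mean = acc.mean()
    best_theta, best_count, best_mask = None, np.inf, None
    for theta in sorted(grid):
        mask = mean >= theta
        if not mask.any():
            count = np.inf
        else:
            count, _ = connected_components(mask, connectivity=8)
        if count < best_count:
            best_theta, best_count, best_mask = float(theta), count, mask
    if best_mask is None:  # every threshold gave an empty mask
        best_theta = float(sorted(grid)[0])
        best_mask = mean >= best_theta
    return best_theta, best_mask
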
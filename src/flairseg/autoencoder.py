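"""The segmentation model: a convolutional autoencoder with pooling indices.

Architecture (SegNet-style). The encoder is 7 convolutional layers (3x3,
ReLU) grouped into pooling blocks — default ``[2, 2, 3]`` — each block
ending in a 2x2 max-pool that *records its argmax indices*, for an overall
downsampling factor of 8. The decoder mirrors the encoder block-for-block:
each stage upsamples by placing values at the recorded indices of the
corresponding encoder pool (nonlinear unpooling), then convolves. A final
1x1 convolution and per-pixel 2-class softmax yield a 2-channel probability
image; channel 1 is "hyperintense lesion".

Seven convolutions cannot each be followed by 2x2 pooling on small training
tiles (the spatial extent would collapse), hence the grouping into 3 blocks
— the deepest hierarchy compatible with 10x10 tiles once reflect-padded to
16x16. Loss is computed only over the original tile region.

Training samples small 2-D regions of interest (default 10x10) from axial
slices, class-balanced between lesion-centred and background-brain-centred
tiles, and minimizes per-pixel cross-entropy by mini-batch SGD with
momentum. Inference runs whole axial slices fully convolutionally (the
network is convolutional, so any reflect-padded slice size works) and
reassembles a 3-D probability map on the input grid.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ModelConfigError,
    NoPositiveTilesError,
    TrainingDivergedError,
    UntrainedModelError,
)
from .nn import DT, Conv2D, MaxPool2x2, MaxUnpool2x2, ReLU, softmax2, softmax_xent_grad
from .phantom import Case
from .volumes import Volume

__all__ = [
    "ModelConfig",
    "RoiBatch",
    "TrainedModel",
    "build_model",
    "sample_rois",
    "train_model",
    "predict_volume",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``pooling_blocks`` groups the encoder convolutions into blocks, each
    ending in one 2x2 max-pool; its sum must equal ``n_encoder_convs``.
    The downsample factor is ``2 ** len(pooling_blocks)``.
    """

    n_encoder_convs: int = 7
    pooling_blocks: tuple[int, ...] = (2, 2, 3)
    filters_per_block: tuple[int, ...] = (16, 32, 64)
    kernel_size: int = 3
    n_classes: int = 2

    def __post_init__(self) -> None:
        if sum(self.pooling_blocks) != self.n_encoder_convs:
            raise ModelConfigError(
                f"sum(pooling_blocks)={sum(self.pooling_blocks)} != "
                f"n_encoder_convs={self.n_encoder_convs}"
            )
        if len(self.filters_per_block) != len(self.pooling_blocks):
            raise ModelConfigError("one filter count per pooling block required")
        if self.n_classes != 2:
            raise ModelConfigError("only 2-class segmentation is supported")

    @property
    def downsample(self) -> int:
        return 2 ** len(self.pooling_blocks)


@dataclass
class RoiBatch:
    """Aligned stacks of intensity tiles and binary label tiles.

    ``provenance[i] = (case_id, slice, row, col)`` records where tile ``i``
    was cut (row/col of the tile centre voxel).
    """

    patches: np.ndarray  # (N, t, t) float32
    labels: np.ndarray  # (N, t, t) uint8
    tile_size: int
    provenance: list[tuple[str, int, int, int]]

    def __post_init__(self) -> None:
        if self.patches.shape != self.labels.shape:
            raise ValueError("patches and labels must align one-to-one")
        if self.patches.shape[1:] != (self.tile_size, self.tile_size):
            raise ValueError("tiles must be tile_size x tile_size")

    def __len__(self) -> int:
        return self.patches.shape[0]


class TrainedModel:
    """Model weights plus everything inference needs (config, input scaling)."""

    def __init__(self, config: ModelConfig, seed: int):
        self.config = config
        self.seed = seed
        self.training_history: list[float] = []
        self.input_mean: float = 0.0
        self.input_std: float = 1.0
        rng = np.random.default_rng(seed)
        k = config.kernel_size
        self.enc_blocks: list[list] = []
        self.pools: list[MaxPool2x2] = []
        c_prev = 1
        for n_convs, c_out in zip(config.pooling_blocks, config.filters_per_block):
            block = []
            for _ in range(n_convs):
                block.append(Conv2D(c_prev, c_out, k, rng))
                block.append(ReLU())
                c_prev = c_out
            self.enc_blocks.append(block)
            self.pools.append(MaxPool2x2())
        # decoder mirrors the encoder: unpool then convs; the last conv of
        # each stage steps the channels down to the next (shallower) block
        self.unpools: list[MaxUnpool2x2] = []
        self.dec_blocks: list[list] = []
        filters = list(config.filters_per_block)
        for bi in reversed(range(len(filters))):
            self.unpools.append(MaxUnpool2x2())
            c_in = filters[bi]
            c_target = filters[bi - 1] if bi > 0 else filters[0]
            block = []
            n_convs = config.pooling_blocks[bi]
            for ci in range(n_convs):
                c_out = c_target if ci == n_convs - 1 else c_in
                block.append(Conv2D(c_in, c_out, k, rng))
                block.append(ReLU())
                c_in = c_out
            self.dec_blocks.append(block)
        self.classifier = Conv2D(filters[0], config.n_classes, 1, rng)
        self.trained = False

    # ---- parameter plumbing ------------------------------------------------

    def _layers_with_params(self) -> list[tuple[str, Conv2D]]:
        out = []
        for bi, block in enumerate(self.enc_blocks):
            for li, layer in enumerate(block):
                if isinstance(layer, Conv2D):
                    out.append((f"enc{bi}_{li}", layer))
        for bi, block in enumerate(self.dec_blocks):
            for li, layer in enumerate(block):
                if isinstance(layer, Conv2D):
                    out.append((f"dec{bi}_{li}", layer))
        out.append(("classifier", self.classifier))
        return out

    # ---- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Probabilities for a batch ``(N, H, W)``; returns ``(N, H, W, 2)``.

        H and W must be multiples of the downsample factor.
        """
        h, w = x.shape[1:3]
        ds = self.config.downsample
        if h % ds or w % ds:
            raise ValueError(f"spatial dims must be multiples of {ds}, got {h}x{w}")
        a = x[..., None].astype(DT)
        indices: list[np.ndarray] = []
        shapes: list[tuple] = []
        for block, pool in zip(self.enc_blocks, self.pools):
            for layer in block:
                a = layer.forward(a, train=train)
            shapes.append(a.shape)
            a, idx = pool.forward(a, train=train)
            indices.append(idx)
        for unpool, block in zip(self.unpools, self.dec_blocks):
            idx = indices.pop()
            shape = shapes.pop()
            a = unpool.forward(a, idx, shape, train=train)
            for layer in block:
                a = layer.forward(a, train=train)
        logits = self.classifier.forward(a, train=train)
        return softmax2(logits)

    def backward(self, dlogits: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        grads: dict[str, dict[str, np.ndarray]] = {}
        d, g = self.classifier.backward(dlogits)
        grads["classifier"] = g
        for bi_rev, (unpool, block) in reversed(list(enumerate(zip(self.unpools, self.dec_blocks)))):
            for li in reversed(range(len(block))):
                layer = block[li]
                if isinstance(layer, Conv2D):
                    d, g = layer.backward(d)
                    grads[f"dec{bi_rev}_{li}"] = g
                else:
                    d = layer.backward(d)
            d = unpool.backward(d)
            # careful: unpool i pairs with encoder block (n-1-i)
        for bi in reversed(range(len(self.enc_blocks))):
            d = self.pools[bi].backward(d)
            block = self.enc_blocks[bi]
            for li in reversed(range(len(block))):
                layer = block[li]
                if isinstance(layer, Conv2D):
                    d, g = layer.backward(d)
                    grads[f"enc{bi}_{li}"] = g
                else:
                    d = layer.backward(d)
        return grads


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> TrainedModel:
    """Construct an untrained model with seeded He-initialized weights."""
    return TrainedModel(cfg or ModelConfig(), seed)


# --------------------------------------------------------------------------
# ROI sampling
# --------------------------------------------------------------------------

def _extract_tile(plane: np.ndarray, r: int, c: int, t: int) -> np.ndarray:
    """Tile of size t x t centred at (r, c), reflect-padded at borders.

    The centre sits at offset ``(t - 1) // 2`` inside the tile.
    """
    off = (t - 1) // 2
    pad = t  # generous; cheap for small tiles
    padded = np.pad(plane, pad, mode="reflect")
    r0, c0 = r + pad - off, c + pad - off
    return padded[r0 : r0 + t, c0 : c0 + t]


def sample_rois(
    cases: list[Case],
    n_total: int,
    tile_size: int = 10,
    tumor_fraction: float = 0.5,
    seed: int = 0,
) -> RoiBatch:
    """Randomly sample class-balanced training tiles from axial slices.

    A ``tumor_fraction`` share of tiles is centred on lesion voxels, the rest
    on non-lesion brain voxels; label tiles are truth-mask crops. If a case
    has no lesion voxels its share shifts to the other cases.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= tumor_fraction <= 1):
        raise ValueError("tumor_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_tumor = int(round(n_total * tumor_fraction))

    # gather candidate centre voxels per class across the cohort
    pos_pool: list[tuple[int, np.ndarray]] = []  # (case index, (3, n) voxel coords)
    neg_pool: list[tuple[int, np.ndarray]] = []
    for ci, case in enumerate(cases):
        les = np.asarray(np.nonzero(case.truth.data))
        bg = np.asarray(np.nonzero(case.brain.data & ~case.truth.data))
        if les.shape[1]:
            pos_pool.append((ci, les))
        if bg.shape[1]:
            neg_pool.append((ci, bg))
    if n_tumor > 0 and not pos_pool:
        raise NoPositiveTilesError("no positive tiles available: cohort has no lesion voxels")
    if n_total - n_tumor > 0 and not neg_pool:
        raise ValueError("cohort has no background brain voxels")

    def draw(pool: list[tuple[int, np.ndarray]], n: int) -> list[tuple[int, int, int, int]]:
        weights = np.array([p[1].shape[1] for p in pool], dtype=float)
        weights /= weights.sum()
        picks = rng.choice(len(pool), size=n, p=weights)
        out = []
        for k in picks:
            ci, coords = pool[k]
            j = rng.integers(coords.shape[1])
            out.append((ci, int(coords[0, j]), int(coords[1, j]), int(coords[2, j])))
        return out

    centres = draw(pos_pool, n_tumor) if n_tumor else []
    centres += draw(neg_pool, n_total - n_tumor) if n_total - n_tumor else []

    patches = np.empty((n_total, tile_size, tile_size), dtype=DT)
    labels = np.empty((n_total, tile_size, tile_size), dtype=np.uint8)
    provenance = []
    for i, (ci, x, y, z) in enumerate(centres):
        case = cases[ci]
        patches[i] = _extract_tile(case.volume.data[:, :, z], x, y, tile_size)
        labels[i] = _extract_tile(case.truth.data[:, :, z].astype(np.uint8), x, y, tile_size)
        provenance.append((case.case_id, z, x, y))
    return RoiBatch(patches=patches, labels=labels, tile_size=tile_size, provenance=provenance)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _pad_to_multiple(x: np.ndarray, m: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad (N, H, W) so H and W are multiples of m; pad is centred."""
    h, w = x.shape[1:3]
    ph, pw = (-h) % m, (-w) % m
    top, left = ph // 2, pw // 2
    out = np.pad(x, ((0, 0), (top, ph - top), (left, pw - left)), mode="reflect")
    return out, (top, left)


def train_model(
    m: TrainedModel,
    rois: RoiBatch,
    epochs: int = 30,
    batch_size: int = 64,
    learning_rate: float = 1e-3,
    momentum: float = 0.9,
    seed: int = 0,
) -> TrainedModel:
    """Minimize mean per-pixel cross-entropy by mini-batch SGD with momentum.

    Tiles are reflect-padded up to the next multiple of the downsample
    factor; the loss counts only the original tile region. Inputs are
    z-scored with statistics of the training tiles, stored on the model so
    inference applies the identical scaling. Deterministic given the seed.
    """
    if len(rois) == 0:
        raise ValueError("empty ROI batch")
    rng = np.random.default_rng(seed)
    ds = m.config.downsample
    x_all, (top, left) = _pad_to_multiple(rois.patches.astype(DT), ds)
    t = rois.tile_size
    y_all = np.zeros(x_all.shape, dtype=np.uint8)
    weight = np.zeros(x_all.shape, dtype=DT)
    y_all[:, top : top + t, left : left + t] = rois.labels
    weight[:, top : top + t, left : left + t] = 1.0

    m.input_mean = float(x_all.mean())
    m.input_std = float(x_all.std() + 1e-8)
    x_all = (x_all - m.input_mean) / m.input_std

    velocity: dict[str, dict[str, np.ndarray]] = {
        name: {k: np.zeros_like(v) for k, v in layer.params().items()}
        for name, layer in m._layers_with_params()
    }
    n = x_all.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            sel = order[start : start + batch_size]
            xb, yb, wb = x_all[sel], y_all[sel], weight[sel]
            prob = m.forward(xb, train=True)
            loss, dlogits = softmax_xent_grad(prob, yb, wb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"training diverged at epoch {epoch}")
            grads = m.backward(dlogits)
            for name, layer in m._layers_with_params():
                p, g, v = layer.params(), grads[name], velocity[name]
                for k in p:
                    v[k] = momentum * v[k] - learning_rate * g[k]
                    p[k] += v[k]
            losses.append(loss)
        m.training_history.append(float(np.mean(losses)))
    m.trained = True
    return m


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def predict_volume(m: TrainedModel, v: Volume) -> "Volume":
    """Slice-wise fully convolutional inference.

    Each axial slice is reflect-padded to a multiple of the downsample
    factor, pushed through the network, and cropped back; the returned
    volume holds the tumor-class probability per voxel on ``v``'s grid.
    """
    if not m.trained:
        raise UntrainedModelError("model has no trained weights")
    if not np.all(np.isfinite(v.data)):
        raise ValueError("volume intensities must be finite")
    nx, ny, nz = v.data.shape
    slices = np.ascontiguousarray(np.moveaxis(v.data, 2, 0)).astype(DT)  # (nz, nx, ny)
    x, (top, left) = _pad_to_multiple(slices, m.config.downsample)
    x = (x - m.input_mean) / m.input_std
    prob = m.forward(x, train=False)[..., 1]
    prob = prob[:, top : top + nx, left : left + ny]
    out = np.moveaxis(prob, 0, 2)
    return v.with_data(np.clip(out, 0.0, 1.0).astype(np.float32))


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def save_model(m: TrainedModel, directory: str | os.PathLike) -> None:
    """Weights to ``weights.npz`` plus a JSON config sidecar."""
    os.makedirs(directory, exist_ok=True)
    arrays = {}
    for name, layer in m._layers_with_params():
        for k, arr in layer.params().items():
            arrays[f"{name}.{k}"] = arr
    np.savez(os.path.join(directory, "weights.npz"), **arrays)
    cfg = m.config
    meta = {
        "config": {
            "n_encoder_convs": cfg.n_encoder_convs,
            "pooling_blocks": list(cfg.pooling_blocks),
            "filters_per_block": list(cfg.filters_per_block),
            "kernel_size": cfg.kernel_size,
            "n_classes": cfg.n_classes,
        },
        "seed": m.seed,
        "trained": m.trained,
        "training_history": m.training_history,
        "input_mean": m.input_mean,
        "input_std": m.input_std,
    }
    with open(os.path.join(directory, "model.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(directory: str | os.PathLike) -> TrainedModel:
    with open(os.path.join(directory, "model.json")) as fh:
        meta = json.load(fh)
    c = meta["config"]
    cfg = ModelConfig(
        n_encoder_convs=c["n_encoder_convs"],
        pooling_blocks=tuple(c["pooling_blocks"]),
        filters_per_block=tuple(c["filters_per_block"]),
        kernel_size=c["kernel_size"],
        n_classes=c["n_classes"],
    )
    m = TrainedModel(cfg, meta["seed"])
    with np.load(os.path.join(directory, "weights.npz")) as npz:
        for name, layer in m._layers_with_params():
            for k in layer.params():
                layer.params()[k][...] = npz[f"{name}.{k}"]
    m.trained = meta["trained"]
    m.training_history = list(meta["training_history"])
    m.input_mean = meta["input_mean"]
    m.input_std = meta["input_std"]
    return m
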
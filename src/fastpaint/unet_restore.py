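"""U-Net restoration of sparse super-resolution reconstructions.

The network maps a sparsely-localized histogram image (optionally
concatenated with the matching widefield image as a second input channel)
to a dense reconstruction.  It is the classic encoder–decoder with skip
connections: each encoder stage is two 3x3 conv + ReLU blocks followed by
2x2 max pooling; the decoder mirrors it with nearest-neighbour upsampling,
a channel-halving convolution, concatenation with the skip feature map and
another double-conv; a final 1x1 convolution produces the single-channel
output.  Skip connections carry fine spatial detail past the bottleneck,
which matters here because the signal is a few-pixel-wide filament.

Training minimizes mean-squared error on intensities normalized to [0, 1]
(16-bit values divided by 65535) with Adam.  The implementation runs on
NumPy (see :mod:`fastpaint.nn`) and is fully deterministic given a seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from fastpaint.errors import ConfigError, ValidationError
from fastpaint.nn import Adam, Conv2d, MaxPool2, ReLU, Upsample2

logger = logging.getLogger(__name__)

#: 16-bit intensity scale used to normalize network inputs/targets
NORM = 65535.0


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the restoration U-Net.

    ``in_channels`` is 1 (sparse image only) or 2 (sparse + widefield);
    ``depth`` is the number of downsampling stages; ``base_width`` the
    number of feature maps at full resolution; ``tile_size`` the square
    input side (must be divisible by ``2**depth``; 256 and 512 are the
    standard sizes, smaller powers of two serve reduced-scale runs).
    """

    in_channels: int = 1
    depth: int = 4
    base_width: int = 64
    tile_size: int = 256

    def __post_init__(self):
        if self.in_channels not in (1, 2):
            raise ConfigError(f"in_channels must be 1 or 2, got {self.in_channels}")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if self.tile_size % (2**self.depth) != 0:
            raise ConfigError(
                f"tile_size {self.tile_size} is not divisible by 2**depth = {2**self.depth}"
            )


@dataclass
class TrainConfig:
    """Training hyper-parameters and provenance paths."""

    epoch_num: int = 200
    train_data_path: str | None = None
    model_load: str | None = None
    model_save: str | None = None
    loss: str = "mse"
    learning_rate: float = 1e-4
    batch_size: int = 4
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.epoch_num <= 2000):
            raise ConfigError(f"epoch_num must be in [1, 2000], got {self.epoch_num}")
        if self.loss != "mse":
            raise ConfigError(f"unsupported loss {self.loss!r}")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")


class _UNet:
    """Bare encoder–decoder; layers and wiring only."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator, dtype=np.float32):
        self.config = config
        self.dtype = np.dtype(dtype)
        c, d, b = config.in_channels, config.depth, config.base_width

        def double_conv(cin, cout):
            return [Conv2d(cin, cout, 3, rng, dtype=dtype), ReLU(),
                    Conv2d(cout, cout, 3, rng, dtype=dtype), ReLU()]

        self.enc = []
        cin = c
        for i in range(d):
            cout = b * 2**i
            self.enc.append(double_conv(cin, cout))
            cin = cout
        self.bottleneck = double_conv(cin, b * 2**d)
        self.up = Upsample2()
        self.dec_reduce = []  # channel-halving conv after upsampling
        self.dec = []
        cin = b * 2**d
        for i in reversed(range(d)):
            cout = b * 2**i
            self.dec_reduce.append(Conv2d(cin, cout, 3, rng, dtype=dtype))
            self.dec.append(double_conv(2 * cout, cout))
            cin = cout
        self.head = Conv2d(cin, 1, 1, rng, dtype=dtype)

    def layers(self):
        out = []
        for block in self.enc:
            out.extend(block)
        out.extend(self.bottleneck)
        for reduce, block in zip(self.dec_reduce, self.dec):
            out.append(reduce)
            out.extend(block)
        out.append(self.head)
        return out

    def conv_layers(self):
        return [l for l in self.layers() if isinstance(l, Conv2d)]

    @staticmethod
    def _run(block, x):
        for layer in block:
            x = layer.forward(x)
        return x

    @staticmethod
    def _run_back(block, g):
        for layer in reversed(block):
            g = layer.backward(g)
        return g

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        self._pools = []
        for block in self.enc:
            x = self._run(block, x)
            skips.append(x)
            pool = MaxPool2()
            x = pool.forward(x)
            self._pools.append(pool)
        x = self._run(self.bottleneck, x)
        self._skip_channels = []
        for reduce, block, skip in zip(self.dec_reduce, self.dec, reversed(skips)):
            x = self.up.forward(x)
            x = reduce.forward(x)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = self._run(block, x)
        self._n_skips = len(skips)
        return self.head.forward(x)

    def backward(self, g: np.ndarray) -> None:
        g = self.head.backward(g)
        skip_grads = []
        for reduce, block, nskip in zip(
            reversed(self.dec_reduce), reversed(self.dec), reversed(self._skip_channels)
        ):
            g = self._run_back(block, g)
            skip_grads.append(g[:, :nskip])
            g = g[:, nskip:]
            g = reduce.backward(g)
            g = self.up.backward(g)
        g = self._run_back(self.bottleneck, g)
        # skip_grads[i] is the gradient w.r.t. encoder stage i's output
        for block, pool, sg in zip(reversed(self.enc), reversed(self._pools), reversed(skip_grads)):
            g = pool.backward(g)
            g = g + sg
            g = self._run_back(block, g)


@dataclass
class RestorationModel:
    """Architecture config + learned weights + training provenance."""

    config: ModelConfig
    net: _UNet
    provenance: dict = field(default_factory=dict)


def build_model(config: ModelConfig, seed: int = 0, dtype=np.float32) -> RestorationModel:
    """Initialize a U-Net deterministically from a seed.

    ``dtype`` selects the working precision; single precision is the
    default (twice the GEMM throughput), double is useful for gradient
    checking.
    """
    rng = np.random.default_rng(seed)
    net = _UNet(config, rng, dtype=dtype)
    return RestorationModel(config=config, net=net, provenance={"init_seed": int(seed)})


def save_model(model: RestorationModel, path) -> None:
    """Serialize a model to a self-describing .npz checkpoint."""
    arrays = {}
    for i, layer in enumerate(model.net.conv_layers()):
        arrays[f"w{i}"] = layer.weight
        arrays[f"b{i}"] = layer.bias
    meta = json.dumps({"config": asdict(model.config), "provenance": model.provenance})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> RestorationModel:
    """Load a checkpoint written by :func:`save_model`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = ModelConfig(**meta["config"])
        model = build_model(config, seed=meta["provenance"].get("init_seed", 0))
        for i, layer in enumerate(model.net.conv_layers()):
            layer.weight = data[f"w{i}"].copy()
            layer.bias = data[f"b{i}"].copy()
    model.provenance = meta["provenance"]
    return model


def _tile_inputs(tile, in_channels: int) -> np.ndarray:
    sparse = np.asarray(tile["sparse"], dtype=np.float64) / NORM
    if in_channels == 1:
        return sparse[None]
    if "widefield" not in tile.images:
        raise ConfigError(
            "2-channel model needs a widefield member in every tile "
            "(widefield-conditioned training)"
        )
    wf = np.asarray(tile["widefield"], dtype=np.float64) / NORM
    return np.stack([sparse, wf])


def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


def train(model: RestorationModel, tileset, config: TrainConfig) -> RestorationModel:
    """Train a restoration model on the ``train`` tiles of a tile set.

    Runs exactly ``epoch_num`` epochs of Adam on MSE between the network
    output and the normalized ground truth.  Per-epoch losses are logged
    and recorded in the model provenance; if ``model_save`` is set, a
    checkpoint is written at the end.  ``model_load`` warm-starts from an
    earlier checkpoint.  Fully deterministic given ``config.seed``.
    """
    if config.model_load:
        loaded = load_model(config.model_load)
        if loaded.config != model.config:
            raise ConfigError("warm-start checkpoint architecture differs from the model's")
        model = loaded
    tiles = tileset.subset("train") if hasattr(tileset, "subset") else list(tileset)
    if not tiles:
        tiles = list(tileset)
    if not tiles:
        raise ValidationError("no training tiles")
    size = tiles[0]["sparse"].shape
    if size != (model.config.tile_size, model.config.tile_size):
        raise ConfigError(
            f"tile shape {size} does not match model tile_size {model.config.tile_size}"
        )
    dt = model.net.dtype
    inputs = np.stack([_tile_inputs(t, model.config.in_channels) for t in tiles]).astype(dt)
    targets = np.stack(
        [np.asarray(t["ground_truth"], dtype=np.float64)[None] / NORM for t in tiles]
    ).astype(dt)
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.net.conv_layers(), lr=config.learning_rate)
    losses = []
    n = len(tiles)
    for epoch in range(config.epoch_num):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            pred = model.net.forward(inputs[idx])
            loss, grad = mse_loss(pred, targets[idx])
            model.net.backward(grad)
            optimizer.step()
            epoch_loss += loss * len(idx)
        epoch_loss /= n
        losses.append(epoch_loss)
        logger.info("epoch %d/%d: train MSE %.3e", epoch + 1, config.epoch_num, epoch_loss)
    model.provenance.update(
        {
            "epochs_completed": model.provenance.get("epochs_completed", 0) + config.epoch_num,
            "final_loss": losses[-1],
            "losses": losses,
            "train_seed": int(config.seed),
            "n_train_tiles": n,
        }
    )
    if config.model_save:
        save_model(model, config.model_save)
    return model


def evaluate_loss(model: RestorationModel, tileset) -> float:
    """Mean MSE of the current model over a tile collection (no updates)."""
    tiles = list(tileset)
    total = 0.0
    for t in tiles:
        x = _tile_inputs(t, model.config.in_channels)[None].astype(model.net.dtype)
        target = np.asarray(t["ground_truth"], dtype=np.float64)[None, None] / NORM
        pred = model.net.forward(x)
        total += float(np.mean((pred - target) ** 2))
    return total / len(tiles)


def predict(model: RestorationModel, sparse_tile, widefield_tile=None) -> np.ndarray:
    """Restore one tile; returns a 16-bit image on the input grid.

    A 2-channel model requires ``widefield_tile`` pre-scaled to the
    super-resolution grid (the widefield image must be scaled 16x to match
    the reconstruction before prediction).
    """
    sparse = np.asarray(sparse_tile, dtype=np.float64)
    t = model.config.tile_size
    if sparse.shape != (t, t):
        raise ValidationError(f"sparse tile shape {sparse.shape} != model tile size ({t}, {t})")
    if model.config.in_channels == 2:
        if widefield_tile is None:
            raise ValueError(
                "this model was trained with widefield conditioning; supply the "
                "matching widefield tile (the widefield variant of prediction)"
            )
        wf = np.asarray(widefield_tile, dtype=np.float64)
        if wf.shape != sparse.shape:
            raise ValidationError(
                f"widefield tile shape {wf.shape} does not match the super-resolution "
                f"grid {sparse.shape}; widefield images must be scaled 16 times "
                "(block-upscaled) to match reconstructed images before prediction"
            )
        x = np.stack([sparse / NORM, wf / NORM])[None]
    else:
        if widefield_tile is not None:
            raise ValueError("model has a single input channel; widefield_tile not accepted")
        x = (sparse / NORM)[None, None]
    out = model.net.forward(x.astype(model.net.dtype))[0, 0].astype(np.float64)
    return np.clip(np.rint(out * NORM), 0, 65535).astype(np.uint16)


def stitch_tiles(tiles, origins) -> np.ndarray:
    """Amalgamate predicted tiles into one panoramic image.

    ``origins`` are (row, col) top-left coordinates.  Non-overlapping
    placements are bit-exact copies; where tiles overlap, values are
    averaged (and rounded back to 16-bit).
    """
    tiles = [np.asarray(t) for t in tiles]
    if not tiles:
        raise ValueError("no tiles to stitch")
    shapes = {t.shape for t in tiles}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent tile shapes: {sorted(shapes)}")
    th, tw = tiles[0].shape
    h = max(r for r, _ in origins) + th
    w = max(c for _, c in origins) + tw
    acc = np.zeros((h, w), dtype=np.float64)
    weight = np.zeros((h, w), dtype=np.float64)
    for tile, (r, c) in zip(tiles, origins):
        acc[r : r + th, c : c + tw] += tile
        weight[r : r + th, c : c + tw] += 1.0
    out = np.divide(acc, weight, out=np.zeros_like(acc), where=weight > 0)
    return np.clip(np.rint(out), 0, 65535).astype(np.uint16)
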
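"""Tiling, content filtering and train/test splitting of registered images.

Training pairs come from large registered reconstructions that are cut into
square tiles (typically 256 or 512 pixels; smaller powers of two are
accepted for reduced-scale runs).  The same non-overlapping grid, anchored
at the image origin, is applied to every member of a group (sparse, ground
truth, optional widefield) so pixel-level correspondence is preserved;
partial tiles at the right/bottom edges are dropped.  Tiles whose ground
truth is essentially empty are filtered out — an automated, reproducible
surrogate for the visual curation a human would do — and the survivors are
split 95/5 into training and testing sets, with a hard floor on the number
of training pairs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from fastpaint.errors import DatasetTooSmallError, RegistrationError
from fastpaint.renderer import RenderedImage, save_tiff

logger = logging.getLogger(__name__)

STANDARD_TILE_SIZES = (256, 512)

#: minimum number of training pairs a usable dataset must provide
MIN_TRAIN_PAIRS = 200

#: default fraction of tiles held out for testing
TEST_FRACTION = 0.05


@dataclass
class TileGroup:
    """Pixel-aligned tiles cut from the same source location."""

    images: dict  # role -> 2D array; must contain 'sparse' and 'ground_truth'
    origin: tuple  # (row, col) of the tile's top-left corner in the source
    split: str | None = None  # 'train' | 'test' | None

    def __getitem__(self, role: str) -> np.ndarray:
        return self.images[role]

    @property
    def roles(self) -> tuple:
        return tuple(sorted(self.images))


@dataclass
class TileSet:
    """A collection of tile groups sharing one tile size."""

    tiles: list
    tile_size: int
    source_shape: tuple | None = None

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)

    def subset(self, split: str) -> list:
        return [t for t in self.tiles if t.split == split]


def _as_array(img) -> np.ndarray:
    if isinstance(img, RenderedImage):
        return img.pixels
    return np.asarray(img)


def crop_tiles(image_group: dict, tile_size: int) -> TileSet:
    """Cut a registered image group into a non-overlapping grid of tiles.

    ``image_group`` maps roles (``sparse``, ``ground_truth``, optionally
    ``widefield``) to 2D arrays of identical shape.  The grid is anchored at
    (0, 0); partial tiles are dropped rather than padded, so an H x W source
    yields ``floor(H/t) * floor(W/t)`` groups.

    Raises
    ------
    RegistrationError
        If members of the group differ in shape — pairs must be in
        one-to-one pixel correspondence and any deviation must be corrected
        upstream.
    """
    if tile_size < 1:
        raise ValueError(f"tile_size must be positive, got {tile_size}")
    if tile_size not in STANDARD_TILE_SIZES:
        logger.info("non-standard tile size %d (standard sizes: %s)", tile_size, STANDARD_TILE_SIZES)
    arrays = {role: _as_array(img) for role, img in image_group.items()}
    if "ground_truth" not in arrays or "sparse" not in arrays:
        raise ValueError("image group needs at least 'ground_truth' and 'sparse' members")
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise RegistrationError(
            f"image group members are not registered: shapes {sorted(shapes)}"
        )
    (h, w) = next(iter(shapes))
    tiles = []
    for r0 in range(0, h - tile_size + 1, tile_size):
        for c0 in range(0, w - tile_size + 1, tile_size):
            images = {
                role: a[r0 : r0 + tile_size, c0 : c0 + tile_size].copy()
                for role, a in arrays.items()
            }
            tiles.append(TileGroup(images=images, origin=(r0, c0)))
    return TileSet(tiles=tiles, tile_size=tile_size, source_shape=(h, w))


def nonzero_fraction(tile: np.ndarray) -> float:
    """Fraction of pixels carrying any signal."""
    return float(np.count_nonzero(tile)) / tile.size


def filter_tiles(tileset: TileSet, min_content_fraction: float = 0.002) -> TileSet:
    """Drop tiles whose ground truth carries (almost) no structure.

    A tile is kept iff the nonzero-pixel fraction of its ground-truth member
    is at least ``min_content_fraction`` (default 0.2%).  Idempotent;
    removals are logged with their source origins.
    """
    kept, removed = [], []
    for tile in tileset:
        if nonzero_fraction(tile["ground_truth"]) >= min_content_fraction:
            kept.append(tile)
        else:
            removed.append(tile.origin)
    if removed:
        logger.info("filter_tiles removed %d near-empty tiles at origins %s", len(removed), removed)
    return TileSet(tiles=kept, tile_size=tileset.tile_size, source_shape=tileset.source_shape)


def split_dataset(
    tileset: TileSet,
    test_fraction: float = TEST_FRACTION,
    min_train_pairs: int = MIN_TRAIN_PAIRS,
    rng: np.random.Generator | None = None,
) -> TileSet:
    """Label tiles train/test: 5% (rounded) test, the rest train.

    The test set is drawn uniformly without replacement with the supplied
    generator.  If the resulting training set has fewer than
    ``min_train_pairs`` members the dataset is rejected — reliable training
    needs at least 200 pairs (1000+ is preferable).

    Raises
    ------
    DatasetTooSmallError
        If the training split would fall below ``min_train_pairs``.
    """
    n = len(tileset)
    if n == 0:
        raise ValueError("cannot split an empty tile set")
    if not (0.0 <= test_fraction < 1.0):
        raise ValueError(f"test_fraction must be in [0, 1), got {test_fraction}")
    if rng is None:
        rng = np.random.default_rng()
    n_test = int(round(test_fraction * n))
    n_train = n - n_test
    if n_train < min_train_pairs:
        raise DatasetTooSmallError(
            f"training split would have {n_train} pairs; at least "
            f"{min_train_pairs} pairs of cropped images are required"
        )
    test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
    tiles = []
    for i, tile in enumerate(tileset):
        tiles.append(
            TileGroup(
                images=tile.images,
                origin=tile.origin,
                split="test" if i in test_idx else "train",
            )
        )
    return TileSet(tiles=tiles, tile_size=tileset.tile_size, source_shape=tileset.source_shape)


def write_tileset(tileset: TileSet, output_dir) -> dict:
    """Write split tiles as TIFFs under ``train/`` and ``test/`` + manifest."""
    output_dir = Path(output_dir)
    entries = []
    for i, tile in enumerate(tileset):
        split = tile.split or "train"
        sub = output_dir / split / f"tile_{i:05d}"
        sub.mkdir(parents=True, exist_ok=True)
        for role, arr in tile.images.items():
            save_tiff(np.asarray(arr, dtype=np.uint16), sub / f"{role}.tif")
        entries.append(
            {"index": i, "split": split, "origin": list(tile.origin), "roles": list(tile.roles), "dir": f"{split}/{sub.name}"}
        )
    manifest = {"tile_size": tileset.tile_size, "tiles": entries}
    with open(output_dir / "split_manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest
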
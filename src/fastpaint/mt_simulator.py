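"""Synthetic microtubule fields for training the restoration network.

Real training data would require paired sparse / dense DNA-PAINT
reconstructions of the same cells.  Simulation sidesteps that: microtubules
are drawn as smooth random curves (a discrete worm-like chain with Gaussian
turning angles, spline-smoothed), decorated with localizations at a chosen
linear density plus isotropic Gaussian localization error, and rendered
three ways to form one training unit:

``ground-truth.tif``
    histogram render of the full localization set on the 16x oversampled
    super-resolution grid;
``sparsely-localized.tif``
    the same render after binomial thinning — each localization is kept
    independently with probability ``sparsity``, emulating a short
    acquisition that catches only a fraction of the binding events;
``widefield.tif``
    the full emitter set binned at camera resolution, blurred with a
    Gaussian PSF and block-upscaled to the super-resolution grid, emulating
    the diffraction-limited image of the fully labeled structure.

Everything is driven by a :class:`SimulationConfig` plus a seed; a dataset
is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep

from fastpaint.errors import ConfigError
from fastpaint.localization_io import LocalizationTable, make_table
from fastpaint.renderer import (
    RenderConfig,
    RenderedImage,
    render_counts,
    save_tiff,
    upscale_widefield,
)

GROUND_TRUTH_NAME = "ground-truth.tif"
WIDEFIELD_NAME = "widefield.tif"
SPARSE_NAME = "sparsely-localized.tif"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the microtubule simulator.

    Parameters
    ----------
    structure_dense : int
        Average number of microtubules per image (Poisson mean, clamped to
        at least one filament).
    sparsity : float in (0, 1]
        Ratio of localizations in the sparse image to those in the ground
        truth (binomial keep probability).
    dataset_size : int
        Number of image triplets to generate.
    image_size : int
        Side of the square super-resolution images in SR pixels (default
        256); must be divisible by ``oversampling``.
    oversampling : int
        Super-resolution pixels per camera pixel (default 16).
    step_length : float
        Arc-length step of the discrete worm-like chain, camera pixels.
    curvature_sigma : float
        Standard deviation of the Gaussian turning angle per step
        (radians); small values give straight, stiff filaments.
    length_range : (float, float) or None
        Contour length range in camera pixels; ``None`` defaults to
        0.5–1.5 field-of-view side lengths.
    localization_density : float
        Expected localizations per camera pixel of filament length.
    localization_sigma : float
        Isotropic localization error, camera pixels (default one SR pixel,
        1/16 camera pixel).
    widefield_psf_sigma : float
        Gaussian PSF sigma of the widefield channel, camera pixels.
    intensity_scale : float
        Linear gain mapping localization counts to 16-bit intensities in
        the ground-truth and sparse images (clipped at 65535).  Real
        rendered training images are 16-bit with display-scaled contrast;
        leaving raw counts of order 1 in a 16-bit container would collapse
        both training contrast and the metric dynamic range.
    widefield_peak : float
        16-bit intensity of the brightest widefield pixel (per-image
        normalization, emulating exposure/display scaling of the
        diffraction-limited channel).
    n_frames : int
        Nominal movie length used to assign frame indices (conventional
        acquisition budget, 30,000 frames), enabling frame-subset
        experiments on simulated tables.
    mean_photons : float
        Mean of the exponential photon-count distribution per event.
    seed : int
        Master seed of the dataset.
    """

    structure_dense: int = 8
    sparsity: float = 0.1
    dataset_size: int = 1
    image_size: int = 256
    oversampling: int = 16
    step_length: float = 0.25
    curvature_sigma: float = 0.12
    length_range: tuple | None = None
    localization_density: float = 60.0
    localization_sigma: float = 1.0 / 16.0
    widefield_psf_sigma: float = 1.3
    intensity_scale: float = 4000.0
    widefield_peak: float = 30000.0
    n_frames: int = 30000
    mean_photons: float = 5000.0
    seed: int = 0

    def __post_init__(self):
        if self.structure_dense < 1:
            raise ConfigError(f"structure_dense must be >= 1, got {self.structure_dense}")
        if not (0.0 < self.sparsity <= 1.0):
            raise ConfigError(f"sparsity must be in (0, 1], got {self.sparsity}")
        if self.dataset_size < 1:
            raise ConfigError(f"dataset_size must be >= 1, got {self.dataset_size}")
        if self.image_size % self.oversampling != 0:
            raise ConfigError(
                f"image_size {self.image_size} is not divisible by oversampling {self.oversampling}"
            )

    @property
    def fov_side(self) -> int:
        """Camera-pixel side length of the simulated field of view."""
        return self.image_size // self.oversampling

    def resolved_length_range(self) -> tuple[float, float]:
        if self.length_range is not None:
            lo, hi = self.length_range
            return float(lo), float(hi)
        return 0.5 * self.fov_side, 1.5 * self.fov_side


@dataclass
class Filament:
    """An open curve in camera-pixel coordinates (ordered points)."""

    points: np.ndarray  # (M, 2) float64, columns (x, y)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("a filament needs at least two (x, y) points")

    @property
    def contour_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def end_to_end_distance(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass
class ImageTriplet:
    """Pixel-aligned (ground truth, widefield, sparse) training unit."""

    ground_truth: RenderedImage
    widefield: RenderedImage
    sparse: RenderedImage
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {self.ground_truth.shape, self.widefield.shape, self.sparse.shape}
        if len(shapes) != 1:
            raise ValueError(f"triplet images are not pixel-aligned: shapes {shapes}")


def _reflect(values: np.ndarray, side: float) -> np.ndarray:
    """Fold coordinates into [0, side] by mirror reflection at the walls."""
    m = np.mod(values, 2.0 * side)
    return np.where(m > side, 2.0 * side - m, m)


def _smooth_spline(points: np.ndarray) -> np.ndarray:
    """Cubic-spline smooth a polyline (keeps endpoint count)."""
    if len(points) < 10:
        return points
    sub = points[::4]
    if not np.array_equal(sub[-1], points[-1]):
        sub = np.vstack([sub, points[-1]])
    # splprep rejects consecutive duplicates (zero-length parameter steps)
    keep = np.ones(len(sub), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(sub, axis=0), axis=1) > 1e-9
    sub = sub[keep]
    if len(sub) < 4:
        return points
    try:
        tck, _ = splprep([sub[:, 0], sub[:, 1]], s=0.0, k=3)
    except (ValueError, TypeError):
        return points
    u = np.linspace(0.0, 1.0, len(points))
    x, y = splev(u, tck)
    return np.column_stack([x, y])


def sample_filaments(config: SimulationConfig, rng: np.random.Generator) -> list[Filament]:
    """Draw one image's worth of filaments.

    The filament count is Poisson with mean ``structure_dense`` (at least
    one); each filament is a fixed-step random walk with Gaussian turning
    angles, reflected at the FOV walls, spline-smoothed and clipped to the
    field of view.
    """
    side = float(config.fov_side)
    lo, hi = config.resolved_length_range()
    n_filaments = max(1, int(rng.poisson(config.structure_dense)))
    filaments = []
    for _ in range(n_filaments):
        length = rng.uniform(lo, hi)
        n_steps = max(2, int(round(length / config.step_length)))
        start = rng.uniform(0.0, side, size=2)
        theta0 = rng.uniform(0.0, 2.0 * np.pi)
        dtheta = rng.normal(0.0, config.curvature_sigma, size=n_steps)
        theta = theta0 + np.cumsum(dtheta)
        steps = config.step_length * np.column_stack([np.cos(theta), np.sin(theta)])
        pts = np.vstack([start, start + np.cumsum(steps, axis=0)])
        pts[:, 0] = _reflect(pts[:, 0], side)
        pts[:, 1] = _reflect(pts[:, 1], side)
        pts = _smooth_spline(pts)
        pts = np.clip(pts, 0.0, np.nextafter(side, 0.0))
        filaments.append(Filament(pts))
    return filaments


def sample_localizations(
    filaments: list[Filament],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> LocalizationTable:
    """Decorate filaments with localizations.

    Counts are Poisson (mean = density x contour length); positions are
    uniform along arc length with isotropic Gaussian jitter of
    ``localization_sigma``; jittered points that leave the FOV are dropped.
    Frame indices are uniform over the nominal movie length and photon
    counts exponential.
    """
    side = float(config.fov_side)
    xs, ys = [], []
    for fil in filaments:
        seg = np.linalg.norm(np.diff(fil.points, axis=0), axis=1)
        total = float(seg.sum())
        n = int(rng.poisson(config.localization_density * total)) if total > 0 else 0
        if n == 0:
            continue
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        t = rng.uniform(0.0, total, size=n)
        x = np.interp(t, cum, fil.points[:, 0])
        y = np.interp(t, cum, fil.points[:, 1])
        jitter = rng.normal(0.0, config.localization_sigma, size=(n, 2))
        xs.append(x + jitter[:, 0])
        ys.append(y + jitter[:, 1])
    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        inside = (x >= 0) & (x < side) & (y >= 0) & (y < side)
        x, y = x[inside], y[inside]
    else:
        x = y = np.empty(0)
    n = len(x)
    frames = rng.integers(0, config.n_frames, size=n)
    photons = rng.exponential(config.mean_photons, size=n)
    return make_table(
        frames, x, y, photons,
        fov_width=config.fov_side, fov_height=config.fov_side,
        n_frames_total=config.n_frames,
    )


def thin_localizations(
    table: LocalizationTable, sparsity: float, rng: np.random.Generator
) -> LocalizationTable:
    """Binomial thinning: keep each record independently with prob ``sparsity``."""
    if not (0.0 <= sparsity <= 1.0):
        raise ValueError(f"sparsity must be in [0, 1], got {sparsity}")
    if sparsity == 1.0:
        kept = table.locs
    else:
        mask = rng.random(len(table)) < sparsity
        kept = table.locs[mask]
    return LocalizationTable(kept, table.fov_width, table.fov_height, table.n_frames_total)


def make_triplet(config: SimulationConfig, rng: np.random.Generator) -> ImageTriplet:
    """Simulate one (ground truth, widefield, sparse) image triplet."""
    filaments = sample_filaments(config, rng)
    full = sample_localizations(filaments, config, rng)
    thinned = thin_localizations(full, config.sparsity, rng)

    render_cfg = RenderConfig(oversampling=config.oversampling)
    g = config.intensity_scale

    def scaled(table, role):
        counts = render_counts(table, render_cfg)
        pixels = np.clip(counts * g, 0, 65535).astype(np.uint16)
        return RenderedImage(pixels, grid_scale=config.oversampling, role=role)

    gt = scaled(full, "ground_truth")
    sparse = scaled(thinned, "sparse")

    # Widefield sees every fluorophore: bin the FULL set at camera
    # resolution, blur with the PSF, normalize the peak, then replicate
    # onto the SR grid.
    cam = render_counts(full, RenderConfig(oversampling=1)).astype(np.float64)
    blurred = ndimage.gaussian_filter(cam, sigma=config.widefield_psf_sigma)
    peak = blurred.max()
    if peak > 0:
        blurred *= config.widefield_peak / peak
    wf_cam = np.clip(np.rint(blurred), 0, 65535).astype(np.uint16)
    widefield = upscale_widefield(wf_cam, factor=config.oversampling)

    provenance = {
        "config": asdict(config),
        "n_filaments": len(filaments),
        "n_localizations_full": len(full),
        "n_localizations_sparse": len(thinned),
        "contour_lengths": [f.contour_length for f in filaments],
    }
    return ImageTriplet(gt, widefield, sparse, provenance)


def config_hash(config: SimulationConfig) -> str:
    """Stable short hash of a configuration (for manifests)."""
    payload = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def generate_dataset(config: SimulationConfig, output_dir) -> dict:
    """Write ``dataset_size`` triplets as TIFFs plus a JSON manifest.

    Each image gets its own child seed derived from ``config.seed``, so any
    single triplet can be regenerated without re-running the whole dataset.
    Returns the manifest (also written to ``manifest.json``).
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(config.dataset_size)
    seeds = (seeds & 0x7FFFFFFF).astype(np.int64)
    images = []
    for i, seed_i in enumerate(seeds):
        rng = np.random.default_rng(int(seed_i))
        triplet = make_triplet(config, rng)
        sub = output_dir / f"img_{i:04d}"
        sub.mkdir(exist_ok=True)
        save_tiff(triplet.ground_truth, sub / GROUND_TRUTH_NAME)
        save_tiff(triplet.widefield, sub / WIDEFIELD_NAME)
        save_tiff(triplet.sparse, sub / SPARSE_NAME)
        images.append(
            {
                "index": i,
                "seed": int(seed_i),
                "dir": sub.name,
                "n_filaments": triplet.provenance["n_filaments"],
                "n_localizations_full": triplet.provenance["n_localizations_full"],
                "n_localizations_sparse": triplet.provenance["n_localizations_sparse"],
            }
        )
    manifest = {
        "config": asdict(config),
        "config_hash": config_hash(config),
        "images": images,
    }
    with open(output_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, default=list)
    return manifest
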
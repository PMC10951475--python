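"""Simulator statistics: filament geometry, localization sampling, thinning."""

import json

import numpy as np
import pytest
from scipy import ndimage

from fastpaint.errors import ConfigError
from fastpaint.localization_io import make_table
from fastpaint.mt_simulator import (
    Filament,
    SimulationConfig,
    generate_dataset,
    make_triplet,
    sample_filaments,
    sample_localizations,
    thin_localizations,
)

SMALL = dict(image_size=64, structure_dense=4)


class TestFilaments:
    def test_fixed_seed_reproducible(self):
        cfg = SimulationConfig(**SMALL)
        a = sample_filaments(cfg, np.random.default_rng(7))
        b = sample_filaments(cfg, np.random.default_rng(7))
        assert len(a) == len(b)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.points, fb.points)

    def test_count_mean_matches_structure_dense(self):
        """Empirical filament count over 500 images within 3 SE of the mean."""
        cfg = SimulationConfig(structure_dense=8, image_size=64)
        rng = np.random.default_rng(42)
        counts = [len(sample_filaments(cfg, rng)) for _ in range(500)]
        # Poisson(8) clamped at >=1; the clamp is negligible at mean 8
        se = np.sqrt(8 / 500)
        assert abs(np.mean(counts) - 8) < 3 * se

    def test_stiff_limit_is_straight(self):
        """Near-zero turning noise gives near-straight filaments (away from walls)."""
        cfg = SimulationConfig(
            image_size=256, curvature_sigma=1e-4, structure_dense=5, length_range=(3.0, 5.0)
        )
        rng = np.random.default_rng(3)
        side = cfg.fov_side
        unreflected = []
        for _ in range(30):
            for fil in sample_filaments(cfg, rng):
                # reflected walks always leave a point near the wall (within one
                # step, plus spline corner-cutting) — a 1 px margin excludes them
                margin = 1.0
                if fil.points.min() > margin and fil.points.max() < side - margin:
                    unreflected.append(fil)
        assert len(unreflected) > 20
        for fil in unreflected:
            assert fil.end_to_end_distance / fil.contour_length > 0.95

    def test_points_stay_inside_fov(self):
        cfg = SimulationConfig(**SMALL, curvature_sigma=0.5)
        for fil in sample_filaments(cfg, np.random.default_rng(11)):
            side = cfg.fov_side
            assert fil.points.min() >= 0
            assert fil.points.max() < side


class TestLocalizations:
    def _straight_filament(self, y=8.0, x0=2.0, x1=14.0):
        xs = np.linspace(x0, x1, 200)
        return Filament(np.column_stack([xs, np.full_like(xs, y)]))

    def test_zero_density_gives_empty_table(self):
        cfg = SimulationConfig(localization_density=0.0)
        table = sample_localizations([self._straight_filament()], cfg, np.random.default_rng(0))
        assert len(table) == 0

    def test_jitter_sigma_recovered(self):
        """Transverse sd of a straight filament's localizations ~ sigma."""
        sigma = 1.0 / 16.0
        cfg = SimulationConfig(localization_density=1000.0, localization_sigma=sigma)
        table = sample_localizations([self._straight_filament()], cfg, np.random.default_rng(5))
        assert len(table) > 10000
        sd = np.std(table.locs["y"].astype(np.float64) - 8.0)
        assert abs(sd - sigma) / sigma < 0.05

    def test_poisson_count_mean(self):
        """Mean localization count over 200 draws within 3 SE of density*length."""
        fil = self._straight_filament()
        cfg = SimulationConfig(localization_density=20.0, localization_sigma=0.01)
        rng = np.random.default_rng(9)
        counts = [len(sample_localizations([fil], cfg, rng)) for _ in range(200)]
        expected = 20.0 * fil.contour_length
        se = np.sqrt(expected / 200)
        assert abs(np.mean(counts) - expected) < 3 * se


class TestThinning:
    def test_sparsity_one_is_identity(self, rng):
        table = _table(rng, 500)
        np.testing.assert_array_equal(thin_localizations(table, 1.0, rng).locs, table.locs)

    def test_sparsity_zero_empties(self, rng):
        assert len(thin_localizations(_table(rng, 500), 0.0, rng)) == 0

    def test_binomial_bound_at_ten_percent(self, rng):
        table = _table(rng, 10000)
        kept = len(thin_localizations(table, 0.1, rng))
        assert abs(kept - 1000) <= 3 * np.sqrt(10000 * 0.1 * 0.9)

    def test_out_of_range_sparsity_rejected(self, rng):
        with pytest.raises(ValueError):
            thin_localizations(_table(rng, 10), 1.5, rng)


def _table(rng, n):
    return make_table(
        rng.integers(0, 100, n), rng.uniform(0, 16, n), rng.uniform(0, 16, n),
        rng.exponential(100, n), 16, 16, 100,
    )


class TestTriplets:
    def test_default_dimensions_256(self):
        t = make_triplet(SimulationConfig(), np.random.default_rng(0))
        assert t.ground_truth.shape == (256, 256)
        assert t.widefield.shape == (256, 256)
        assert t.sparse.shape == (256, 256)

    def test_no_emitters_gives_blank_triplet(self):
        t = make_triplet(SimulationConfig(localization_density=0.0), np.random.default_rng(0))
        assert not t.ground_truth.pixels.any()
        assert not t.widefield.pixels.any()
        assert not t.sparse.pixels.any()

    def test_sparse_to_gt_intensity_ratio_tracks_sparsity(self):
        """Mean pixel-sum ratio over 100 triplets within 3 SE of sparsity."""
        cfg = SimulationConfig(image_size=64, structure_dense=4, sparsity=0.1)
        rng = np.random.default_rng(21)
        ratios = []
        for _ in range(100):
            t = make_triplet(cfg, rng)
            gt_sum = float(t.ground_truth.pixels.sum())
            if gt_sum:
                ratios.append(float(t.sparse.pixels.sum()) / gt_sum)
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - cfg.sparsity) < 3 * se

    def test_sparse_count_never_exceeds_ground_truth(self):
        rng = np.random.default_rng(2)
        cfg = SimulationConfig(image_size=64)
        for _ in range(10):
            t = make_triplet(cfg, rng)
            assert t.provenance["n_localizations_sparse"] <= t.provenance["n_localizations_full"]

    def test_widefield_support_covers_ground_truth(self):
        """Every nonzero GT pixel lies within 3 PSF sigmas of widefield support."""
        cfg = SimulationConfig(image_size=256)
        t = make_triplet(cfg, np.random.default_rng(8))
        radius = int(np.ceil(3 * cfg.widefield_psf_sigma * cfg.oversampling))
        dist = ndimage.distance_transform_edt(t.widefield.pixels == 0)
        gt_rows, gt_cols = np.nonzero(t.ground_truth.pixels)
        assert (dist[gt_rows, gt_cols] <= radius).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(sparsity=1.5)
        with pytest.raises(ConfigError):
            SimulationConfig(image_size=250)  # not divisible by oversampling


class TestGenerateDataset:
    def test_file_count_and_manifest(self, tmp_path):
        cfg = SimulationConfig(dataset_size=10, image_size=64, seed=1)
        manifest = generate_dataset(cfg, tmp_path / "d")
        tiffs = list((tmp_path / "d").rglob("*.tif"))
        assert len(tiffs) == 30
        assert len(manifest["images"]) == 10
        assert (tmp_path / "d" / "manifest.json").exists()

    def test_bit_identical_rerun(self, tmp_path):
        cfg = SimulationConfig(dataset_size=3, image_size=64, seed=5)
        generate_dataset(cfg, tmp_path / "a")
        generate_dataset(cfg, tmp_path / "b")
        for f in sorted((tmp_path / "a").rglob("*.tif")):
            g = tmp_path / "b" / f.relative_to(tmp_path / "a")
            assert f.read_bytes() == g.read_bytes()

    def test_manifest_counts_regenerate_from_seeds(self, tmp_path):
        """Per-image seeds reproduce the recorded localization counts."""
        cfg = SimulationConfig(dataset_size=4, image_size=64, seed=9)
        manifest = generate_dataset(cfg, tmp_path / "d")
        with open(tmp_path / "d" / "manifest.json") as f:
            on_disk = json.load(f)
        assert on_disk["images"] == manifest["images"]
        for entry in manifest["images"]:
            t = make_triplet(cfg, np.random.default_rng(entry["seed"]))
            assert t.provenance["n_localizations_full"] == entry["n_localizations_full"]
            assert t.provenance["n_localizations_sparse"] == entry["n_localizations_sparse"]
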
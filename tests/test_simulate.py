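"""Scene simulator: marginal distributions, footprint labels, rasterization."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import ks_2samp

from canopyfuse.raster import GeoTransform
from canopyfuse.simulate import (
    SCENE_CLASS_NOT_VEGETATED,
    SCENE_CLASS_VEGETATED,
    SCENE_CLASS_WATER,
    BandLink,
    FootprintSet,
    SimConfig,
    apply_scene_class_zeroing,
    generate_height_field,
    rasterize_footprints,
    render_acquisitions,
    sample_footprints,
)


def _mixture_oracle(cfg: SimConfig, n: int, seed: int) -> np.ndarray:
    """Literal independent sampler of the configured height mixture."""
    r = np.random.default_rng(seed)
    out = np.empty(n)
    for i in range(n):
        if r.random() < cfg.p_zero:
            out[i] = 0.0
            continue
        if r.random() < cfg.p_tall:
            h = r.normal(cfg.tall_mean, cfg.tall_sd)
        else:
            h = r.normal(cfg.low_mean, cfg.low_sd)
        out[i] = min(max(h, 0.0), cfg.max_height)
    return out


class TestHeightField:
    def test_deterministic_and_bounded(self):
        cfg = SimConfig(grid_size=32, seed=7)
        f1 = generate_height_field(cfg)
        f2 = generate_height_field(cfg)
        assert np.array_equal(f1.heights, f2.heights)
        assert f1.heights.min() >= 0
        assert f1.heights.max() <= cfg.max_height

    def test_full_zero_inflation_gives_bare_field(self):
        cfg = SimConfig(grid_size=16, p_zero=1.0, seed=1)
        assert np.all(generate_height_field(cfg).heights == 0)

    def test_tall_fraction_matches_mixture_oracle(self):
        cfg = SimConfig(grid_size=128, p_tall=0.05, tall_mean=35.0, seed=3)
        field = generate_height_field(cfg)
        frac = (field.heights > 30.0).mean()
        oracle = _mixture_oracle(cfg, 10 ** 6, seed=12345) > 30.0
        p = oracle.mean()
        se = np.sqrt(p * (1 - p) / field.heights.size
                     + p * (1 - p) / oracle.size)
        assert abs(frac - p) <= 2 * se + 1e-12

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(grid_size=0)
        with pytest.raises(ValueError):
            SimConfig(grid_size=8, corr_length=8)
        with pytest.raises(ValueError):
            SimConfig(p_zero=1.5)


class TestRenderAcquisitions:
    def test_identity_link_zero_noise_reproduces_heights(self):
        links = tuple([BandLink("identity", 0.0, 1.0)]
                      + [BandLink()] * 11)
        cfg = SimConfig(grid_size=16, band_links=links, band_noise_sd=0.0,
                        cloud_fraction=0.0, n_dates=2, seed=4)
        field = generate_height_field(cfg)
        stack = render_acquisitions(field, cfg)
        np.testing.assert_allclose(stack.images[0, 0], field.heights,
                                   rtol=0, atol=1e-5)

    def test_full_cloud_cover_invalidates_every_pixel(self):
        cfg = SimConfig(grid_size=16, cloud_fraction=1.0, n_dates=3, seed=2)
        stack = render_acquisitions(generate_height_field(cfg), cfg)
        assert not stack.valid.any()

    def test_noise_variance_matches_configuration(self):
        # Monte-Carlo moment check: across many dates the only per-pixel
        # variation is the configured sensor noise.
        cfg = SimConfig(grid_size=12, band_noise_sd=0.05, cloud_fraction=0.0,
                        n_dates=500, seed=9)
        stack = render_acquisitions(generate_height_field(cfg), cfg)
        var = stack.images[:, 3].var(axis=0, ddof=1, dtype=np.float64)
        assert abs(var.mean() - 0.05 ** 2) / 0.05 ** 2 < 0.05

    def test_geo_channels_appended_and_bounded(self):
        cfg = SimConfig(grid_size=8, n_dates=1, seed=1)
        stack = render_acquisitions(generate_height_field(cfg), cfg)
        assert stack.n_channels == cfg.n_bands + 3
        geo = stack.images[0, cfg.n_bands:]
        assert np.all(np.abs(geo) <= 1.0)

    def test_rejects_zero_dates(self):
        cfg = SimConfig(grid_size=8, seed=1)
        field = generate_height_field(cfg)
        with pytest.raises(ValueError):
            render_acquisitions(field, dataclasses.replace(cfg, n_dates=0))


def _disc_scan_oracle(field, xc, yc, radius):
    """O(H*W) literal disc scan over every pixel centre."""
    h, w = field.heights.shape
    gsd = field.transform.gsd
    best = -np.inf
    for r in range(h):
        for c in range(w):
            px = (c + 0.5) * gsd
            py = (h - r - 0.5) * gsd
            if (px - xc) ** 2 + (py - yc) ** 2 <= radius ** 2:
                best = max(best, field.heights[r, c])
    return best


class TestFootprints:
    def test_noise_free_constant_field_labels(self):
        cfg = SimConfig(grid_size=16, p_zero=0.0, low_mean=20.0, low_sd=0.0,
                        p_tall=0.0, label_noise_sd=0.0, jitter_sd=0.0, seed=5)
        field = generate_height_field(cfg)
        fps = sample_footprints(field, 50, cfg)
        np.testing.assert_allclose(fps.rh98, 20.0, atol=1e-9)

    def test_zero_footprints_gives_empty_set(self):
        cfg = SimConfig(grid_size=8, seed=1)
        fps = sample_footprints(generate_height_field(cfg), 0, cfg)
        assert len(fps) == 0

    def test_negative_count_rejected(self):
        cfg = SimConfig(grid_size=8, seed=1)
        with pytest.raises(ValueError):
            sample_footprints(generate_height_field(cfg), -1, cfg)

    def test_single_spike_matches_disc_scan_oracle(self):
        cfg = SimConfig(grid_size=12, p_zero=1.0, label_noise_sd=0.0,
                        jitter_sd=0.0, seed=6)
        field = generate_height_field(cfg)
        field.heights[5, 7] = 30.0
        fps = sample_footprints(field, 200, cfg)
        for i in range(len(fps)):
            expect = _disc_scan_oracle(field, fps.x_true[i], fps.y_true[i],
                                       cfg.footprint_radius)
            assert fps.rh98[i] == expect

    def test_label_distribution_converges_to_disc_max(self):
        # two-sample KS against an independent disc-scan sampler
        cfg = SimConfig(grid_size=40, label_noise_sd=0.0, jitter_sd=0.0,
                        seed=11)
        field = generate_height_field(cfg)
        fps = sample_footprints(field, 10_000, cfg)
        r2 = np.random.default_rng(777)
        gsd = cfg.gsd
        h, w = field.heights.shape
        # oracle: vectorized literal disc-max at fresh random positions
        xs = r2.uniform(0, w * gsd, 10_000)
        ys = r2.uniform(0, h * gsd, 10_000)
        cols_c = np.arange(w)[None, :]
        rows_c = np.arange(h)[:, None]
        px = (cols_c + 0.5) * gsd
        py = (h - rows_c - 0.5) * gsd
        oracle = np.empty(len(xs))
        for i in range(len(xs)):
            inside = (px - xs[i]) ** 2 + (py - ys[i]) ** 2 <= cfg.footprint_radius ** 2
            oracle[i] = field.heights[inside].max()
        assert ks_2samp(fps.rh98, oracle).pvalue > 0.01


class TestRasterize:
    transform = GeoTransform(0.0, 80.0, 10.0)

    def _fps(self, xs, ys, labels):
        a = np.asarray
        return FootprintSet(a(xs, float), a(ys, float), a(xs, float),
                            a(ys, float), a(labels, float))

    def test_single_footprint_single_pixel(self):
        lab = rasterize_footprints(self._fps([15.0], [75.0], [12.0]),
                                   self.transform, (8, 8))
        assert lab.valid.sum() == 1
        assert lab.heights[0, 1] == 12.0

    def test_collision_keeps_last_and_counts(self):
        lab = rasterize_footprints(
            self._fps([15.0, 12.0], [75.0, 71.0], [12.0, 30.0]),
            self.transform, (8, 8))
        assert lab.valid.sum() == 1
        assert lab.n_collisions == 1
        assert lab.heights[0, 1] == 30.0  # last-written wins

    def test_off_grid_footprint_dropped(self):
        lab = rasterize_footprints(self._fps([-0.01], [75.0], [5.0]),
                                   self.transform, (8, 8))
        assert lab.valid.sum() == 0
        assert lab.n_dropped == 1


class TestSceneClassZeroing:
    def _labels(self):
        h = np.full((4, 4), np.nan)
        v = np.zeros((4, 4), bool)
        h[1, 1] = 12.0
        h[2, 2] = 12.0
        v[1, 1] = v[2, 2] = True
        from canopyfuse.simulate import SparseLabelRaster

        return SparseLabelRaster(heights=h, valid=v)

    def test_water_label_forced_to_zero(self):
        classes = np.full((4, 4), SCENE_CLASS_VEGETATED)
        classes[1, 1] = SCENE_CLASS_WATER
        out = apply_scene_class_zeroing(self._labels(), classes)
        assert out.heights[1, 1] == 0.0
        assert out.valid[1, 1]
        assert out.heights[2, 2] == 12.0  # vegetated pixel unchanged

    def test_all_bare_grid_zeroes_all_valid(self):
        classes = np.full((4, 4), SCENE_CLASS_NOT_VEGETATED)
        out = apply_scene_class_zeroing(self._labels(), classes)
        assert np.all(out.heights[out.valid] == 0.0)

    def test_misaligned_grid_rejected(self):
        with pytest.raises(ValueError):
            apply_scene_class_zeroing(self._labels(), np.zeros((3, 3)))
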
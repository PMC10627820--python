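"""Synthetic scene generation for sparsely supervised canopy-height retrieval.

The simulator produces everything the downstream stages consume, with the
statistical structure the method assumes:

* a latent canopy-top **height field** with a zero-inflated, long-tailed
  marginal (low vegetation dominates, tall stands are rare) and spatial
  correlation (stands, not salt-and-pepper);
* **acquisition stacks**: T dated multi-band images where each band is a
  monotone link of height plus Gaussian sensor noise, with per-date cloud
  masks and cyclically encoded geographic coordinate channels appended;
* **footprints**: sparse LiDAR-like labels defined as the maximum height
  within a 25-m-diameter disc around the true centre (the canopy-top
  metric a large-footprint waveform sees), with label noise and
  geolocation jitter applied to the reported position;
* a **sparse label raster**: footprints rasterized to the 10-m pixel grid
  by writing each label into the pixel containing its reported centre.

Every operation is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter

from .coords import encode_coordinates
from .raster import GeoTransform

__all__ = [
    "BandLink",
    "SimConfig",
    "HeightField",
    "AcquisitionStack",
    "FootprintSet",
    "SparseLabelRaster",
    "generate_height_field",
    "render_acquisitions",
    "sample_footprints",
    "rasterize_footprints",
    "apply_scene_class_zeroing",
    "simulate_scene",
    "build_patch_dataset",
    "disc_max_truth",
    "SCENE_CLASS_VEGETATED",
    "SCENE_CLASS_NOT_VEGETATED",
    "SCENE_CLASS_WATER",
]

# Scene-classification codes (echo the Sentinel-2 L2A SCL convention).
SCENE_CLASS_VEGETATED = 4
SCENE_CLASS_NOT_VEGETATED = 5
SCENE_CLASS_WATER = 6

_METERS_PER_DEGREE = 111_320.0


@dataclass(frozen=True)
class BandLink:
    """Monotone height-to-reflectance link for one band.

    ``saturating``: r = offset + gain * (1 - exp(-h / scale)) — reflectance
    saturates with canopy height, the behaviour that makes tall canopies
    hard for purely spectral regressors. ``identity``: r = offset + gain*h,
    useful for controlled tests.
    """

    kind: str = "saturating"
    offset: float = 0.1
    gain: float = 0.2
    scale: float = 20.0

    def apply(self, h):
        if self.kind == "identity":
            return self.offset + self.gain * np.asarray(h, dtype=float)
        if self.kind == "saturating":
            return self.offset + self.gain * (1.0 - np.exp(-np.asarray(h, dtype=float) / self.scale))
        raise ValueError(f"unknown band link kind: {self.kind!r}")


def _default_links(n_bands: int) -> tuple[BandLink, ...]:
    # Visible-like bands darken with canopy, NIR-like brighten strongly,
    # SWIR-like darken moderately; saturation scales vary across bands so
    # the joint spectrum stays informative over the whole height range.
    links = []
    for b in range(n_bands):
        if b % 3 == 0:
            links.append(BandLink("saturating", 0.12, -0.08, 12.0 + 2.0 * b))
        elif b % 3 == 1:
            links.append(BandLink("saturating", 0.15, 0.30, 18.0 + 2.0 * b))
        else:
            links.append(BandLink("saturating", 0.22, -0.12, 25.0 + 2.0 * b))
    return tuple(links)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic scene generator.

    Heights (m) follow a zero-inflated two-component Gaussian mixture
    clipped to [0, max_height]: with probability ``p_zero`` a pixel is
    bare (0 m); otherwise it is tall with probability ``p_tall``
    (N(tall_mean, tall_sd)) or low vegetation (N(low_mean, low_sd)).
    """

    grid_size: int = 64
    gsd: float = 10.0
    n_bands: int = 12
    # height mixture
    p_zero: float = 0.35
    low_mean: float = 8.0
    low_sd: float = 5.0
    p_tall: float = 0.05
    tall_mean: float = 35.0
    tall_sd: float = 6.0
    max_height: float = 60.0
    # spatial texture
    corr_length: float = 4.0
    # radiometry
    band_links: tuple[BandLink, ...] | None = None
    band_noise_sd: float | tuple[float, ...] = 0.02
    # acquisitions
    cloud_fraction: float = 0.3
    n_dates: int = 10
    # footprints
    footprint_radius: float = 12.5
    label_noise_sd: float = 2.0
    jitter_sd: float = 8.0
    # geographic anchor of the scene's top-left corner (degrees)
    lat0: float = 12.0
    lon0: float = 24.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_size <= 0:
            raise ValueError("grid_size must be positive")
        for name in ("p_zero", "p_tall", "cloud_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("low_sd", "tall_sd", "label_noise_sd", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.max_height <= 0:
            raise ValueError("max_height must be positive")
        if self.corr_length >= self.grid_size:
            raise ValueError("corr_length must be smaller than grid_size")
        if self.gsd <= 0 or self.footprint_radius <= 0:
            raise ValueError("gsd and footprint_radius must be positive")

    @property
    def links(self) -> tuple[BandLink, ...]:
        if self.band_links is not None:
            if len(self.band_links) != self.n_bands:
                raise ValueError("band_links length must equal n_bands")
            return self.band_links
        return _default_links(self.n_bands)

    @property
    def noise_sds(self) -> np.ndarray:
        sd = np.broadcast_to(np.asarray(self.band_noise_sd, dtype=float),
                             (self.n_bands,))
        if np.any(sd < 0):
            raise ValueError("band_noise_sd must be >= 0")
        return np.array(sd)


@dataclass
class HeightField:
    """Latent true canopy-top height grid (m) with scene geometry."""

    heights: np.ndarray          # (H, W) metres
    transform: GeoTransform
    lat: np.ndarray              # (H, W) degrees, pixel centres
    lon: np.ndarray              # (H, W) degrees
    max_height: float

    def __post_init__(self):
        if self.heights.shape != self.lat.shape or self.heights.shape != self.lon.shape:
            raise ValueError("heights/lat/lon shapes must match")
        if np.any(self.heights < 0) or np.any(self.heights > self.max_height):
            raise ValueError("heights must lie in [0, max_height]")

    @property
    def shape(self):
        return self.heights.shape

    def lonlat_of(self, x, y):
        """Scene-metric coords (m) -> (lon, lat) under the equirectangular anchor."""
        h = self.heights.shape[0]
        lat0 = self.lat[0, 0] + 0.5 * self.transform.gsd / _METERS_PER_DEGREE
        lon0 = self.lon[0, 0] - 0.5 * self.transform.gsd / (
            _METERS_PER_DEGREE * np.cos(np.deg2rad(lat0)))
        lat = lat0 - (h * self.transform.gsd - np.asarray(y)) / _METERS_PER_DEGREE
        lon = lon0 + np.asarray(x) / (_METERS_PER_DEGREE * np.cos(np.deg2rad(lat0)))
        return lon, lat


@dataclass
class AcquisitionStack:
    """T dated multi-channel images sharing one geometry.

    ``images`` has shape (T, C, H, W) with C = n_bands + 3 geo channels;
    ``valid`` (T, H, W) flags cloud-free pixels. Invalid pixels keep their
    rendered values (they are flagged, never NaN) so masking bugs surface
    as wrong numbers rather than silent NaN propagation.
    """

    images: np.ndarray
    valid: np.ndarray
    dates: list
    transform: GeoTransform

    def __post_init__(self):
        if self.images.ndim != 4:
            raise ValueError("images must be (T, C, H, W)")
        if self.valid.shape != (self.images.shape[0],) + self.images.shape[2:]:
            raise ValueError("valid mask must be (T, H, W)")
        if len(self.dates) != self.images.shape[0]:
            raise ValueError("one date per acquisition required")

    @property
    def n_dates(self):
        return self.images.shape[0]

    @property
    def n_channels(self):
        return self.images.shape[1]


@dataclass
class FootprintSet:
    """Sparse LiDAR-like labels: true and reported centres plus heights."""

    x_true: np.ndarray
    y_true: np.ndarray
    x_reported: np.ndarray
    y_reported: np.ndarray
    rh98: np.ndarray             # label height (m), >= 0

    def __post_init__(self):
        n = len(self.rh98)
        for a in (self.x_true, self.y_true, self.x_reported, self.y_reported):
            if len(a) != n:
                raise ValueError("all footprint columns must share length")
        if n and np.any(self.rh98 < 0):
            raise ValueError("labels must be >= 0")

    def __len__(self):
        return len(self.rh98)

    def to_frame(self, field: HeightField | None = None):
        import pandas as pd

        data = {
            "x": self.x_reported,
            "y": self.y_reported,
            "x_true": self.x_true,
            "y_true": self.y_true,
            "rh98_m": self.rh98,
        }
        if field is not None:
            lon, lat = field.lonlat_of(self.x_reported, self.y_reported)
            data = {"lon": lon, "lat": lat, **data}
        return pd.DataFrame(data)


@dataclass
class SparseLabelRaster:
    """Per-pixel reference heights where a footprint centre fell; NaN elsewhere."""

    heights: np.ndarray          # (H, W), NaN at invalid pixels
    valid: np.ndarray            # (H, W) bool
    n_collisions: int = 0
    n_dropped: int = 0

    def __post_init__(self):
        if self.heights.shape != self.valid.shape:
            raise ValueError("heights and valid must share shape")
        vals = self.heights[self.valid]
        if vals.size and (np.any(~np.isfinite(vals)) or np.any(vals < 0)):
            raise ValueError("valid pixels must carry finite heights >= 0")

    @property
    def values(self):
        return self.heights[self.valid]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _sample_mixture(config: SimConfig, n: int, rng) -> np.ndarray:
    """iid draws from the zero-inflated clipped height mixture."""
    u = rng.random(n)
    comp_tall = rng.random(n) < config.p_tall
    h = np.where(
        comp_tall,
        rng.normal(config.tall_mean, config.tall_sd, n),
        rng.normal(config.low_mean, config.low_sd, n),
    )
    h = np.clip(h, 0.0, config.max_height)
    h[u < config.p_zero] = 0.0
    return h


def _smooth_standard_field(shape, corr_length, rng) -> np.ndarray:
    z = rng.standard_normal(shape)
    if corr_length > 0:
        z = gaussian_filter(z, sigma=corr_length, mode="wrap")
    return z


def generate_height_field(config: SimConfig) -> HeightField:
    """Draw a spatially correlated, zero-inflated, long-tailed height grid.

    The marginal distribution is exactly the configured mixture: heights
    are drawn iid from the mixture and then assigned to pixels by the rank
    of a Gaussian-filtered white-noise field (a rank copula), so spatial
    texture is imposed without disturbing the marginal.
    """
    rng = _rng(config, 0)
    n = config.grid_size
    shape = (n, n)
    draws = np.sort(_sample_mixture(config, n * n, rng))
    z = _smooth_standard_field(shape, config.corr_length, rng)
    order = np.argsort(z.ravel(), kind="stable")
    heights = np.empty(n * n)
    heights[order] = draws
    heights = heights.reshape(shape)

    transform = GeoTransform(origin_x=0.0, origin_y=n * config.gsd, gsd=config.gsd)
    rows, cols = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    lat = config.lat0 - (rows + 0.5) * config.gsd / _METERS_PER_DEGREE
    lon = config.lon0 + (cols + 0.5) * config.gsd / (
        _METERS_PER_DEGREE * np.cos(np.deg2rad(config.lat0)))
    return HeightField(heights=heights, transform=transform, lat=lat, lon=lon,
                       max_height=config.max_height)


def render_acquisitions(field: HeightField, config: SimConfig) -> AcquisitionStack:
    """Render T dated multi-band images of a height field.

    Each band applies its monotone link to the height grid and adds
    date-independent Gaussian sensor noise per date; each date draws a
    spatially correlated cloud mask covering ``cloud_fraction`` of the
    pixels. Cyclic geographic coordinate channels are appended, so each
    acquisition carries n_bands + 3 channels.
    """
    if config.n_dates < 1:
        raise ValueError("n_dates must be >= 1")
    if field.heights.shape != (config.grid_size, config.grid_size):
        raise ValueError("field dims inconsistent with config")
    rng = _rng(config, 1)
    h, w = field.heights.shape
    t_dates = config.n_dates
    links = config.links
    noise_sds = config.noise_sds
    geo = encode_coordinates(field.lat, field.lon).astype(np.float32)

    base = np.stack([link.apply(field.heights) for link in links]).astype(np.float32)
    images = np.empty((t_dates, config.n_bands + 3, h, w), dtype=np.float32)
    valid = np.empty((t_dates, h, w), dtype=bool)
    for t in range(t_dates):
        noise = rng.standard_normal((config.n_bands, h, w)) * noise_sds[:, None, None]
        images[t, : config.n_bands] = base + noise.astype(np.float32)
        images[t, config.n_bands:] = geo
        cloud_field = _smooth_standard_field((h, w), config.corr_length, rng)
        if config.cloud_fraction >= 1.0:
            cloudy = np.ones((h, w), dtype=bool)
        elif config.cloud_fraction <= 0.0:
            cloudy = np.zeros((h, w), dtype=bool)
        else:
            thr = np.quantile(cloud_field, config.cloud_fraction)
            cloudy = cloud_field < thr
        valid[t] = ~cloudy
    dates = [np.datetime64("2020-05-01") + np.timedelta64(10 * t, "D")
             for t in range(t_dates)]
    return AcquisitionStack(images=images, valid=valid, dates=dates,
                            transform=field.transform)


def _disc_max(field: HeightField, xc: float, yc: float, radius: float) -> float:
    """Max height over pixels whose centre lies within ``radius`` of (xc, yc)."""
    gsd = field.transform.gsd
    h, w = field.heights.shape
    r_px = int(np.ceil(radius / gsd)) + 1
    row_c, col_c = field.transform.pixel_of(xc, yc)
    r0, r1 = max(0, row_c - r_px), min(h, row_c + r_px + 1)
    c0, c1 = max(0, col_c - r_px), min(w, col_c + r_px + 1)
    if r0 >= r1 or c0 >= c1:
        return 0.0
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    px, py = field.transform.center_of(rows[:, None], cols[None, :])
    inside = (px - xc) ** 2 + (py - yc) ** 2 <= radius ** 2
    window = field.heights[r0:r1, c0:c1]
    if not inside.any():
        # footprint centred between pixel centres with a tiny radius:
        # fall back to the containing pixel
        rr = int(np.clip(row_c, 0, h - 1))
        cc = int(np.clip(col_c, 0, w - 1))
        return float(field.heights[rr, cc])
    return float(window[inside].max())


def sample_footprints(field: HeightField, n: int, config: SimConfig) -> FootprintSet:
    """Sample n LiDAR-like footprints from a height field.

    The label is the canopy-top metric a 25-m waveform footprint measures:
    the maximum height over pixels within ``footprint_radius`` of the TRUE
    centre, plus Gaussian label noise, clipped at 0. The REPORTED centre is
    displaced by isotropic Gaussian geolocation jitter; rasterization later
    uses the reported position, reproducing the label-misalignment noise of
    real spaceborne LiDAR.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _rng(config, 2)
    h, w = field.heights.shape
    gsd = field.transform.gsd
    x_true = rng.uniform(0.0, w * gsd, n)
    y_true = rng.uniform(0.0, h * gsd, n)
    labels = np.array([
        _disc_max(field, x_true[i], y_true[i], config.footprint_radius)
        for i in range(n)
    ]) if n else np.empty(0)
    labels = labels + rng.normal(0.0, config.label_noise_sd, n) if n else labels
    labels = np.clip(labels, 0.0, None)
    x_rep = x_true + rng.normal(0.0, config.jitter_sd, n)
    y_rep = y_true + rng.normal(0.0, config.jitter_sd, n)
    return FootprintSet(x_true=x_true, y_true=y_true,
                        x_reported=x_rep, y_reported=y_rep, rh98=labels)


def rasterize_footprints(fps: FootprintSet, transform: GeoTransform,
                         shape: tuple[int, int]) -> SparseLabelRaster:
    """Write each footprint's label into the pixel containing its reported centre.

    Off-grid footprints are dropped and counted. When several footprints
    fall into one pixel the last-written label wins and the collision
    counter increments — deterministic and auditable.
    """
    h, w = shape
    heights = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    n_coll = 0
    n_drop = 0
    rows, cols = transform.pixel_of(fps.x_reported, fps.y_reported)
    for i in range(len(fps)):
        r, c = rows[i], cols[i]
        if not (0 <= r < h and 0 <= c < w):
            n_drop += 1
            continue
        if valid[r, c]:
            n_coll += 1
        heights[r, c] = fps.rh98[i]
        valid[r, c] = True
    return SparseLabelRaster(heights=heights, valid=valid,
                             n_collisions=n_coll, n_dropped=n_drop)


def apply_scene_class_zeroing(
    labels: SparseLabelRaster,
    class_grid: np.ndarray,
    zero_classes=(SCENE_CLASS_NOT_VEGETATED, SCENE_CLASS_WATER),
) -> SparseLabelRaster:
    """Force labels on bare/water pixels to 0 m (validity kept).

    Mirrors the scene-classification correction that repairs geolocation
    noise: a footprint whose reported centre lands on a 'not vegetated' or
    'water' pixel cannot have canopy there, so its reference height is 0.
    """
    class_grid = np.asarray(class_grid)
    if class_grid.shape != labels.heights.shape:
        raise ValueError("class grid must align with label grid")
    heights = labels.heights.copy()
    zero_mask = labels.valid & np.isin(class_grid, list(zero_classes))
    heights[zero_mask] = 0.0
    return SparseLabelRaster(heights=heights, valid=labels.valid.copy(),
                             n_collisions=labels.n_collisions,
                             n_dropped=labels.n_dropped)


def disc_max_truth(field: HeightField, radius: float | None = None) -> np.ndarray:
    """GEDI-like canopy-top truth at every pixel: disc-max of the true field.

    This is the quantity the sparse labels (and hence the trained model)
    estimate — each map pixel effectively carries the largest canopy top
    within a footprint-sized disc centred on it.
    """
    if radius is None:
        radius = 12.5
    gsd = field.transform.gsd
    r_px = int(np.floor(radius / gsd))
    size = 2 * r_px + 1
    di, dj = np.meshgrid(np.arange(-r_px, r_px + 1), np.arange(-r_px, r_px + 1),
                         indexing="ij")
    disc = (di ** 2 + dj ** 2) * gsd ** 2 <= radius ** 2
    return maximum_filter(field.heights, footprint=disc, mode="constant",
                          cval=-np.inf)


def simulate_scene(config: SimConfig, n_footprints: int):
    """Full scene: height field, acquisitions, footprints, rasterized labels."""
    field = generate_height_field(config)
    stack = render_acquisitions(field, config)
    fps = sample_footprints(field, n_footprints, config)
    labels = rasterize_footprints(fps, field.transform, field.heights.shape)
    return field, stack, fps, labels


def build_patch_dataset(config: SimConfig, n_scenes: int, n_footprints: int,
                        patch_size: int = 15, base_seed: int | None = None):
    """Training patches: one image window per footprint, labels rasterized.

    For every footprint whose pixel allows a full ``patch_size`` window and
    is cloud-free on at least one date, the least-cloudy such date is
    selected and the window extracted. The label raster window (NaN where
    unlabeled or cloudy on the selected date) is the sparse supervision.

    Returns
    -------
    X : (n, C, patch_size, patch_size) float32
    Y : (n, patch_size, patch_size) float32 with NaN at unlabeled pixels
    scenes : list of (field, stack, labels) for downstream evaluation
    """
    if base_seed is None:
        base_seed = config.seed
    half = patch_size // 2
    xs, ys, scenes = [], [], []
    for s in range(n_scenes):
        cfg = dataclasses.replace(config, seed=base_seed + s)
        field, stack, fps, labels = simulate_scene(cfg, n_footprints)
        scenes.append((field, stack, labels))
        cloudiness = 1.0 - stack.valid.reshape(stack.n_dates, -1).mean(axis=1)
        order = np.argsort(cloudiness, kind="stable")
        rows, cols = field.transform.pixel_of(fps.x_reported, fps.y_reported)
        h, w = field.heights.shape
        for i in range(len(fps)):
            r, c = rows[i], cols[i]
            if not (half <= r < h - half and half <= c < w - half):
                continue
            t_sel = next((int(t) for t in order if stack.valid[t, r, c]), None)
            if t_sel is None:
                continue
            sl = np.s_[r - half: r + half + 1, c - half: c + half + 1]
            x = stack.images[t_sel][(slice(None),) + sl]
            y = labels.heights[sl].astype(np.float32).copy()
            y[~(labels.valid[sl] & stack.valid[t_sel][sl])] = np.nan
            xs.append(x)
            ys.append(y)
    if not xs:
        c = config.n_bands + 3
        return (np.empty((0, c, patch_size, patch_size), np.float32),
                np.empty((0, patch_size, patch_size), np.float32), scenes)
    return np.stack(xs), np.stack(ys), scenes
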
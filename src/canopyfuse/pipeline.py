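"""Tiled inference, acquisition selection and map export.

The production convention for exported height maps is followed: the
height band is unsigned 8-bit metres (values 0-254, round-half-even)
with 255 reserved as the nodata sentinel, accompanied by a float32
predictive-standard-deviation band; a lossless float export is available
for analysis. Built-up, snow/ice and permanent water pixels are masked
to nodata with a land-cover grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import FusionInput, ModelEnsemble, assign_members, fuse
from .raster import GeoTransform, read_geotiff, write_geotiff
from .simulate import AcquisitionStack

__all__ = [
    "NODATA",
    "LANDCOVER_BUILTUP",
    "LANDCOVER_SNOW_ICE",
    "LANDCOVER_WATER",
    "PredictiveMap",
    "AcquisitionCatalog",
    "select_images",
    "predict_tile",
    "apply_landcover_mask",
    "write_map",
    "read_map",
]

logger = logging.getLogger(__name__)

NODATA = 255

# ESA WorldCover-style class codes used by the masking step
LANDCOVER_BUILTUP = 50
LANDCOVER_SNOW_ICE = 70
LANDCOVER_WATER = 80
_MASKED_CLASSES = (LANDCOVER_BUILTUP, LANDCOVER_SNOW_ICE, LANDCOVER_WATER)


@dataclass
class PredictiveMap:
    """Fused per-pixel height mean and predictive standard deviation (m)."""

    mean: np.ndarray       # (H, W) metres, NaN at nodata
    std: np.ndarray        # (H, W) metres, NaN at nodata
    nodata: np.ndarray     # (H, W) bool
    transform: GeoTransform

    def __post_init__(self):
        if not (self.mean.shape == self.std.shape == self.nodata.shape):
            raise ValueError("mean, std and nodata must share shape")
        ok = ~self.nodata
        if np.any(self.std[ok] < 0):
            raise ValueError("std must be >= 0 where valid")


@dataclass
class AcquisitionCatalog:
    """Catalog of candidate acquisitions: date, cloud fraction, file path."""

    records: pd.DataFrame  # columns: date (datetime64), cloud_fraction, path

    def __post_init__(self):
        need = {"date", "cloud_fraction", "path"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"catalog needs columns {sorted(need)}")
        cf = self.records["cloud_fraction"]
        if ((cf < 0) | (cf > 1)).any():
            raise ValueError("cloud_fraction must lie in [0, 1]")


def select_images(catalog: AcquisitionCatalog, window=None,
                  count: int = 10) -> pd.DataFrame:
    """Up to ``count`` least-cloudy acquisitions within a date window.

    Ties in cloud fraction break deterministically by date, then path.
    Fewer than ``count`` matches are returned with a warning.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    df = catalog.records.copy()
    df["date"] = pd.to_datetime(df["date"])
    if window is not None:
        start, end = pd.to_datetime(window[0]), pd.to_datetime(window[1])
        df = df[(df["date"] >= start) & (df["date"] <= end)]
    if df.empty:
        raise ValueError("no acquisitions in the requested window")
    df = df.sort_values(["cloud_fraction", "date", "path"],
                        kind="stable").reset_index(drop=True)
    if len(df) < count:
        logger.warning("only %d of %d requested acquisitions available",
                       len(df), count)
    return df.head(count)


def _forward_dates(stack: AcquisitionStack, ensemble: ModelEnsemble,
                   member_map, region=None):
    """Per-date dense predictions (m) over an optional (r0, r1, c0, c1) region."""
    t_dates = stack.n_dates
    if region is None:
        region = (0, stack.images.shape[2], 0, stack.images.shape[3])
    r0, r1, c0, c1 = region
    h, w = r1 - r0, c1 - c0
    means = np.empty((t_dates, h, w))
    variances = np.empty((t_dates, h, w))
    valid = np.empty((t_dates, h, w), dtype=bool)
    for t in range(t_dates):
        valid[t] = stack.valid[t, r0:r1, c0:c1]
        if not valid[t].any():
            means[t] = 0.0
            variances[t] = 1.0
            continue
        net = ensemble.members[member_map[t]]
        out = net.predict(stack.images[t][:, r0:r1, c0:c1], stats=ensemble.stats)
        means[t] = out.mean
        variances[t] = out.variance
    return means, variances, valid


def predict_tile(stack: AcquisitionStack, ensemble: ModelEnsemble, seed: int = 0,
                 window_size: int | None = None) -> PredictiveMap:
    """Fused prediction over a tile: per-date forward passes, then fusion.

    Each date is processed by a randomly assigned ensemble member
    (deterministic given ``seed``); per-pixel fusion runs over the valid
    (cloud-free) dates only, and pixels with zero valid observations are
    nodata. With ``window_size`` the tile is processed in overlapping
    windows whose margin equals the network's receptive-field half-width,
    then centre-cropped and stitched — interior results match whole-tile
    inference.
    """
    member_map = assign_members(stack.n_dates, len(ensemble), seed)
    th, tw = stack.images.shape[2], stack.images.shape[3]
    if not stack.valid.any():
        warnings.warn("no valid acquisition anywhere: all-nodata map")
    if window_size is None:
        means, variances, valid = _forward_dates(stack, ensemble, member_map)
        fmean, fvar, nodata = fuse(FusionInput(means, variances, valid))
    else:
        margin = ensemble.members[0].receptive_margin
        fmean = np.empty((th, tw))
        fvar = np.empty((th, tw))
        nodata = np.empty((th, tw), dtype=bool)
        for r0 in range(0, th, window_size):
            for c0 in range(0, tw, window_size):
                r1 = min(r0 + window_size, th)
                c1 = min(c0 + window_size, tw)
                rr0, rr1 = max(0, r0 - margin), min(th, r1 + margin)
                cc0, cc1 = max(0, c0 - margin), min(tw, c1 + margin)
                m, v, val = _forward_dates(stack, ensemble, member_map,
                                           region=(rr0, rr1, cc0, cc1))
                wm, wv, wn = fuse(FusionInput(m, v, val))
                sl = np.s_[r0 - rr0: r1 - rr0, c0 - cc0: c1 - cc0]
                fmean[r0:r1, c0:c1] = wm[sl]
                fvar[r0:r1, c0:c1] = wv[sl]
                nodata[r0:r1, c0:c1] = wn[sl]
    with np.errstate(invalid="ignore"):
        std = np.sqrt(fvar)
    return PredictiveMap(mean=fmean, std=std, nodata=nodata,
                         transform=stack.transform)


def apply_landcover_mask(pmap: PredictiveMap, class_grid: np.ndarray,
                         masked_classes=_MASKED_CLASSES) -> PredictiveMap:
    """Set built-up, snow/ice and permanent-water pixels to nodata."""
    class_grid = np.asarray(class_grid)
    if class_grid.shape != pmap.mean.shape:
        raise ValueError("land-cover grid must align with the map")
    masked = np.isin(class_grid, list(masked_classes))
    mean = np.where(masked, np.nan, pmap.mean)
    std = np.where(masked, np.nan, pmap.std)
    return PredictiveMap(mean=mean, std=std, nodata=pmap.nodata | masked,
                         transform=pmap.transform)


def write_map(pmap: PredictiveMap, path, lossless: bool = False):
    """Export a fused map as a 2-band GeoTIFF.

    Default product format: band 1 is height in whole metres as uint8
    (round-half-even, clipped to [0, 254]) with 255 = nodata; band 2 is
    the predictive standard deviation as float32 with the 255.0 sentinel
    at nodata. ``lossless=True`` writes both bands as float32 (mean kept
    at full precision, NaN at nodata).
    """
    ok = ~pmap.nodata
    if lossless:
        mean_band = np.where(ok, pmap.mean, np.nan).astype(np.float32)
    else:
        q = np.rint(pmap.mean)  # round-half-even, numpy default
        n_clip = int(np.sum(ok & (q > 254)))
        if n_clip:
            warnings.warn(f"{n_clip} heights above 254 m clipped")
        q = np.clip(q, 0, 254)
        mean_band = np.where(ok, q, NODATA).astype(np.uint8)
    std_band = np.where(ok, pmap.std, float(NODATA)).astype(np.float32)
    write_geotiff(path, [mean_band, std_band], pmap.transform)


def write_stack(stack: AcquisitionStack, out_dir):
    """Write an acquisition stack as one GeoTIFF per date.

    Each file holds the C float32 channel pages plus a trailing uint8
    validity page; dates are recorded in ``dates.txt`` alongside.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    for t in range(stack.n_dates):
        bands = [stack.images[t, c].astype(np.float32)
                 for c in range(stack.n_channels)]
        bands.append(stack.valid[t].astype(np.uint8))
        write_geotiff(os.path.join(out_dir, f"acq_{t:03d}.tif"), bands,
                      stack.transform)
    with open(os.path.join(out_dir, "dates.txt"), "w") as fh:
        for d in stack.dates:
            fh.write(f"{d}\n")


def read_stack(in_dir) -> AcquisitionStack:
    """Read a stack written by :func:`write_stack`."""
    import glob
    import os

    paths = sorted(glob.glob(os.path.join(in_dir, "acq_*.tif")))
    if not paths:
        raise FileNotFoundError(f"no acquisitions under {in_dir}")
    images, valid = [], []
    transform = None
    for p in paths:
        bands, transform = read_geotiff(p)
        images.append(np.stack(bands[:-1]))
        valid.append(bands[-1].astype(bool))
    with open(os.path.join(in_dir, "dates.txt")) as fh:
        dates = [np.datetime64(line.strip()) for line in fh if line.strip()]
    return AcquisitionStack(images=np.stack(images).astype(np.float32),
                            valid=np.stack(valid), dates=dates,
                            transform=transform)


def read_map(path) -> PredictiveMap:
    """Read a map written by :func:`write_map` (either format)."""
    bands, transform = read_geotiff(path)
    mean_band, std_band = bands[0], bands[1]
    if mean_band.dtype == np.uint8:
        nodata = mean_band == NODATA
        mean = np.where(nodata, np.nan, mean_band.astype(float))
    else:
        nodata = ~np.isfinite(mean_band)
        mean = mean_band.astype(float)
    std = np.where(nodata, np.nan, std_band.astype(float))
    return PredictiveMap(mean=mean, std=std, nodata=nodata, transform=transform)
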
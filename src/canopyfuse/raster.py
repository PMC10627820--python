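"""Minimal GeoTIFF raster I/O built on tifffile.

Rasters are stored as one TIFF page per band with GeoTIFF
ModelPixelScale/ModelTiepoint tags carrying the affine geo-transform
(north-up, square pixels). This covers everything the package needs:
multi-band scenes, sparse label rasters and fused prediction maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

__all__ = ["GeoTransform", "write_geotiff", "read_geotiff", "upsample_cubic"]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine transform: top-left corner origin and square pixel size.

    ``origin_x``/``origin_y`` are the map coordinates of the top-left corner
    of pixel (0, 0); ``gsd`` is the ground sampling distance in map units
    (metres for scene-local frames).
    """

    origin_x: float
    origin_y: float
    gsd: float

    def pixel_of(self, x, y):
        """Map coordinates -> (row, col) integer pixel indices (floor)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.gsd).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.gsd).astype(int)
        return row, col

    def center_of(self, row, col):
        """Pixel indices -> map coordinates of the pixel centre."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.gsd
        y = self.origin_y - (np.asarray(row) + 0.5) * self.gsd
        return x, y


def _geo_tags(transform: GeoTransform):
    scale = (transform.gsd, transform.gsd, 0.0)
    tie = (0.0, 0.0, 0.0, transform.origin_x, transform.origin_y, 0.0)
    return [
        (_TAG_PIXEL_SCALE, "d", 3, scale, True),
        (_TAG_TIEPOINT, "d", 6, tie, True),
    ]


def write_geotiff(path, bands, transform: GeoTransform):
    """Write a list of 2-D arrays as a multi-page GeoTIFF.

    Bands may have different dtypes (e.g. a uint8 height band plus a
    float32 standard-deviation band); each is written as its own page.
    Geo tags are attached to every page so single-band reads stay geo-aware.
    """
    bands = [np.asarray(b) for b in bands]
    shape = bands[0].shape
    for b in bands:
        if b.ndim != 2 or b.shape != shape:
            raise ValueError("all bands must be 2-D with identical shape")
    with tifffile.TiffWriter(path) as tif:
        for b in bands:
            tif.write(b, extratags=_geo_tags(transform), photometric="minisblack")


def read_geotiff(path):
    """Read a multi-page GeoTIFF written by :func:`write_geotiff`.

    Returns
    -------
    (bands, transform)
        ``bands`` is a list of 2-D arrays (original dtypes preserved);
        ``transform`` a :class:`GeoTransform`.
    """
    with tifffile.TiffFile(path) as tif:
        bands = [page.asarray() for page in tif.pages]
        tags = tif.pages[0].tags
        scale = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
    transform = GeoTransform(origin_x=float(tie[3]), origin_y=float(tie[4]),
                             gsd=float(scale[0]))
    return bands, transform


def upsample_cubic(band, factor: int):
    """Cubic-spline upsampling of a coarse band to a finer grid.

    Mirrors the standard preprocessing step where 20-m/60-m bands are
    brought to the common 10-m grid. Uses pixel-centre alignment.
    """
    from scipy.ndimage import map_coordinates

    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    band = np.asarray(band, dtype=float)
    h, w = band.shape
    rows = (np.arange(h * factor) + 0.5) / factor - 0.5
    cols = (np.arange(w * factor) + 0.5) / factor - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(band, [rr, cc], order=3, mode="nearest")
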
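"""GEDI-like canopy-top rasters from high-resolution canopy height models.

A large-footprint waveform LiDAR reports the *maximum* canopy top within
its ~25-m footprint, so a 1-m airborne CHM is not directly comparable to
footprint-level heights. The standard harmonization runs a circular
max-pooling filter (12-m radius, stride 1) over the 1-m grid and then
resamples to the 10-m target grid, yielding the canopy-top metric a
footprint centred at each pixel would see.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import maximum_filter

__all__ = ["circular_max_pool", "gedi_like_canopy_top"]


def _disc_footprint(radius: float, gsd: float) -> np.ndarray:
    """Boolean disc: pixels whose centre distance is <= radius (inclusive)."""
    r_px = int(np.floor(radius / gsd))
    di, dj = np.meshgrid(np.arange(-r_px, r_px + 1), np.arange(-r_px, r_px + 1),
                         indexing="ij")
    return (di ** 2 + dj ** 2) * gsd ** 2 <= radius ** 2


def circular_max_pool(chm: np.ndarray, radius: float, gsd: float = 1.0) -> np.ndarray:
    """Per-pixel max over the circular neighbourhood, stride 1.

    Neighbourhoods are clipped at the grid boundary: no padding value ever
    enters the maximum (implemented with a -inf constant fill, which is
    neutral for max).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    chm = np.asarray(chm, dtype=float)
    return maximum_filter(chm, footprint=_disc_footprint(radius, gsd),
                          mode="constant", cval=-np.inf)


def gedi_like_canopy_top(chm: np.ndarray, radius: float = 12.0,
                         source_gsd: float = 1.0, target_gsd: float = 10.0,
                         agg: str = "mean") -> np.ndarray:
    """Circular max-pool a fine CHM, then aggregate to the target grid.

    Parameters
    ----------
    chm : 2-D array, canopy heights (m) at ``source_gsd`` resolution.
    radius : max-pooling radius in metres (12 m mirrors the footprint
        harmonization protocol; distinct from the 12.5-m footprint radius
        used for label synthesis).
    agg : ``mean`` (block average, the default resampling), ``nearest``
        (top-left sample of each block) or ``max``.

    The target GSD must be an integer multiple of the source GSD; trailing
    rows/columns that do not fill a whole block are trimmed.
    """
    ratio = target_gsd / source_gsd
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError("target GSD must be an integer multiple of source GSD")
    f = int(round(ratio))
    pooled = circular_max_pool(chm, radius, source_gsd)
    h, w = pooled.shape
    if h < f or w < f:
        raise ValueError("grid smaller than one output pixel")
    pooled = pooled[: (h // f) * f, : (w // f) * f]
    blocks = pooled.reshape(h // f, f, w // f, f)
    if agg == "mean":
        # accumulate block elements in row-major order so the result is
        # bit-reproducible and matches a literal double-loop computation
        acc = np.zeros((h // f, w // f))
        for k in range(f):
            for l in range(f):
                acc += blocks[:, k, :, l]
        return acc / (f * f)
    if agg == "max":
        return blocks.max(axis=(1, 3))
    if agg == "nearest":
        return blocks[:, 0, :, 0].copy()
    raise ValueError(f"unknown aggregation {agg!r}")
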
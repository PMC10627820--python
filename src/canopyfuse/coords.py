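"""Cyclic encoding of geographical coordinates as network input channels.

Latitude lives on [-90, 90] and needs a single bounded channel; longitude
is periodic, so it needs a sine/cosine pair to stay continuous across the
antimeridian. The three channels are appended to the reflectance bands so
the network can learn geographical priors.
"""

from __future__ import annotations

import numpy as np

__all__ = ["encode_coordinates"]


def encode_coordinates(lat, lon):
    """Encode latitude/longitude into three cyclic channels in [-1, 1].

    Parameters
    ----------
    lat, lon : array_like
        Degrees; lat in [-90, 90], lon in [-180, 180]. Scalars or arrays
        of matching shape.

    Returns
    -------
    ndarray
        Shape ``(3,) + shape(lat)``: ``(sin(pi*lat/180), sin(pi*lon/180),
        cos(pi*lon/180))``. Continuous across the antimeridian:
        lon = -180 and lon = +180 encode identically.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude out of range [-180, 180]")
    return np.stack(
        [
            np.sin(np.pi * lat / 180.0),
            np.sin(np.pi * lon / 180.0),
            np.cos(np.pi * lon / 180.0),
        ]
    )
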
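"""Geographic distance helpers (great-circle, in km)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in decimal degrees.

    Broadcasts over array inputs.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Symmetric n-by-n great-circle distance matrix for one point set."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def min_distance_to_set_km(qlon, qlat, slon, slat) -> np.ndarray:
    """Distance from each query point to its nearest point in a reference set."""
    d = haversine_km(
        np.asarray(qlon, dtype=float)[:, None],
        np.asarray(qlat, dtype=float)[:, None],
        np.asarray(slon, dtype=float)[None, :],
        np.asarray(slat, dtype=float)[None, :],
    )
    return d.min(axis=1)
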
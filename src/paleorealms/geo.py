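"""Great-circle geometry helpers on the WGS84 sphere (mean radius)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km; arguments in degrees, broadcastable."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def chord_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Straight-line (through-the-sphere) chord distance in km."""
    gc = haversine_km(lon1, lat1, lon2, lat2) / EARTH_RADIUS_KM
    return 2.0 * EARTH_RADIUS_KM * np.sin(gc / 2.0)


def to_unit_vectors(lons, lats) -> np.ndarray:
    lons = np.radians(np.asarray(lons, dtype=float))
    lats = np.radians(np.asarray(lats, dtype=float))
    return np.stack(
        [np.cos(lats) * np.cos(lons), np.cos(lats) * np.sin(lons), np.sin(lats)], axis=-1
    )


def spherical_centroid(lons, lats) -> tuple[float, float]:
    """Spherical mean of points; raises if the mean vector degenerates."""
    mean = to_unit_vectors(lons, lats).mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-9:
        raise ValueError("undefined centroid: points cancel (antipodal configuration)")
    mean /= norm
    lat = np.degrees(np.arcsin(np.clip(mean[2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(mean[1], mean[0]))
    return float(lon), float(lat)
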
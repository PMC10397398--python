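"""Great-circle and planar distances on municipality centroids."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees.

    Broadcasts over array inputs.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def euclidean_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Flat-plane distance treating degrees as km; for small synthetic grids."""
    lat1, lon1, lat2, lon2 = (np.asarray(a, float) for a in (lat1, lon1, lat2, lon2))
    return np.hypot(lat2 - lat1, lon2 - lon1)


DISTANCE_METRICS = {"haversine": haversine_km, "euclidean": euclidean_km}
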
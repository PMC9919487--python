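"""Great-circle geometry helpers.

All geographic distances in this package are haversine (spherical) distances
in kilometres; polyline chainage is the cumulative haversine length of the
segments.  Linear interpolation between vertices is done in lon/lat space,
which is adequate at the segment lengths used here (tens to hundreds of km).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
#: km per degree of great-circle arc; used to convert degree-valued buffers
#: (e.g. the two-degree pseudo-absence exclusion) into metric distances.
KM_PER_DEGREE = EARTH_RADIUS_KM * np.pi / 180.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lons, lats):
    """Full symmetric distance matrix (km) for a set of points."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])


def polyline_lengths_km(vertices: np.ndarray) -> np.ndarray:
    """Per-segment haversine lengths of a polyline given as (k, 2) lon/lat."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
        raise ValueError("polyline must be an (k>=2, 2) array of lon/lat vertices")
    return haversine_km(v[:-1, 0], v[:-1, 1], v[1:, 0], v[1:, 1])


def polyline_length_km(vertices: np.ndarray) -> float:
    return float(polyline_lengths_km(vertices).sum())


def interpolate_chainage(vertices: np.ndarray, chainages: np.ndarray) -> np.ndarray:
    """Map chainage positions (km from the first vertex) to lon/lat points.

    Positions are clipped to [0, total length].  Interpolation is linear in
    lon/lat within each segment.
    """
    v = np.asarray(vertices, dtype=float)
    seg = polyline_lengths_km(v)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.clip(np.asarray(chainages, dtype=float), 0.0, cum[-1])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(seg[idx] > 0, (s - cum[idx]) / seg[idx], 0.0)
    return v[idx] + frac[:, None] * (v[idx + 1] - v[idx])
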
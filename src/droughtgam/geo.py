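"""Great-circle geometry on the mean-Earth sphere.

All public functions accept latitude/longitude in decimal degrees and
return distances in kilometres.  Internally, points are embedded as unit
3-vectors so that pairwise distance blocks reduce to a matrix product,
which keeps the streamed Moran computation fast.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def unit_vectors(lat_deg, lon_deg):
    """Embed (lat, lon) degrees as unit 3-vectors; output shape (..., 3)."""
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    lon = np.radians(np.asarray(lon_deg, dtype=float))
    cl = np.cos(lat)
    return np.stack([cl * np.cos(lon), cl * np.sin(lon), np.sin(lat)], axis=-1)


def chord_sq_matrix(u_a: np.ndarray, u_b: np.ndarray) -> np.ndarray:
    """Squared chord distances between two sets of unit vectors.

    Shapes (m, 3) and (n, 3) give an (m, n) matrix with values in [0, 4].
    """
    g = u_a @ u_b.T
    return np.clip(2.0 - 2.0 * g, 0.0, 4.0)


def chord_to_km(chord) -> np.ndarray:
    """Convert chord length on the unit sphere to great-circle kilometres."""
    c = np.clip(np.asarray(chord, dtype=float), 0.0, 2.0)
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(c / 2.0)


def km_to_chord(km) -> np.ndarray:
    """Convert great-circle kilometres to chord length on the unit sphere."""
    half = np.clip(np.asarray(km, dtype=float) / (2.0 * EARTH_RADIUS_KM), 0.0, np.pi / 2.0)
    return 2.0 * np.sin(half)


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between broadcastable coordinate arrays."""
    u = unit_vectors(lat1, lon1)
    v = unit_vectors(lat2, lon2)
    chord = np.sqrt(np.clip(2.0 - 2.0 * np.sum(u * v, axis=-1), 0.0, 4.0))
    return chord_to_km(chord)


def pairwise_km(lat_a, lon_a, lat_b, lon_b) -> np.ndarray:
    """Dense (m, n) great-circle distance matrix in km."""
    u = unit_vectors(lat_a, lon_a)
    v = unit_vectors(lat_b, lon_b)
    return chord_to_km(np.sqrt(chord_sq_matrix(u, v)))
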
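"""Inverse-distance-weighted interpolation of test scores onto a map grid.

Each population contributes one point (its coordinates and a Z-score);
cell values are the distance-weighted average ``sum z_i d_i^-beta /
sum d_i^-beta`` with great-circle (haversine) distances, so the surface is
bounded by the data values and reproduces them exactly at the points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import PopulationPanel

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "GeoPoint",
    "GeoGrid",
    "idw_interpolate",
    "idw_values",
    "idw_at",
    "panel_points",
]


@dataclass(frozen=True)
class GeoPoint:
    latitude: float
    longitude: float
    value: float

    def __post_init__(self) -> None:
        if not (-90 <= self.latitude <= 90 and -180 <= self.longitude <= 180):
            raise ValueError(
                f"invalid coordinates ({self.latitude}, {self.longitude})"
            )


@dataclass
class GeoGrid:
    """Regular lat/lon grid of interpolated values."""

    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray  # (n_lats, n_lons)
    power: float
    spacing: float

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("power must be positive")
        if np.any(np.diff(self.lats) <= 0) or np.any(np.diff(self.lons) <= 0):
            raise ValueError("grid axes must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        lon_g, lat_g = np.meshgrid(self.lons, self.lats)
        return pd.DataFrame(
            {"lat": lat_g.ravel(), "lon": lon_g.ravel(), "value": self.values.ravel()}
        )


def haversine_km(
    lat1: np.ndarray, lon1: np.ndarray, lat2: np.ndarray, lon2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _finite_points(points: list[GeoPoint]) -> list[GeoPoint]:
    pts = [p for p in points if np.isfinite(p.value)]
    if not pts:
        raise ValueError("no points with finite values to interpolate")
    return pts


def idw_values(
    points: list[GeoPoint],
    lat: np.ndarray,
    lon: np.ndarray,
    power: float = 2.0,
) -> np.ndarray:
    """IDW values at arbitrary coordinates.

    ``v = sum z_i d_i^-power / sum d_i^-power``; a location within 1e-9 km
    of a data point takes that point's value exactly.
    """
    pts = _finite_points(points)
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    plat = np.array([p.latitude for p in pts])
    plon = np.array([p.longitude for p in pts])
    pval = np.array([p.value for p in pts])
    d = haversine_km(lat[:, None], lon[:, None], plat[None, :], plon[None, :])
    exact = d < 1e-9
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    values = np.empty(d.shape[0])
    hit = exact.any(axis=1)
    values[hit] = pval[np.argmax(exact[hit], axis=1)]
    wn = w[~hit]
    values[~hit] = (wn * pval).sum(axis=1) / wn.sum(axis=1)
    return values


def idw_at(points: list[GeoPoint], lat: float, lon: float, power: float = 2.0) -> float:
    """IDW value at a single location."""
    return float(idw_values(points, np.array([lat]), np.array([lon]), power)[0])


def idw_interpolate(
    points: list[GeoPoint],
    spacing: float = 0.5,
    power: float = 2.0,
    padding: float = 2.0,
) -> GeoGrid:
    """Interpolate point values onto a regular grid by inverse distance.

    The grid spans the points' bounding box extended by ``padding``
    degrees.  A cell within 1e-9 km of a data point takes that point's
    value exactly.
    """
    pts = _finite_points(points)
    plat = np.array([p.latitude for p in pts])
    plon = np.array([p.longitude for p in pts])
    lats = np.arange(plat.min() - padding, plat.max() + padding + spacing / 2, spacing)
    lons = np.arange(plon.min() - padding, plon.max() + padding + spacing / 2, spacing)
    lon_g, lat_g = np.meshgrid(lons, lats)
    values = idw_values(pts, lat_g.ravel(), lon_g.ravel(), power)
    return GeoGrid(lats, lons, values.reshape(len(lats), len(lons)), power, spacing)


def panel_points(
    panel: PopulationPanel, scores: dict[str, float]
) -> list[GeoPoint]:
    """One point per population from panel coordinates and a score map.

    Populations without coordinates are skipped with a warning.
    """
    pts = []
    for pop, z in scores.items():
        coords = panel.coordinates_of_population(pop)
        if coords is None:
            warnings.warn(f"population {pop!r} has no coordinates; skipped",
                          stacklevel=2)
            continue
        pts.append(GeoPoint(coords[0], coords[1], z))
    return pts
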
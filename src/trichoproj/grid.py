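"""Spatial frame: regular latitude-longitude grids on a spherical Earth.

Cell areas use the exact spherical formula ``R_e^2 * dlon * (sin(lat_top) -
sin(lat_bottom))`` so that the areas of any latitude band, and of the whole
sphere, are closed-form exact rather than quadrature approximations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from trichoproj.errors import ConfigurationError, ShapeError

EARTH_RADIUS_M = 6.371e6
#: Surface area of the sphere, 4 pi R_e^2 (m^2).
SPHERE_AREA_M2 = 4.0 * np.pi * EARTH_RADIUS_M**2


@dataclass(frozen=True)
class GridGeometry:
    """A regular lat-lon grid with per-cell areas and an ocean mask.

    Attributes
    ----------
    lat_edges : (n_lat+1,) array, degrees, monotone increasing in [-90, 90].
    lon_edges : (n_lon+1,) array, degrees, monotone, spanning 360 degrees.
    cell_area : (n_lat, n_lon) array, m^2.
    ocean_mask : (n_lat, n_lon) boolean array, True on ocean cells.
    """

    lat_edges: np.ndarray
    lon_edges: np.ndarray
    cell_area: np.ndarray
    ocean_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.cell_area.shape != self.ocean_mask.shape:
            raise ShapeError(
                f"cell_area {self.cell_area.shape} and ocean_mask "
                f"{self.ocean_mask.shape} shapes differ"
            )
        if np.any(self.cell_area <= 0):
            raise ConfigurationError("all cell areas must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_area.shape

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    @property
    def n_ocean(self) -> int:
        return int(self.ocean_mask.sum())

    def ocean_area(self) -> float:
        """Total ocean area in m^2."""
        return float(self.cell_area[self.ocean_mask].sum())

    def area_weighted_mean(self, values: np.ndarray) -> float:
        """Area-weighted mean of a per-cell field over ocean cells."""
        if values.shape != self.shape:
            raise ShapeError(f"field shape {values.shape} != grid {self.shape}")
        w = self.cell_area[self.ocean_mask]
        return float(np.sum(values[self.ocean_mask] * w) / w.sum())


def cell_areas_from_edges(lat_edges: np.ndarray, lon_edges: np.ndarray) -> np.ndarray:
    """Exact spherical areas (m^2) of every cell of a regular grid."""
    lat = np.deg2rad(np.asarray(lat_edges, dtype=float))
    lon = np.deg2rad(np.asarray(lon_edges, dtype=float))
    band = np.sin(lat[1:]) - np.sin(lat[:-1])  # (n_lat,)
    dlon = np.diff(lon)  # (n_lon,)
    return EARTH_RADIUS_M**2 * np.outer(band, dlon)


def generate_grid(
    resolution_deg: float,
    lon_resolution_deg: float | None = None,
    ocean_mask: np.ndarray | None = None,
) -> GridGeometry:
    """Build a regular global grid at the given resolution.

    Parameters
    ----------
    resolution_deg : latitude cell size in degrees; 180 must divide evenly.
    lon_resolution_deg : longitude cell size; defaults to ``resolution_deg``.
        360 must divide evenly.
    ocean_mask : optional boolean land template. Default is an all-ocean
        ("aquaplanet") mask; any deterministic template with the grid's
        shape can be injected.
    """
    if not 0.1 <= resolution_deg <= 180.0:
        raise ConfigurationError(f"latitude resolution {resolution_deg} out of range")
    lon_res = resolution_deg if lon_resolution_deg is None else lon_resolution_deg

    n_lat = 180.0 / resolution_deg
    n_lon = 360.0 / lon_res
    if abs(n_lat - round(n_lat)) > 1e-9 or abs(n_lon - round(n_lon)) > 1e-9:
        raise ConfigurationError(
            f"resolution ({resolution_deg}, {lon_res}) does not divide 180/360 evenly"
        )
    n_lat, n_lon = int(round(n_lat)), int(round(n_lon))

    lat_edges = np.linspace(-90.0, 90.0, n_lat + 1)
    lon_edges = np.linspace(0.0, 360.0, n_lon + 1)
    area = cell_areas_from_edges(lat_edges, lon_edges)
    if ocean_mask is None:
        ocean_mask = np.ones((n_lat, n_lon), dtype=bool)
    else:
        ocean_mask = np.asarray(ocean_mask, dtype=bool)
        if ocean_mask.shape != area.shape:
            raise ShapeError(
                f"injected mask shape {ocean_mask.shape} != grid {(n_lat, n_lon)}"
            )
    return GridGeometry(lat_edges, lon_edges, area, ocean_mask)
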
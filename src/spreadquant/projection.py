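"""Spherical equal-area map projections for polygon area measurement.

Occupied-area estimates must be computed in an equal-area plane: planar
(shoelace) areas of lon/lat polygons are meaningless in km². The default
projection is an Albers equal-area conic auto-parameterized from the point
extent (standard parallels at one-sixth insets of the latitude range, the
usual cartographic rule). When the parallels straddle or sit on the equator
the cone degenerates; the projection then falls back to its analytic limit,
the Lambert cylindrical equal-area projection, which is also exactly
equal-area on the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Mean Earth radius (IUGG), km.
EARTH_RADIUS_KM = 6371.0088

# Below this |n| the Albers cone is numerically flat; use the cylindrical limit.
_N_DEGENERATE = 1e-9


@dataclass(frozen=True)
class AlbersEqualArea:
    """Spherical Albers equal-area conic projection, coordinates in km.

    Parameters
    ----------
    lat1, lat2
        Standard parallels in decimal degrees.
    lon0, lat0
        Projection origin in decimal degrees.
    """

    lat1: float
    lat2: float
    lon0: float = 0.0
    lat0: float = 0.0

    @classmethod
    def from_points(cls, lons, lats) -> "AlbersEqualArea":
        """Auto-parameterize from a point cloud's extent (one-sixth rule)."""
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        if lons.size == 0:
            raise ValueError("cannot parameterize a projection from zero points")
        lat_min, lat_max = float(lats.min()), float(lats.max())
        span = lat_max - lat_min
        return cls(
            lat1=lat_min + span / 6.0,
            lat2=lat_max - span / 6.0,
            lon0=float(lons.mean()),
            lat0=0.5 * (lat_min + lat_max),
        )

    def __call__(self, lons, lats):
        """Project lon/lat arrays (degrees) to x/y arrays (km)."""
        lam = np.radians(np.asarray(lons, dtype=float))
        phi = np.radians(np.asarray(lats, dtype=float))
        lam0 = np.radians(self.lon0)
        phi0 = np.radians(self.lat0)
        phi1 = np.radians(self.lat1)
        phi2 = np.radians(self.lat2)
        R = EARTH_RADIUS_KM

        n = 0.5 * (np.sin(phi1) + np.sin(phi2))
        if abs(n) < _N_DEGENERATE:
            # Cylindrical equal-area limit (equatorial aspect).
            x = R * (lam - lam0)
            y = R * np.sin(phi)
            return x, y
        C = np.cos(phi1) ** 2 + 2.0 * n * np.sin(phi1)
        rho = R * np.sqrt(np.maximum(C - 2.0 * n * np.sin(phi), 0.0)) / n
        rho0 = R * np.sqrt(max(C - 2.0 * n * np.sin(phi0), 0.0)) / n
        theta = n * (lam - lam0)
        return rho * np.sin(theta), rho0 - rho * np.cos(theta)
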
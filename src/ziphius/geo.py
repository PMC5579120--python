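"""Shared geospatial primitives: great-circle distance, local planar
projection, a lat/lon elevation raster with bilinear sampling, and
point-in-polygon sub-area assignment.

Conventions: longitudes are signed decimal degrees in (-180, 180],
elevation is metres, negative below sea level. Distances are km on a
spherical Earth of mean radius 6371.0088 km -- distortion over the
~400 km study area is far below track-CI widths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, shape
from shapely.prepared import prep

EARTH_RADIUS_KM = 6371.0088


def normalize_lon(lon):
    """Wrap longitude(s) into (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    wrapped = ((lon - 180.0) % -360.0) + 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def great_circle_km(lat1, lon1, lat2, lon2):
    """Haversine great-circle distance in km (vectorized)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return d if d.ndim else float(d)


@dataclass
class LocalProjection:
    """Local equirectangular projection about a reference point.

    x (east) and y (north) in km. Adequate for the study-area scale;
    the error relative to a geodesic is quadratic in the span.
    """

    lat0: float
    lon0: float

    def forward(self, lat, lon):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        kx = np.cos(np.radians(self.lat0)) * np.pi / 180.0 * EARTH_RADIUS_KM
        ky = np.pi / 180.0 * EARTH_RADIUS_KM
        return (lon - self.lon0) * kx, (lat - self.lat0) * ky

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        kx = np.cos(np.radians(self.lat0)) * np.pi / 180.0 * EARTH_RADIUS_KM
        ky = np.pi / 180.0 * EARTH_RADIUS_KM
        return self.lat0 + y / ky, self.lon0 + x / kx


def sample_path(lat1, lon1, lat2, lon2, max_spacing_km=0.5):
    """Points along the path between two positions at <= max_spacing_km.

    Linear interpolation in lat/lon; over study-area distances this stays
    within metres of the great circle, which is ample for a 2-arcmin-class
    bathymetry grid. Includes both endpoints; symmetric in its endpoints.
    """
    d = great_circle_km(lat1, lon1, lat2, lon2)
    n = max(int(np.ceil(d / max_spacing_km)), 1) + 1
    f = np.linspace(0.0, 1.0, n)
    return lat1 + f * (lat2 - lat1), lon1 + f * (lon2 - lon1)


class ElevationGrid:
    """Regular lat/lon raster of elevation (m, negative underwater).

    Supports bilinear sampling (exact at nodes) and slope/aspect from
    central differences.
    """

    def __init__(self, lats, lons, values):
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        values = np.asarray(values, dtype=float)
        if values.shape != (lats.size, lons.size):
            raise ValueError("values must be (n_lat, n_lon)")
        if lats.size < 2 or lons.size < 2:
            raise ValueError("grid needs at least 2 nodes per axis")
        if np.any(np.diff(lats) <= 0) or np.any(np.diff(lons) <= 0):
            raise ValueError("axes must be strictly increasing")
        self.lats = lats
        self.lons = lons
        self.values = values

    # -- sampling ---------------------------------------------------------
    def _locate(self, axis, x):
        i = np.searchsorted(axis, x, side="right") - 1
        i = np.clip(i, 0, axis.size - 2)
        f = (x - axis[i]) / (axis[i + 1] - axis[i])
        return i, f

    def sample(self, lat, lon):
        """Bilinear elevation at (lat, lon); raises if off-grid."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        if (np.any(lat < self.lats[0]) or np.any(lat > self.lats[-1])
                or np.any(lon < self.lons[0]) or np.any(lon > self.lons[-1])):
            raise ValueError("point off elevation grid")
        i, fy = self._locate(self.lats, lat)
        j, fx = self._locate(self.lons, lon)
        v = self.values
        out = (v[i, j] * (1 - fy) * (1 - fx)
               + v[i + 1, j] * fy * (1 - fx)
               + v[i, j + 1] * (1 - fy) * fx
               + v[i + 1, j + 1] * fy * fx)
        return out if out.ndim else float(out)

    def slope_aspect(self, lat, lon):
        """Slope (deg from horizontal) and downslope aspect (deg cw from N).

        Central differences on the raster, sampled bilinearly at the point.
        Flat cells return slope 0 and aspect nan.
        """
        dlat_km = np.gradient(self.lats) * np.pi / 180.0 * EARTH_RADIUS_KM
        dlon_km = (np.gradient(self.lons) * np.pi / 180.0 * EARTH_RADIUS_KM
                   * np.cos(np.radians(np.mean(self.lats))))
        dz_dy = np.gradient(self.values, axis=0) / dlat_km[:, None] / 1000.0
        dz_dx = np.gradient(self.values, axis=1) / dlon_km[None, :] / 1000.0
        gx = ElevationGrid(self.lats, self.lons, dz_dx).sample(lat, lon)
        gy = ElevationGrid(self.lats, self.lons, dz_dy).sample(lat, lon)
        gx = np.asarray(gx, dtype=float)
        gy = np.asarray(gy, dtype=float)
        slope = np.degrees(np.arctan(np.hypot(gx, gy)))
        aspect = (np.degrees(np.arctan2(-gx, -gy))) % 360.0
        aspect = np.where(np.hypot(gx, gy) == 0.0, np.nan, aspect)
        if slope.ndim:
            return slope, aspect
        return float(slope), float(aspect)

    # -- plain-text IO ----------------------------------------------------
    def to_csv(self, path):
        with open(path, "w") as fh:
            fh.write("lon," + ",".join(f"{x:.6f}" for x in self.lons) + "\n")
            for lat, row in zip(self.lats, self.values):
                fh.write(f"{lat:.6f}," + ",".join(f"{v:.3f}" for v in row) + "\n")

    @classmethod
    def from_csv(cls, path):
        with open(path) as fh:
            header = fh.readline().strip().split(",")
            lons = np.array([float(x) for x in header[1:]])
            lats, rows = [], []
            for line in fh:
                parts = line.strip().split(",")
                if not parts or parts == [""]:
                    continue
                lats.append(float(parts[0]))
                rows.append([float(v) for v in parts[1:]])
        return cls(np.array(lats), lons, np.array(rows))


class SubareaPolygons:
    """Named sub-area polygons with point-in-polygon lookup.

    Points falling in no polygon are assigned 'Outside'. A dedicated
    'SOAR' polygon, if present, drives the on_soar flag but is not a
    sub-area label.
    """

    OUTSIDE = "Outside"

    def __init__(self, polygons):
        # polygons: dict name -> shapely geometry
        self.polygons = dict(polygons)
        self._prepared = {k: prep(v) for k, v in self.polygons.items()}

    def subarea(self, lat, lon):
        for name, geom in self._prepared.items():
            if name == "SOAR":
                continue
            if geom.covers(Point(lon, lat)):
                return name
        return self.OUTSIDE

    def on_soar(self, lat, lon):
        g = self._prepared.get("SOAR")
        return bool(g and g.covers(Point(lon, lat)))

    # -- GeoJSON IO -------------------------------------------------------
    def to_geojson(self, path):
        features = []
        for name, geom in self.polygons.items():
            features.append({
                "type": "Feature",
                "properties": {"name": name},
                "geometry": geom.__geo_interface__,
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path):
        with open(path) as fh:
            fc = json.load(fh)
        polys = {f["properties"]["name"]: shape(f["geometry"])
                 for f in fc["features"]}
        return cls(polys)
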
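"""Seasonal range delineation: kernel utilization distributions, isopleth
polygons, convex hulls, and point-in-range queries.

The home-range estimator is the classical fixed-kernel utilization
distribution: relocations are projected to a local equal-area plane, smoothed
with an isotropic Gaussian kernel whose bandwidth is a fraction (default 0.8)
of the bivariate normal reference bandwidth h_ref = sigma_hat * n^(-1/6), and
the 95% isopleth — the smallest set of highest-density cells holding 95% of
the probability mass — is returned as a polygon in lon/lat.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence
import warnings

import numpy as np
import shapely
from shapely.geometry import MultiPoint, MultiPolygon, Polygon, mapping, shape
from shapely.geometry.polygon import orient
from skimage.measure import find_contours

from .geo import LocalEqualArea


class DegenerateGeometryError(ValueError):
    """Raised for point sets without two-dimensional spread."""


@dataclass
class UtilizationDistribution:
    """Kernel density of space use on a planar grid (km units).

    ``density`` is indexed [iy, ix]; ``x`` and ``y`` are cell-centre
    coordinates. ``cell_area * density.sum()`` is 1 up to numerical error.
    """

    x: np.ndarray
    y: np.ndarray
    density: np.ndarray
    cell_area: float
    bandwidth_km: float
    projection: LocalEqualArea

    def mode_xy(self, top_fraction: float = 0.8):
        """Location of the density mode, refined as the density-weighted
        centroid of the cells above ``top_fraction`` of the peak (the raw
        argmax cell is noisy on a flat-topped density)."""
        dmax = self.density.max()
        mask = self.density >= top_fraction * dmax
        w = self.density[mask]
        yy, xx = np.nonzero(mask)
        return (float(np.average(self.x[xx], weights=w)),
                float(np.average(self.y[yy], weights=w)))


@dataclass
class RangePolygon:
    """A labelled seasonal range: geometry in lon/lat (WGS84)."""

    label: str
    geometry: MultiPolygon
    method: str                       # "kernel_isopleth" or "convex_hull"
    isopleth_level: float | None = None


def reference_bandwidth(points: np.ndarray) -> float:
    """Bivariate normal reference ("ad hoc") bandwidth h_ref = sigma * n^(-1/6)
    with sigma = sqrt((var_x + var_y) / 2), for planar points shaped (n, 2).

    Callers conventionally scale the result (the pipeline uses 0.8 * h_ref).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise ValueError("need at least 5 planar points shaped (n, 2)")
    var = pts.var(axis=0, ddof=1)
    sigma = np.sqrt(var.mean())
    if sigma <= 0:
        raise DegenerateGeometryError("zero-variance (coincident) point set")
    return float(sigma * len(pts) ** (-1.0 / 6.0))


def kernel_ud(lon: np.ndarray, lat: np.ndarray, bandwidth_scale: float = 0.8,
              grid_size: int = 250, pad_bandwidths: float = 3.0,
              projection: LocalEqualArea | None = None) -> UtilizationDistribution:
    """Gaussian fixed-kernel utilization distribution of lon/lat relocations.

    Points are projected to a local equal-area plane centred on their
    centroid, binned, and convolved with an isotropic Gaussian of bandwidth
    ``bandwidth_scale * h_ref``. The grid spans the data extent padded by
    ``pad_bandwidths`` bandwidths, with ``grid_size`` cells on the longer
    axis; the density integrates to one.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if not (0.0 < bandwidth_scale <= 1.0):
        raise ValueError("bandwidth_scale must be in (0, 1]")
    if len(lon) < 30:
        warnings.warn(f"kernel UD from only {len(lon)} relocations", stacklevel=2)
    if projection is None:
        projection = LocalEqualArea(float(np.mean(lon)), float(np.mean(lat)))
    x, y = projection.forward(lon, lat)
    h = bandwidth_scale * reference_bandwidth(np.column_stack([x, y]))

    x0, x1 = x.min() - pad_bandwidths * h, x.max() + pad_bandwidths * h
    y0, y1 = y.min() - pad_bandwidths * h, y.max() + pad_bandwidths * h
    cell = max(x1 - x0, y1 - y0) / grid_size
    nx = max(int(np.ceil((x1 - x0) / cell)), 8)
    ny = max(int(np.ceil((y1 - y0) / cell)), 8)
    counts, xedges, yedges = np.histogram2d(
        x, y, bins=[nx, ny], range=[[x0, x0 + nx * cell], [y0, y0 + ny * cell]])
    from scipy.ndimage import gaussian_filter
    dens = gaussian_filter(counts.T, sigma=h / cell, mode="constant", truncate=6.0)
    cell_area = cell * cell
    dens /= dens.sum() * cell_area
    xc = 0.5 * (xedges[:-1] + xedges[1:])
    yc = 0.5 * (yedges[:-1] + yedges[1:])
    return UtilizationDistribution(x=xc, y=yc, density=dens, cell_area=cell_area,
                                   bandwidth_km=h, projection=projection)


def _rings_to_multipolygon(rings: list[np.ndarray], ud: UtilizationDistribution,
                           threshold: float) -> MultiPolygon:
    """Classify contour rings as exteriors or holes by the density at an
    interior point, attach holes to their containing exteriors, and return
    lon/lat polygons."""
    cell = ud.x[1] - ud.x[0]
    exteriors, holes = [], []
    for ring in rings:
        if len(ring) < 4:
            continue
        poly = Polygon(ring)
        if not poly.is_valid or poly.area < 1e-12:
            continue
        rp = poly.representative_point()
        ix = int(np.clip(round((rp.x - ud.x[0]) / cell), 0, len(ud.x) - 1))
        iy = int(np.clip(round((rp.y - ud.y[0]) / cell), 0, len(ud.y) - 1))
        (exteriors if ud.density[iy, ix] >= threshold else holes).append(poly)
    exteriors.sort(key=lambda p: p.area, reverse=True)
    assembled = []
    for ext in exteriors:
        inner = [h.exterior.coords for h in holes if ext.contains(h.representative_point())]
        assembled.append(Polygon(ext.exterior.coords, inner))
    # project each vertex ring back to lon/lat
    out = []
    for poly in assembled:
        def back(coords):
            arr = np.asarray(coords)
            lon, lat = ud.projection.inverse(arr[:, 0], arr[:, 1])
            return list(zip(lon, lat))
        out.append(Polygon(back(poly.exterior.coords),
                           [back(r.coords) for r in poly.interiors]))
    geom = MultiPolygon(out)
    if not geom.is_valid:
        geom = geom.buffer(0)
        if isinstance(geom, Polygon):
            geom = MultiPolygon([geom])
    return geom


def isopleth_polygon(ud: UtilizationDistribution, level: float = 0.95,
                     label: str = "range") -> RangePolygon:
    """Polygon(s) enclosing the smallest set of highest-density cells whose
    cumulative probability reaches ``level`` (ties included)."""
    if not (0.0 < level < 1.0):
        raise ValueError("isopleth level must be in (0, 1)")
    flat = np.sort(ud.density.ravel())[::-1]
    cum = np.cumsum(flat) * ud.cell_area
    idx = int(np.searchsorted(cum, level))
    idx = min(idx, len(flat) - 1)
    threshold = flat[idx]
    padded = np.zeros((ud.density.shape[0] + 2, ud.density.shape[1] + 2))
    padded[1:-1, 1:-1] = ud.density
    cell = ud.x[1] - ud.x[0]
    rings = []
    for contour in find_contours(padded, threshold):
        # contour coords are (row, col) in the padded array
        xs = ud.x[0] + (contour[:, 1] - 1.0) * cell
        ys = ud.y[0] + (contour[:, 0] - 1.0) * cell
        ring = np.column_stack([xs, ys])
        if not np.allclose(ring[0], ring[-1]):
            ring = np.vstack([ring, ring[:1]])
        rings.append(ring)
    geom = _rings_to_multipolygon(rings, ud, threshold)
    return RangePolygon(label=label, geometry=geom, method="kernel_isopleth",
                        isopleth_level=level)


def super_range(tracks: "object", label: str = "super", level: float = 0.95,
                bandwidth_scale: float = 0.8, subset=None,
                grid_size: int = 250) -> RangePolygon:
    """Pooled ("super") kernel range across birds: combine the selected fixes
    of all birds and take the ``level`` isopleth of their joint UD.

    ``tracks`` is a DataFrame with lon/lat columns; ``subset`` an optional
    boolean mask or callable returning one.
    """
    df = tracks
    if subset is not None:
        mask = subset(df) if callable(subset) else np.asarray(subset, dtype=bool)
        df = df.loc[mask]
    if len(df) == 0:
        raise ValueError("empty fix pool for super range")
    ud = kernel_ud(df["lon"].to_numpy(), df["lat"].to_numpy(),
                   bandwidth_scale=bandwidth_scale, grid_size=grid_size)
    return isopleth_polygon(ud, level=level, label=label)


def convex_hull_range(points: np.ndarray, label: str = "breeding") -> RangePolygon:
    """Smallest convex polygon covering the given lon/lat points (n, 2)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 lon/lat points")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if not isinstance(hull, Polygon):
        raise DegenerateGeometryError("points are collinear; hull is degenerate")
    return RangePolygon(label=label, geometry=MultiPolygon([hull]),
                        method="convex_hull", isopleth_level=None)


def point_in_range(lon, lat, polygon: RangePolygon) -> np.ndarray | bool:
    """Boundary-inclusive containment of lon/lat point(s) in a range polygon.

    A fix exactly on the edge counts as inside, so a bird sitting on its range
    boundary does not flicker between departed and present.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    geom = polygon.geometry
    shapely.prepare(geom)
    res = shapely.intersects_xy(geom, lon, lat)
    return bool(res) if res.ndim == 0 else res


# ----------------------------------------------------------------------
# GeoJSON I/O (RFC 7946: WGS84; exteriors counter-clockwise, holes clockwise)

def _oriented(geom: MultiPolygon) -> MultiPolygon:
    return MultiPolygon([orient(p, sign=1.0) for p in geom.geoms])


def write_geojson(polygons: Iterable[RangePolygon], path) -> None:
    features = []
    for rp in polygons:
        props = {"label": rp.label, "method": rp.method}
        if rp.isopleth_level is not None:
            props["isopleth_level"] = rp.isopleth_level
        features.append({"type": "Feature", "properties": props,
                         "geometry": mapping(_oriented(rp.geometry))})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path) -> list[RangePolygon]:
    with open(path) as fh:
        fc = json.load(fh)
    out = []
    for feat in fc["features"]:
        geom = shape(feat["geometry"])
        if isinstance(geom, Polygon):
            geom = MultiPolygon([geom])
        props = feat.get("properties", {})
        out.append(RangePolygon(label=props.get("label", "range"), geometry=geom,
                                method=props.get("method", "kernel_isopleth"),
                                isopleth_level=props.get("isopleth_level")))
    return out
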
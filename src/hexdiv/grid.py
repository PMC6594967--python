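"""Equal-area hexagonal grids, latitude/depth binning, and gridded rasters.

The study region is tessellated with hexagonal cells of (by default)
~50,000 km² on a spherical Lambert azimuthal equal-area (LAEA) projection
centred on the region. Because LAEA preserves area exactly on the sphere,
a planar hexagon of area A corresponds to a spherical cell of area A, so
the grid is equal-area by construction. Cells crossing the study-box
boundary are clipped to it so that cell areas sum to the spherical area
of the box.

Latitude bands (5°) and depth intervals (100 m) are half-open [lo, hi)
with the top edge closed. All spherical areas use a sphere of radius
R = 6371 km.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

EARTH_RADIUS_KM = 6371.0

#: Study bounding box (lat_min, lat_max, lon_min, lon_max), degrees.
STUDY_BBOX = (0.0, 90.0, 100.0, 180.0)


# ---------------------------------------------------------------------------
# Spherical Lambert azimuthal equal-area projection (Snyder 1987, sphere)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LaeaProjection:
    """Spherical LAEA projection centred at (lat0, lon0), output in km."""

    lat0: float
    lon0: float
    radius: float = EARTH_RADIUS_KM

    def forward(self, lat, lon):
        """Project (lat, lon) degrees -> planar (x, y) km."""
        lat = np.deg2rad(np.asarray(lat, dtype=float))
        lon = np.deg2rad(np.asarray(lon, dtype=float))
        lat0 = math.radians(self.lat0)
        dlon = lon - math.radians(self.lon0)
        denom = 1.0 + np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(dlon)
        # antipode of the projection centre is a singularity; the study box
        # never reaches it, guard anyway
        denom = np.maximum(denom, 1e-12)
        k = np.sqrt(2.0 / denom)
        x = self.radius * k * np.cos(lat) * np.sin(dlon)
        y = self.radius * k * (np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(dlon))
        return x, y

    def inverse(self, x, y):
        """Planar (x, y) km -> (lat, lon) degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lat0 = math.radians(self.lat0)
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / (2.0 * self.radius), -1.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            lat = np.where(
                rho == 0.0,
                lat0,
                np.arcsin(np.clip(np.cos(c) * math.sin(lat0) + y * np.sin(c) * math.cos(lat0) / np.where(rho == 0, 1, rho), -1, 1)),
            )
            lon = math.radians(self.lon0) + np.arctan2(
                x * np.sin(c),
                rho * math.cos(lat0) * np.cos(c) - y * math.sin(lat0) * np.sin(c),
            )
        return np.rad2deg(lat), np.rad2deg(lon)


def zone_area_km2(lat_lo: float, lat_hi: float, lon_lo: float, lon_hi: float,
                  radius: float = EARTH_RADIUS_KM) -> float:
    """Exact spherical area of a lat/lon rectangle: R²·Δλ·(sin φ₂ − sin φ₁)."""
    dlam = math.radians(lon_hi - lon_lo)
    return radius ** 2 * dlam * (math.sin(math.radians(lat_hi)) - math.sin(math.radians(lat_lo)))


# ---------------------------------------------------------------------------
# Hexagonal grid
# ---------------------------------------------------------------------------

@dataclass
class HexCell:
    cell_id: str
    centroid: tuple[float, float]          # (lat, lon) degrees
    vertices: list[tuple[float, float]]    # six (lat, lon) pairs
    spherical_area: float                  # km², clipped to the study box
    axial: tuple[int, int] = (0, 0)        # axial (q, r) indices in the tessellation
    planar_centroid: tuple[float, float] = (0.0, 0.0)


@dataclass
class HexGrid:
    """Equal-area hexagonal tessellation of a lat/lon study box."""

    target_area: float
    bbox: tuple[float, float, float, float]
    projection: LaeaProjection
    cells: list[HexCell]
    hex_size: float                        # circumradius of a hexagon, km
    _by_axial: dict[tuple[int, int], HexCell] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._by_axial:
            self._by_axial = {c.axial: c for c in self.cells}

    def cell(self, cell_id: str) -> HexCell:
        return next(c for c in self.cells if c.cell_id == cell_id)

    # -- point membership ---------------------------------------------------

    def locate(self, lat, lon):
        """Map points to cell ids; exactly one cell per in-box point.

        Boundary points between two hexagons resolve to the nearer planar
        centroid, ties to the lowest cell_id (the axial hex-rounding rule
        implements exactly this nearest-centre partition).
        """
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        x, y = self.projection.forward(lat, lon)
        q, r = _pixel_to_axial(x, y, self.hex_size)
        out = []
        for qi, ri, la, lo in zip(q, r, lat, lon):
            cell = self._by_axial.get((int(qi), int(ri)))
            if cell is None:
                raise RuntimeError(
                    f"tiling error: point ({la:.4f}, {lo:.4f}) maps to no grid cell"
                )
            out.append(cell.cell_id)
        return out

    def to_geojson(self) -> dict:
        feats = []
        for c in self.cells:
            ring = [[lon, lat] for lat, lon in c.vertices]
            ring.append(ring[0])
            feats.append({
                "type": "Feature",
                "properties": {
                    "cell_id": c.cell_id,
                    "area_km2": c.spherical_area,
                    "centroid_lat": c.centroid[0],
                    "centroid_lon": c.centroid[1],
                },
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            })
        return {"type": "FeatureCollection", "features": feats}


def _axial_to_pixel(q, r, size):
    # pointy-top axial coordinates
    x = size * math.sqrt(3.0) * (np.asarray(q, float) + np.asarray(r, float) / 2.0)
    y = size * 1.5 * np.asarray(r, float)
    return x, y


def _pixel_to_axial(x, y, size):
    qf = (np.sqrt(3.0) / 3.0 * np.asarray(x, float) - np.asarray(y, float) / 3.0) / size
    rf = (2.0 / 3.0 * np.asarray(y, float)) / size
    return _hex_round(qf, rf)


def _hex_round(qf, rf):
    """Round fractional axial coordinates to the containing hexagon (cube rounding)."""
    xf = np.asarray(qf, float)
    zf = np.asarray(rf, float)
    yf = -xf - zf
    rx, ry, rz = np.round(xf), np.round(yf), np.round(zf)
    dx, dy, dz = np.abs(rx - xf), np.abs(ry - yf), np.abs(rz - zf)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    return rx.astype(int), rz.astype(int)


def build_hex_grid(target_area: float = 50_000.0,
                   bbox: tuple[float, float, float, float] = STUDY_BBOX) -> HexGrid:
    """Tessellate the study box with ~``target_area`` km² equal-area hexagons.

    Parameters
    ----------
    target_area : planar (= spherical) hexagon area in km².
    bbox : (lat_min, lat_max, lon_min, lon_max) in degrees.

    The tessellation is axial (pointy-top) in LAEA coordinates centred on
    the box. Cells intersecting the box are kept; their ``spherical_area``
    is the area of the hexagon clipped to the projected box boundary, so
    areas sum to the spherical area of the box.
    """
    lat_min, lat_max, lon_min, lon_max = bbox
    if not (lat_min < lat_max and lon_min < lon_max):
        raise ValueError(f"degenerate bounding box {bbox!r}")
    if target_area <= 0:
        raise ValueError("target_area must be positive")

    proj = LaeaProjection(lat0=(lat_min + lat_max) / 2.0, lon0=(lon_min + lon_max) / 2.0)
    size = math.sqrt(2.0 * target_area / (3.0 * math.sqrt(3.0)))

    # densified box boundary in the projected plane
    box_poly = Polygon(zip(*proj.forward(*_box_boundary(bbox, step=0.05))))

    bx = box_poly.bounds
    margin = 2.5 * size
    r_min = int(math.floor((bx[1] - margin) / (1.5 * size)))
    r_max = int(math.ceil((bx[3] + margin) / (1.5 * size)))

    hex_angles = [math.pi / 6 + i * math.pi / 3 for i in range(6)]
    cells: list[HexCell] = []
    for r in range(r_min - 1, r_max + 2):
        # x = size*sqrt(3)*(q + r/2)  =>  q = x/(size*sqrt(3)) - r/2
        q_lo = int(math.floor((bx[0] - margin) / (size * math.sqrt(3.0)) - r / 2.0))
        q_hi = int(math.ceil((bx[2] + margin) / (size * math.sqrt(3.0)) - r / 2.0))
        for q in range(q_lo - 1, q_hi + 2):
            cx, cy = _axial_to_pixel(q, r, size)
            vx = [cx + size * math.cos(a) for a in hex_angles]
            vy = [cy + size * math.sin(a) for a in hex_angles]
            hexagon = Polygon(zip(vx, vy))
            clipped = hexagon.intersection(box_poly)
            if clipped.is_empty or clipped.area <= 0:
                continue
            lat_c, lon_c = proj.inverse(cx, cy)
            vlat, vlon = proj.inverse(np.array(vx), np.array(vy))
            cells.append(HexCell(
                cell_id=f"q{q}r{r}",
                centroid=(float(lat_c), float(lon_c)),
                vertices=list(zip(vlat.tolist(), vlon.tolist())),
                spherical_area=float(clipped.area),
                axial=(q, r),
                planar_centroid=(cx, cy),
            ))
    cells.sort(key=lambda c: c.axial)
    return HexGrid(target_area=target_area, bbox=bbox, projection=proj,
                   cells=cells, hex_size=size)


def _corner_axial(x, y, size):
    q, r = _pixel_to_axial(np.asarray([x]), np.asarray([y]), size)
    return int(q[0]), int(r[0])


def _box_boundary(bbox, step=0.05):
    """Densified lat/lon boundary ring of a box (degrees)."""
    lat_min, lat_max, lon_min, lon_max = bbox
    lats, lons = [], []
    lon_steps = np.arange(lon_min, lon_max, step)
    lat_steps = np.arange(lat_min, lat_max, step)
    lats += [lat_min] * len(lon_steps); lons += lon_steps.tolist()
    lats += lat_steps.tolist(); lons += [lon_max] * len(lat_steps)
    lats += [lat_max] * len(lon_steps); lons += lon_steps[::-1].tolist()
    lats += lat_steps[::-1].tolist(); lons += [lon_min] * len(lat_steps)
    return np.array(lats), np.array(lons)


def assign_to_cell(records: Sequence, grid: HexGrid) -> dict[str, str]:
    """Assign cleaned records to hexagon cells; returns record_id -> cell_id."""
    if not records:
        return {}
    lat = np.array([r.latitude for r in records])
    lon = np.array([r.longitude for r in records])
    ids = grid.locate(lat, lon)
    return {r.record_id: cid for r, cid in zip(records, ids)}


# ---------------------------------------------------------------------------
# Latitude bands and depth intervals
# ---------------------------------------------------------------------------

BAND_WIDTH = 5.0
DEPTH_INTERVAL = 100.0
MAX_DEPTH = 11_000.0

#: Named coarse depth bins used for shallow-water reporting (m).
COARSE_DEPTH_BINS = ((0, 50), (50, 100), (100, 200), (200, 500), (500, MAX_DEPTH))


def assign_band(latitude, width: float = BAND_WIDTH, lat_max: float = 90.0):
    """5° band index for latitudes in [0, lat_max]; bands [5k, 5k+5), top closed."""
    lat = np.asarray(latitude, dtype=float)
    if np.any((lat < 0) | (lat > lat_max)):
        bad = lat[(lat < 0) | (lat > lat_max)]
        raise ValueError(f"latitude outside [0, {lat_max}]: {bad[:5]}")
    idx = np.floor(lat / width).astype(int)
    n_bands = int(round(lat_max / width))
    idx = np.minimum(idx, n_bands - 1)
    return idx if idx.ndim else int(idx)


def band_edges(index: int, width: float = BAND_WIDTH) -> tuple[float, float]:
    return index * width, (index + 1) * width


def assign_depth_interval(depth, width: float = DEPTH_INTERVAL, max_depth: float = MAX_DEPTH):
    """100-m interval index for depths in [0, max_depth]; [100k, 100k+100), top closed."""
    d = np.asarray(depth, dtype=float)
    if np.any((d < 0) | (d > max_depth)):
        bad = d[(d < 0) | (d > max_depth)]
        raise ValueError(f"depth outside [0, {max_depth}]: {bad[:5]}")
    idx = np.floor(d / width).astype(int)
    n = int(round(max_depth / width))
    idx = np.minimum(idx, n - 1)
    return idx if idx.ndim else int(idx)


# ---------------------------------------------------------------------------
# Rasters
# ---------------------------------------------------------------------------

@dataclass
class EnvRaster:
    """Regular lat/lon grid of one environmental variable.

    ``values[i, j]`` covers latitudes ``origin_lat + i*cs .. +(i+1)*cs`` and
    longitudes ``origin_lon + j*cs .. +(j+1)*cs`` where ``cs`` is the cell
    size in degrees (``cell_size_arcmin``/60); row 0 is the southernmost.
    """

    name: str
    origin_lat: float
    origin_lon: float
    cell_size_arcmin: float
    values: np.ndarray
    units: str = ""
    nodata: float = -9999.0

    def __post_init__(self):
        if self.cell_size_arcmin <= 0:
            raise ValueError("cell size must be positive")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def cell_size_deg(self) -> float:
        return self.cell_size_arcmin / 60.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cs = self.cell_size_deg
        n_rows, n_cols = self.values.shape
        lats = self.origin_lat + cs * (np.arange(n_rows) + 0.5)
        lons = self.origin_lon + cs * (np.arange(n_cols) + 0.5)
        return lats, lons

    def extent(self) -> tuple[float, float, float, float]:
        cs = self.cell_size_deg
        n_rows, n_cols = self.values.shape
        return (self.origin_lat, self.origin_lat + n_rows * cs,
                self.origin_lon, self.origin_lon + n_cols * cs)

    def cell_areas_km2(self) -> np.ndarray:
        """Exact spherical area of every raster cell (km²), shape (n_rows, 1)-broadcastable."""
        cs = self.cell_size_deg
        n_rows, n_cols = self.values.shape
        lat_lo = self.origin_lat + cs * np.arange(n_rows)
        areas = (EARTH_RADIUS_KM ** 2 * math.radians(cs)
                 * (np.sin(np.deg2rad(lat_lo + cs)) - np.sin(np.deg2rad(lat_lo))))
        return np.repeat(areas[:, None], n_cols, axis=1)

    # -- plain-text round trip ---------------------------------------------

    def write_ascii(self, path) -> None:
        n_rows, n_cols = self.values.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {n_cols}\n")
            fh.write(f"nrows {n_rows}\n")
            fh.write(f"xllcorner {self.origin_lon!r}\n")
            fh.write(f"yllcorner {self.origin_lat!r}\n")
            fh.write(f"cellsize_arcmin {self.cell_size_arcmin!r}\n")
            fh.write(f"nodata_value {self.nodata!r}\n")
            fh.write(f"name {self.name}\n")
            fh.write(f"units {self.units}\n")
            # write north-up, as ESRI ASCII grids do
            np.savetxt(fh, self.values[::-1], fmt="%.6g")

    @classmethod
    def read_ascii(cls, path) -> "EnvRaster":
        header: dict[str, str] = {}
        with open(path) as fh:
            for _ in range(8):
                key, _, val = fh.readline().partition(" ")
                header[key.strip()] = val.strip()
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)[::-1]
        return cls(name=header.get("name", ""),
                   origin_lat=float(header["yllcorner"]),
                   origin_lon=float(header["xllcorner"]),
                   cell_size_arcmin=float(header["cellsize_arcmin"]),
                   values=values,
                   units=header.get("units", ""),
                   nodata=float(header["nodata_value"]))


def sample_raster_at(points: Iterable[tuple[float, float]], raster: EnvRaster) -> np.ndarray:
    """Nearest-cell-centre lookup of raster values at (lat, lon) points.

    Nodata cells propagate as NaN; points outside the raster extent raise.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.size == 0:
        return np.empty(0)
    lat, lon = pts[:, 0], pts[:, 1]
    lat_lo, lat_hi, lon_lo, lon_hi = raster.extent()
    bad = (lat < lat_lo) | (lat > lat_hi) | (lon < lon_lo) | (lon > lon_hi)
    if np.any(bad):
        raise ValueError(f"points outside raster extent: {pts[bad][:5].tolist()}")
    cs = raster.cell_size_deg
    i = np.clip(((lat - lat_lo) / cs).astype(int), 0, raster.shape[0] - 1)
    j = np.clip(((lon - lon_lo) / cs).astype(int), 0, raster.shape[1] - 1)
    vals = raster.values[i, j].astype(float)
    vals[vals == raster.nodata] = np.nan
    return vals


def band_ocean_area(band_index: int, ocean_mask: EnvRaster,
                    bbox: tuple[float, float, float, float] = STUDY_BBOX,
                    width: float = BAND_WIDTH) -> float:
    """Spherical ocean area (km²) of one latitude band within the study box.

    Sums exact per-raster-cell zone areas over mask==1 cells whose centres
    fall in band ∩ bbox.
    """
    lo, hi = band_edges(band_index, width)
    lat_min, lat_max, lon_min, lon_max = bbox
    lats, lons = ocean_mask.cell_centers()
    in_band = (lats >= max(lo, lat_min)) & (lats < min(hi, lat_max))
    in_lon = (lons >= lon_min) & (lons < lon_max)
    if not in_band.any() or not in_lon.any():
        return 0.0
    sub = ocean_mask.values[np.ix_(in_band, in_lon)]
    areas = ocean_mask.cell_areas_km2()[np.ix_(in_band, in_lon)]
    return float(np.sum(areas[sub == 1]))


def grid_to_geojson_file(grid: HexGrid, path) -> None:
    with open(path, "w") as fh:
        json.dump(grid.to_geojson(), fh)
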
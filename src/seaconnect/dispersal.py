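"""Passive larval drift over gridded ocean currents.

Particles are released daily from ~3 km release cells inside spawning
polygons during each site's spawning season, advected hourly by bilinear
interpolation of the (daily) velocity field, and classified by the first
event among: entering a settlement polygon (``settled``), running aground
(``beached``), leaving the grid (``lost_open_ocean``), or surviving the full
pelagic larval duration (``expired``). Aggregating fates gives pairwise
source→sink connectivity probabilities.

Velocity fields are piecewise-constant per day in time (the forcing is
daily); spatial interpolation is bilinear over the four surrounding grid
nodes, with land nodes contributing zero velocity. The default integrator is
forward Euler at 1 h; a classical RK4 scheme is available for convergence
checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import Point, Polygon, shape, mapping
from shapely.prepared import prep

from .geo import EARTH_RADIUS_KM, M_PER_DEG_LAT, haversine_km

__all__ = [
    "VelocityField",
    "SpawningSite",
    "Particle",
    "TrajectorySet",
    "ConnectivityMatrix",
    "interpolate_velocity",
    "advect",
    "run_simulation",
    "dispersal_stats",
    "connectivity_matrix",
    "read_sites_geojson",
    "write_sites_geojson",
]

FATES = ("settled", "beached", "lost_open_ocean", "expired")


class OutOfDomainError(Exception):
    """Query point falls outside the velocity grid."""


class LandError(Exception):
    """The whole interpolation stencil is land."""


@dataclass
class VelocityField:
    """Time-indexed u/v currents on a regular lon/lat grid with a land mask.

    ``u``/``v`` are eastward/northward speed in m/s with shape
    (time, lat, lon); ``land_mask`` is True on land cells.
    """

    lon: np.ndarray
    lat: np.ndarray
    time: np.ndarray  # np.datetime64[ns], daily
    u: np.ndarray
    v: np.ndarray
    land_mask: np.ndarray
    land_polygons: list = dc_field(default_factory=list)

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.time = np.asarray(self.time, dtype="datetime64[ns]")
        for name in ("lon", "lat"):
            c = getattr(self, name)
            if c.size > 1:
                d = np.diff(c)
                if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6):
                    raise ValueError(f"{name} must be strictly increasing with uniform step")
        if self.u.shape != (self.time.size, self.lat.size, self.lon.size):
            raise ValueError("u shape must be (time, lat, lon)")
        if self.v.shape != self.u.shape:
            raise ValueError("u and v shapes differ")
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.land_mask.shape != (self.lat.size, self.lon.size):
            raise ValueError("land_mask shape must be (lat, lon)")

    @property
    def step_deg(self) -> float:
        return float(self.lon[1] - self.lon[0]) if self.lon.size > 1 else 0.0

    def day_index(self, t: np.datetime64) -> int:
        """Index of the daily field active at time ``t`` (piecewise constant)."""
        t = np.datetime64(t, "ns")
        if t < self.time[0] or t >= self.time[-1] + np.timedelta64(1, "D"):
            raise OutOfDomainError(f"time {t} outside field coverage")
        return int((t - self.time[0]) // np.timedelta64(1, "D"))

    def day_index_clamped(self, t: np.datetime64) -> int:
        """Like :meth:`day_index` but clamped to the covered range."""
        t = np.datetime64(t, "ns")
        k = int((t - self.time[0]) // np.timedelta64(1, "D"))
        return int(np.clip(k, 0, self.time.size - 1))

    def in_extent(self, lon: float, lat: float) -> bool:
        return (self.lon[0] <= lon <= self.lon[-1]) and (self.lat[0] <= lat <= self.lat[-1])

    def is_land(self, lon: float, lat: float) -> bool:
        """Nearest-cell land check (used for release validation)."""
        i = int(np.clip(np.rint((lat - self.lat[0]) / (self.lat[1] - self.lat[0])), 0, self.lat.size - 1)) if self.lat.size > 1 else 0
        j = int(np.clip(np.rint((lon - self.lon[0]) / (self.lon[1] - self.lon[0])), 0, self.lon.size - 1)) if self.lon.size > 1 else 0
        return bool(self.land_mask[i, j])

    # ---- NetCDF round trip (CF-style: dims time/lat/lon, u/v in m/s) ----
    def to_netcdf(self, path) -> None:
        u = np.where(self.land_mask[None, :, :], np.nan, self.u)
        v = np.where(self.land_mask[None, :, :], np.nan, self.v)
        ds = xr.Dataset(
            {
                "u": (("time", "lat", "lon"), u, {"units": "m s-1", "long_name": "eastward_sea_water_velocity"}),
                "v": (("time", "lat", "lon"), v, {"units": "m s-1", "long_name": "northward_sea_water_velocity"}),
                "land_mask": (("lat", "lon"), self.land_mask.astype("i1")),
            },
            coords={
                "time": self.time,
                "lat": ("lat", self.lat, {"units": "degrees_north"}),
                "lon": ("lon", self.lon, {"units": "degrees_east"}),
            },
        )
        ds.to_netcdf(path)

    @classmethod
    def from_netcdf(cls, path) -> "VelocityField":
        with xr.open_dataset(path) as ds:
            ds = ds.load()
        if "land_mask" in ds:
            mask = ds["land_mask"].values.astype(bool)
        else:  # HYCOM-style files mark land with NaN fill
            mask = np.isnan(ds["u"].isel(time=0).values)
        u = np.nan_to_num(ds["u"].values, nan=0.0)
        v = np.nan_to_num(ds["v"].values, nan=0.0)
        return cls(lon=ds["lon"].values, lat=ds["lat"].values, time=ds["time"].values, u=u, v=v, land_mask=mask)


@dataclass
class SpawningSite:
    """A spawning location: polygon, release cells, season, settlement target."""

    name: str
    polygon: Polygon
    release_cells: list  # [(lon, lat), ...]
    season: tuple  # (start day-of-year, end day-of-year), inclusive
    settlement_polygon: Polygon | None = None

    def __post_init__(self):
        start, end = self.season
        if not (1 <= start <= end <= 366):
            raise ValueError("season must satisfy 1 <= start <= end <= 366 within a year")
        if self.settlement_polygon is None:
            self.settlement_polygon = self.polygon

    @classmethod
    def from_polygon(
        cls,
        name: str,
        polygon: Polygon,
        season: tuple,
        field: VelocityField | None = None,
        cell_km: float = 3.0,
        settlement_buffer_km: float = 10.0,
    ) -> "SpawningSite":
        """Build a site by rasterising the polygon into ~``cell_km`` release cells.

        Cells whose centroid is on land (per ``field``) are dropped. The
        settlement polygon defaults to the spawning polygon buffered by
        ``settlement_buffer_km`` (local equal-area approximation).
        """
        cells = rasterise_release_cells(polygon, cell_km=cell_km, field=field)
        deg = settlement_buffer_km / (M_PER_DEG_LAT / 1000.0)
        settle = polygon.buffer(deg) if settlement_buffer_km > 0 else polygon
        return cls(name=name, polygon=polygon, release_cells=cells, season=season, settlement_polygon=settle)


def rasterise_release_cells(polygon: Polygon, cell_km: float = 3.0, field: VelocityField | None = None) -> list:
    """Centroids of a ~``cell_km`` grid laid over the polygon, interior + ocean only."""
    minx, miny, maxx, maxy = polygon.bounds
    lat_c = 0.5 * (miny + maxy)
    dlat = cell_km / (M_PER_DEG_LAT / 1000.0)
    dlon = dlat / max(np.cos(np.radians(lat_c)), 1e-6)
    prepared = prep(polygon)
    cells = []
    lat = miny + dlat / 2.0
    while lat < maxy:
        lon = minx + dlon / 2.0
        while lon < maxx:
            if prepared.contains(Point(lon, lat)):
                if field is None or (field.in_extent(lon, lat) and not field.is_land(lon, lat)):
                    cells.append((lon, lat))
            lon += dlon
        lat += dlat
    return cells


@dataclass
class Particle:
    source_site: str
    release_time: np.datetime64
    fate: str
    settle_site: str | None
    dispersal_km: float
    final_lon: float
    final_lat: float
    n_hours: int
    positions: np.ndarray | None = None  # (n, 2) lon/lat if recorded


@dataclass
class TrajectorySet:
    particles: list
    site_names: list

    def __len__(self):
        return len(self.particles)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": [p.source_site for p in self.particles],
                "release_time": [p.release_time for p in self.particles],
                "fate": [p.fate for p in self.particles],
                "settle_site": [p.settle_site for p in self.particles],
                "dispersal_km": [p.dispersal_km for p in self.particles],
                "final_lon": [p.final_lon for p in self.particles],
                "final_lat": [p.final_lat for p in self.particles],
                "n_hours": [p.n_hours for p in self.particles],
            }
        )


@dataclass
class ConnectivityMatrix:
    """P[i][j]: proportion of particles released at site i that settled at site j."""

    sites: list
    P: np.ndarray
    n_released: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.sites, columns=self.sites)

    @property
    def local_retention(self) -> np.ndarray:
        return np.diag(self.P)


def interpolate_velocity(field: VelocityField, lon: float, lat: float, t: np.datetime64):
    """Bilinear (u, v) at (lon, lat) using the nearest-day field.

    Land nodes contribute zero velocity; if all four stencil nodes are land a
    :class:`LandError` is raised, outside the grid an :class:`OutOfDomainError`.
    """
    if not field.in_extent(lon, lat):
        raise OutOfDomainError(f"({lon}, {lat}) outside grid")
    k = field.day_index(t)
    return _bilinear(field, lon, lat, k)


def _bilinear(field: VelocityField, lon: float, lat: float, k: int):
    nx, ny = field.lon.size, field.lat.size
    dx = field.lon[1] - field.lon[0] if nx > 1 else 1.0
    dy = field.lat[1] - field.lat[0] if ny > 1 else 1.0
    fx = (lon - field.lon[0]) / dx
    fy = (lat - field.lat[0]) / dy
    j0 = int(np.clip(np.floor(fx), 0, max(nx - 2, 0)))
    i0 = int(np.clip(np.floor(fy), 0, max(ny - 2, 0)))
    j1 = min(j0 + 1, nx - 1)
    i1 = min(i0 + 1, ny - 1)
    tx = float(np.clip(fx - j0, 0.0, 1.0))
    ty = float(np.clip(fy - i0, 0.0, 1.0))
    w = np.array([(1 - tx) * (1 - ty), tx * (1 - ty), (1 - tx) * ty, tx * ty])
    ii = (i0, i0, i1, i1)
    jj = (j0, j1, j0, j1)
    land = np.array([field.land_mask[a, b] for a, b in zip(ii, jj)])
    if land.all():
        raise LandError(f"all stencil nodes land at ({lon}, {lat})")
    uu = np.array([field.u[k, a, b] for a, b in zip(ii, jj)])
    vv = np.array([field.v[k, a, b] for a, b in zip(ii, jj)])
    uu[land] = 0.0
    vv[land] = 0.0
    return float(w @ uu), float(w @ vv)


def _velocity_deg_per_s(field: VelocityField, lon: float, lat: float, k: int):
    u, v = _bilinear(field, lon, lat, k)
    m_per_deg = M_PER_DEG_LAT
    dlon = u / (m_per_deg * max(np.cos(np.radians(lat)), 1e-9))
    dlat = v / m_per_deg
    return dlon, dlat


def advect(
    field: VelocityField,
    site: SpawningSite,
    release_time,
    release_cell: tuple | None = None,
    step: float = 1.0,
    max_days: int = 30,
    sites_all: Sequence[SpawningSite] | None = None,
    method: str = "euler",
    min_age_hours: float = 0.0,
    record_positions: bool = False,
) -> Particle:
    """Advect one particle from a release cell and classify its fate.

    ``step`` is the integration step in hours. Fate is the first event among
    settlement (entering any site's settlement polygon, once older than
    ``min_age_hours``), beaching (interpolation stencil entirely land),
    leaving the grid, or expiry at ``max_days``.
    """
    if max_days < 1:
        raise ValueError("max_days must be >= 1")
    release_time = np.datetime64(release_time, "ns")
    if release_cell is None:
        if not site.release_cells:
            raise ValueError(f"site {site.name} has no release cells")
        release_cell = site.release_cells[0]
    lon0, lat0 = float(release_cell[0]), float(release_cell[1])
    if field.is_land(lon0, lat0):
        raise ValueError("release cell is on land")
    if sites_all is None:
        sites_all = [site]
    settle_polys = [(s.name, prep(s.settlement_polygon)) for s in sites_all]
    land_polys = [prep(p) for p in field.land_polygons]

    dt_s = step * 3600.0
    n_steps = int(round(max_days * 24.0 / step))
    lon, lat = lon0, lat0
    t = release_time
    fate, settle_site = None, None
    positions = [(lon, lat)] if record_positions else None
    hours = 0.0

    def check_settle(x, y, age_h):
        if age_h < min_age_hours:
            return None
        pt = Point(x, y)
        for name, poly in settle_polys:
            if poly.contains(pt):
                return name
        return None

    s0 = check_settle(lon, lat, 0.0)
    if s0 is not None:
        fate, settle_site = "settled", s0
        n_steps = 0

    for istep in range(n_steps):
        k = field.day_index_clamped(t)
        try:
            if method == "euler":
                dlo, dla = _velocity_deg_per_s(field, lon, lat, k)
                nlon = lon + dlo * dt_s
                nlat = lat + dla * dt_s
            elif method == "rk4":
                k1 = _velocity_deg_per_s(field, lon, lat, k)
                k2 = _velocity_deg_per_s(field, lon + 0.5 * dt_s * k1[0], lat + 0.5 * dt_s * k1[1], k)
                k3 = _velocity_deg_per_s(field, lon + 0.5 * dt_s * k2[0], lat + 0.5 * dt_s * k2[1], k)
                k4 = _velocity_deg_per_s(field, lon + dt_s * k3[0], lat + dt_s * k3[1], k)
                nlon = lon + dt_s / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
                nlat = lat + dt_s / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            else:
                raise ValueError(f"unknown integrator {method!r}")
        except LandError:
            fate = "beached"
            break
        if not field.in_extent(nlon, nlat):
            lon, lat = nlon, nlat
            hours += step
            fate = "lost_open_ocean"
            break
        lon, lat = nlon, nlat
        hours += step
        t = release_time + np.timedelta64(int(round(hours * 3600)), "s")
        if record_positions:
            positions.append((lon, lat))
        # beaching: interpolation stencil all land, or inside a land polygon
        try:
            _bilinear(field, lon, lat, min(k, field.time.size - 1))
        except LandError:
            fate = "beached"
            break
        if land_polys and any(p.contains(Point(lon, lat)) for p in land_polys):
            fate = "beached"
            break
        s = check_settle(lon, lat, hours)
        if s is not None:
            fate, settle_site = "settled", s
            break
    if fate is None:
        fate = "expired"
    return Particle(
        source_site=site.name,
        release_time=release_time,
        fate=fate,
        settle_site=settle_site,
        dispersal_km=float(haversine_km(lon0, lat0, lon, lat)),
        final_lon=lon,
        final_lat=lat,
        n_hours=int(round(hours)),
        positions=np.array(positions) if record_positions else None,
    )


def run_simulation(
    field: VelocityField,
    sites: Sequence[SpawningSite],
    years: Iterable[int],
    release_per_day: int = 1,
    step: float = 1.0,
    max_days: int = 30,
    min_age_hours: float = 0.0,
    method: str = "euler",
) -> TrajectorySet:
    """Release particles daily, per release cell, through each site's season.

    For every (site, year, in-season day, release cell) combination,
    ``release_per_day`` particles are advected. Releases whose day falls
    outside the field's time coverage raise a configuration error.
    """
    t0 = field.time[0]
    t1 = field.time[-1]
    particles = []
    for site in sites:
        start, end = site.season
        for year in years:
            for doy in range(start, end + 1):
                day = np.datetime64(f"{year}-01-01") + np.timedelta64(doy - 1, "D")
                day = np.datetime64(day, "ns")
                if day < t0 or day > t1:
                    raise ValueError(
                        f"season day {day} for site {site.name} outside field time coverage"
                    )
                for cell in site.release_cells:
                    for _ in range(release_per_day):
                        particles.append(
                            advect(
                                field,
                                site,
                                day,
                                release_cell=cell,
                                step=step,
                                max_days=max_days,
                                sites_all=sites,
                                min_age_hours=min_age_hours,
                                method=method,
                            )
                        )
    return TrajectorySet(particles=particles, site_names=[s.name for s in sites])


def dispersal_stats(trajs: TrajectorySet, by_site: bool = True) -> dict:
    """Per-site and pooled {mean, sd, q95, max, n} of dispersal distance (km).

    sd is the population standard deviation; q95 is the linear-interpolation
    95th percentile.
    """
    if len(trajs) == 0:
        raise ValueError("empty trajectory set")

    def _stats(d):
        d = np.asarray(d, dtype=float)
        return {
            "mean": float(np.mean(d)),
            "sd": float(np.std(d)),
            "q95": float(np.quantile(d, 0.95)),
            "max": float(np.max(d)),
            "n": int(d.size),
        }

    out = {"pooled": _stats([p.dispersal_km for p in trajs.particles])}
    if by_site:
        out["by_site"] = {}
        for name in trajs.site_names:
            d = [p.dispersal_km for p in trajs.particles if p.source_site == name]
            if d:
                out["by_site"][name] = _stats(d)
    return out


def connectivity_matrix(trajs: TrajectorySet, sites: Sequence[SpawningSite] | None = None) -> ConnectivityMatrix:
    """Pairwise transfer probabilities P[i][j] = settled at j / released at i."""
    names = [s.name for s in sites] if sites is not None else list(trajs.site_names)
    idx = {n: i for i, n in enumerate(names)}
    for p in trajs.particles:
        if p.source_site not in idx:
            raise ValueError(f"particle source {p.source_site} not among sites")
    n = len(names)
    counts = np.zeros((n, n))
    released = np.zeros(n, dtype=int)
    for p in trajs.particles:
        i = idx[p.source_site]
        released[i] += 1
        if p.fate == "settled":
            counts[i, idx[p.settle_site]] += 1
    P = np.full((n, n), np.nan)
    nz = released > 0
    P[nz, :] = counts[nz, :] / released[nz, None]
    return ConnectivityMatrix(sites=names, P=P, n_released=released)


# ---- GeoJSON site I/O ----

def read_sites_geojson(path, field: VelocityField | None = None, cell_km: float = 3.0, settlement_buffer_km: float = 10.0) -> list:
    """Load spawning sites from a GeoJSON FeatureCollection.

    Each feature needs properties ``name``, ``season_start_doy``,
    ``season_end_doy``; release cells are rasterised from the polygon.
    """
    with open(path) as fh:
        gj = json.load(fh)
    sites = []
    for feat in gj["features"]:
        props = feat["properties"]
        poly = shape(feat["geometry"])
        sites.append(
            SpawningSite.from_polygon(
                name=props["name"],
                polygon=poly,
                season=(int(props["season_start_doy"]), int(props["season_end_doy"])),
                field=field,
                cell_km=cell_km,
                settlement_buffer_km=settlement_buffer_km,
            )
        )
    return sites


def write_sites_geojson(sites: Sequence[SpawningSite], path) -> None:
    feats = []
    for s in sites:
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(s.polygon),
                "properties": {
                    "name": s.name,
                    "season_start_doy": s.season[0],
                    "season_end_doy": s.season[1],
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
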
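"""Synthetic ocean domain, environmental layers and seaweed-yield ensembles.

This module generates the gridded inputs the technoeconomic analysis runs
on: an equal-angle latitude/longitude grid with a land mask, smooth
environmental fields (depth, significant wave height, distance to port,
100-yr sequestration fraction, shipping/MPA masks) and per-type seaweed
harvest-yield maps at five uncertainty percentiles under two nutrient
scenarios. The synthetic fields stand in for the biophysical-model yield
maps and real-world rasters of the full-scale analysis; their magnitudes
are anchored to reported peak yields (~6,000 tDW km^-2 yr^-1 for tropical
red seaweeds, ~2,000 for temperate browns). Everything is reproducible
from a seed, and every structure round-trips through CF-style NetCDF so
real rasters can be dropped in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import xarray as xr
from scipy.ndimage import gaussian_filter

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in degrees."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    a = (
        np.sin(0.5 * (lat2 - lat1)) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin(0.5 * (lon2 - lon1)) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class OceanGrid:
    """Equal-angle lat/lon raster geometry with land mask and cell areas.

    Latitude rows are ordered south to north; cell areas follow spherical
    geometry (proportional to the difference of sines of the edge
    latitudes, i.e. ~cos(latitude) for thin rows).
    """

    lat_edges: np.ndarray
    lon_edges: np.ndarray
    land_mask: np.ndarray

    def __post_init__(self) -> None:
        self.lat_edges = np.asarray(self.lat_edges, dtype=float)
        self.lon_edges = np.asarray(self.lon_edges, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.land_mask.shape != (self.n_lat, self.n_lon):
            raise ValueError("land_mask shape does not match grid dimensions")
        if self.land_mask.all():
            raise ValueError("degenerate grid: all cells are land")

    @property
    def n_lat(self) -> int:
        return len(self.lat_edges) - 1

    @property
    def n_lon(self) -> int:
        return len(self.lon_edges) - 1

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    @property
    def cell_area(self) -> np.ndarray:
        """Cell areas in km^2, shape (n_lat, n_lon)."""
        band = np.diff(np.sin(np.radians(self.lat_edges)))  # (n_lat,)
        dlon = np.diff(np.radians(self.lon_edges))  # (n_lon,)
        return EARTH_RADIUS_KM**2 * np.outer(band, dlon)

    @property
    def ocean_mask(self) -> np.ndarray:
        return ~self.land_mask

    @property
    def total_ocean_area_km2(self) -> float:
        return float(self.cell_area[self.ocean_mask].sum())

    @property
    def wraps_lon(self) -> bool:
        """Whether the grid spans the full 360 degrees of longitude."""
        return bool(np.isclose(self.lon_edges[-1] - self.lon_edges[0], 360.0))


@dataclass
class EnvLayers:
    """Environmental layers on an OceanGrid; NaN on land.

    depth (m, positive down), swh (significant wave height, m), d_port
    (over-water distance to nearest port, km; NaN where no port is
    reachable), f_seq (fraction of sunk carbon sequestered >= 100 yr).
    """

    depth: np.ndarray
    swh: np.ndarray
    d_port: np.ndarray
    f_seq: np.ndarray
    port_mask: np.ndarray
    shipping_mask: np.ndarray
    mpa_mask: np.ndarray


@dataclass
class SeaweedType:
    """Latitude affinity, yield scale and farming traits of one type."""

    name: str
    lat_center: float  # degrees of |latitude| where the type peaks
    lat_width: float  # e-folding width of the latitude envelope, degrees
    peak_yield: float  # max median yield, tDW km^-2 yr^-1
    n_harv: float  # harvests per year
    line_spacing_m: float  # spacing between seeded lines, m


#: Four types spanning the tropical/temperate and red/brown axes. Peak
#: yields anchor to reported magnitudes; line spacings reflect practice
#: (dense off-bottom lines for tropical reds, sparse longlines for kelps).
DEFAULT_SEAWEED_TYPES: tuple[SeaweedType, ...] = (
    SeaweedType("tropical_red", 0.0, 15.0, 6000.0, 6.0, 0.25),
    SeaweedType("tropical_brown", 0.0, 20.0, 3000.0, 4.0, 0.5),
    SeaweedType("temperate_red", 35.0, 12.0, 1500.0, 2.0, 0.5),
    SeaweedType("temperate_brown", 45.0, 12.0, 2000.0, 2.0, 1.5),
)

SCENARIOS = ("ambient", "limited")


@dataclass
class YieldEnsemble:
    """Per-type, per-scenario, per-percentile harvest maps.

    ``s_dw`` has shape (type, scenario, percentile, lat, lon) in
    tDW km^-2 yr^-1, NaN on land, non-decreasing along the percentile
    axis, and limited <= ambient cell-wise.
    """

    s_dw: np.ndarray
    type_names: tuple[str, ...]
    scenarios: tuple[str, ...]
    percentiles: tuple[int, ...]
    n_harv: np.ndarray  # (n_types,) harvests per year
    line_spacing_m: np.ndarray  # (n_types,)
    preferred_type: np.ndarray  # (lat, lon) int, -1 on land

    def select(self, scenario: str, percentile: int, type_index: int) -> np.ndarray:
        return self.s_dw[
            type_index,
            self.scenarios.index(scenario),
            self.percentiles.index(percentile),
        ]

    def preferred_map(self, scenario: str, percentile: int) -> np.ndarray:
        """Yield of the per-cell preferred type, NaN on land."""
        si = self.scenarios.index(scenario)
        pi = self.percentiles.index(percentile)
        idx = np.clip(self.preferred_type, 0, None)
        stacked = self.s_dw[:, si, pi]  # (type, lat, lon)
        out = np.take_along_axis(stacked, idx[None], axis=0)[0]
        return np.where(self.preferred_type >= 0, out, np.nan)

    def preferred_n_harv(self) -> np.ndarray:
        idx = np.clip(self.preferred_type, 0, None)
        out = self.n_harv[idx].astype(float)
        return np.where(self.preferred_type >= 0, out, np.nan)

    def preferred_p_sline(self) -> np.ndarray:
        """Seeded-line length per km^2 (m km^-2) of the preferred type."""
        idx = np.clip(self.preferred_type, 0, None)
        out = 1e6 / self.line_spacing_m[idx]
        return np.where(self.preferred_type >= 0, out, np.nan)


def smooth_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    sigma: float,
    wrap_lon: bool = True,
) -> np.ndarray:
    """Smoothed Gaussian noise rescaled to [0, 1]."""
    noise = rng.standard_normal(shape)
    mode = ("nearest", "wrap") if wrap_lon else "nearest"
    f = gaussian_filter(noise, sigma=sigma, mode=mode)
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.full(shape, 0.5)
    return (f - lo) / (hi - lo)


def generate_ocean_grid(
    n_lat: int,
    n_lon: int,
    land_fraction: float,
    seed: int,
    lat_range: tuple[float, float] = (-90.0, 90.0),
    lon_range: tuple[float, float] = (-180.0, 180.0),
) -> OceanGrid:
    """Generate a grid whose land forms contiguous smoothed-noise blobs."""
    if n_lat < 8 or n_lon < 8:
        raise ValueError("grid must be at least 8x8")
    if not 0.0 <= land_fraction < 1.0:
        raise ValueError("land_fraction must be in [0, 1)")
    lat_edges = np.linspace(*lat_range, n_lat + 1)
    lon_edges = np.linspace(*lon_range, n_lon + 1)
    if land_fraction == 0.0:
        land = np.zeros((n_lat, n_lon), dtype=bool)
    else:
        rng = np.random.default_rng(seed)
        wrap = np.isclose(lon_range[1] - lon_range[0], 360.0)
        f = smooth_field(rng, (n_lat, n_lon), sigma=max(1.0, min(n_lat, n_lon) / 10), wrap_lon=wrap)
        land = f >= np.quantile(f, 1.0 - land_fraction)
        if land.all():
            raise ValueError("degenerate grid: all cells are land")
    return OceanGrid(lat_edges, lon_edges, land)


def _neighbor_any(mask: np.ndarray, wrap_lon: bool) -> np.ndarray:
    """True where any 8-neighbour of a cell is True (lat edges clamped)."""
    out = np.zeros_like(mask)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            shifted = np.roll(mask, (di, dj), axis=(0, 1))
            # rolling in latitude wraps pole to pole; blank those rows
            if di == 1:
                shifted[0, :] = False
            elif di == -1:
                shifted[-1, :] = False
            if not wrap_lon:
                if dj == 1:
                    shifted[:, 0] = False
                elif dj == -1:
                    shifted[:, -1] = False
            out |= shifted
    return out


def coastal_cells(grid: OceanGrid) -> np.ndarray:
    """Ocean cells with at least one land cell among their 8 neighbours."""
    return grid.ocean_mask & _neighbor_any(grid.land_mask, grid.wraps_lon)


def generate_env_layers(
    grid: OceanGrid,
    n_ports: int = 8,
    seed: int = 0,
    port_mask: np.ndarray | None = None,
    shipping_fraction: float = 0.05,
    mpa_fraction: float = 0.03,
) -> EnvLayers:
    """Generate smooth environmental fields and a port-seeded distance map.

    Ports are placed on randomly chosen coastal cells unless an explicit
    ``port_mask`` is given; ``d_port`` is the over-water shortest-path
    distance from each ocean cell to its nearest port.
    """
    from .sinkroute import weighted_distance_transform

    rng = np.random.default_rng(seed)
    shape = (grid.n_lat, grid.n_lon)
    sigma = max(1.0, min(shape) / 8)
    ocean = grid.ocean_mask

    depth = 50.0 + 5950.0 * smooth_field(rng, shape, sigma, grid.wraps_lon)
    swh = 6.0 * smooth_field(rng, shape, sigma, grid.wraps_lon)
    f_seq = 0.05 + 0.9 * smooth_field(rng, shape, sigma, grid.wraps_lon)

    if port_mask is None:
        coast = coastal_cells(grid)
        idx = np.flatnonzero(coast)
        if idx.size == 0:
            raise ValueError(
                "no coastal cell available for a port; pass port_mask explicitly"
            )
        chosen = rng.choice(idx, size=min(n_ports, idx.size), replace=False)
        port_mask = np.zeros(shape, dtype=bool)
        port_mask.flat[chosen] = True
    else:
        port_mask = np.asarray(port_mask, dtype=bool)
        if not port_mask.any():
            raise ValueError("port_mask contains no port cell")
        if (port_mask & grid.land_mask).any():
            raise ValueError("ports must sit on ocean cells")

    d_port = weighted_distance_transform(grid, port_mask).distance
    d_port = np.where(np.isfinite(d_port), d_port, np.nan)

    ship_f = smooth_field(rng, shape, sigma / 2, grid.wraps_lon)
    mpa_f = smooth_field(rng, shape, sigma / 2, grid.wraps_lon)
    shipping_mask = ocean & (ship_f >= np.quantile(ship_f[ocean], 1 - shipping_fraction))
    mpa_mask = ocean & (mpa_f >= np.quantile(mpa_f[ocean], 1 - mpa_fraction))

    nanland = lambda a: np.where(ocean, a, np.nan)
    return EnvLayers(
        depth=nanland(depth),
        swh=nanland(swh),
        d_port=nanland(d_port),
        f_seq=nanland(f_seq),
        port_mask=port_mask,
        shipping_mask=shipping_mask,
        mpa_mask=mpa_mask,
    )


def generate_yield_ensemble(
    grid: OceanGrid,
    env: EnvLayers,
    seed: int = 0,
    types: Sequence[SeaweedType] = DEFAULT_SEAWEED_TYPES,
    percentiles: Sequence[int] = (5, 25, 50, 75, 95),
    percentile_multipliers: Sequence[float] = (0.5, 0.8, 1.0, 1.2, 1.5),
    min_yield: float = 1.0,
) -> YieldEnsemble:
    """Generate per-type yield maps with ordered uncertainty percentiles.

    The median map of each type is a latitude envelope (Gaussian in
    |latitude| around the type's affinity band) times a smooth random
    texture, normalized so the best ocean cell reaches the type's peak
    yield. Percentile maps scale the median by ordered multipliers with a
    smooth +/-10% perturbation (sorted cell-wise so monotonicity holds
    exactly), and the limited-nutrient scenario multiplies ambient yields
    by one shared smooth factor in (0, 1].
    """
    rng = np.random.default_rng(seed)
    shape = (grid.n_lat, grid.n_lon)
    sigma = max(1.0, min(shape) / 8)
    ocean = grid.ocean_mask
    abslat = np.abs(grid.lat_centers)[:, None] * np.ones((1, grid.n_lon))

    mults = np.asarray(percentile_multipliers, dtype=float)
    if np.any(np.diff(mults) < 0):
        raise ValueError("percentile multipliers must be non-decreasing")

    limited_factor = 0.4 + 0.6 * smooth_field(rng, shape, sigma, grid.wraps_lon)

    n_types = len(types)
    s_dw = np.full((n_types, 2, len(mults), *shape), np.nan)
    for ti, t in enumerate(types):
        envelope = np.exp(-(((abslat - t.lat_center) / t.lat_width) ** 2))
        texture = 0.15 + 0.85 * smooth_field(rng, shape, sigma, grid.wraps_lon)
        base = envelope * texture
        peak = base[ocean].max()
        median = t.peak_yield * base / peak
        median[median < min_yield] = 0.0

        perturb = 0.1 * (2.0 * smooth_field(rng, shape, sigma, grid.wraps_lon) - 1.0)
        pct_mults = mults[:, None, None] * (1.0 + perturb[None])
        pct_mults = np.sort(pct_mults, axis=0)  # enforce percentile ordering
        ambient = median[None] * pct_mults
        s_dw[ti, 0] = np.where(ocean, ambient, np.nan)
        s_dw[ti, 1] = np.where(ocean, ambient * limited_factor[None], np.nan)

    median_idx = int(np.argmin(np.abs(mults - 1.0)))
    medians = s_dw[:, 0, median_idx]  # (type, lat, lon)
    preferred = np.argmax(np.nan_to_num(medians, nan=-1.0), axis=0)
    preferred = np.where(ocean, preferred, -1)

    return YieldEnsemble(
        s_dw=s_dw,
        type_names=tuple(t.name for t in types),
        scenarios=SCENARIOS,
        percentiles=tuple(int(p) for p in percentiles),
        n_harv=np.array([t.n_harv for t in types]),
        line_spacing_m=np.array([t.line_spacing_m for t in types]),
        preferred_type=preferred,
    )


# --------------------------------------------------------------------------
# NetCDF round-trip (CF-style dims lat/lon; land as a mask variable)
# --------------------------------------------------------------------------

def to_dataset(
    grid: OceanGrid,
    env: EnvLayers | None = None,
    yields: YieldEnsemble | None = None,
    attrs: dict | None = None,
) -> xr.Dataset:
    """Bundle grid (and optionally layers/yields) into an xarray Dataset."""
    coords = {
        "lat": ("lat", grid.lat_centers, {"units": "degrees_north"}),
        "lon": ("lon", grid.lon_centers, {"units": "degrees_east"}),
    }
    data = {
        "land_mask": (("lat", "lon"), grid.land_mask.astype(np.int8), {"flag_meanings": "ocean land"}),
        "cell_area": (("lat", "lon"), grid.cell_area, {"units": "km2"}),
    }
    ds_attrs = {
        "lat_edges": json.dumps(grid.lat_edges.tolist()),
        "lon_edges": json.dumps(grid.lon_edges.tolist()),
    }
    if attrs:
        ds_attrs.update(attrs)
    if env is not None:
        data.update(
            depth=(("lat", "lon"), env.depth, {"units": "m", "positive": "down"}),
            swh=(("lat", "lon"), env.swh, {"units": "m"}),
            d_port=(("lat", "lon"), env.d_port, {"units": "km"}),
            f_seq=(("lat", "lon"), env.f_seq, {"units": "1"}),
            port_mask=(("lat", "lon"), env.port_mask.astype(np.int8), {}),
            shipping_mask=(("lat", "lon"), env.shipping_mask.astype(np.int8), {}),
            mpa_mask=(("lat", "lon"), env.mpa_mask.astype(np.int8), {}),
        )
    if yields is not None:
        coords.update(
            seaweed_type=("seaweed_type", list(yields.type_names)),
            scenario=("scenario", list(yields.scenarios)),
            percentile=("percentile", list(yields.percentiles)),
        )
        data.update(
            s_dw=(
                ("seaweed_type", "scenario", "percentile", "lat", "lon"),
                yields.s_dw,
                {"units": "tDW km-2 yr-1"},
            ),
            n_harv=(("seaweed_type",), yields.n_harv, {"units": "yr-1"}),
            line_spacing=(("seaweed_type",), yields.line_spacing_m, {"units": "m"}),
            preferred_type=(("lat", "lon"), yields.preferred_type.astype(np.int16), {}),
        )
    return xr.Dataset(data, coords=coords, attrs=ds_attrs)


def grid_from_dataset(ds: xr.Dataset) -> OceanGrid:
    return OceanGrid(
        lat_edges=np.asarray(json.loads(ds.attrs["lat_edges"])),
        lon_edges=np.asarray(json.loads(ds.attrs["lon_edges"])),
        land_mask=ds["land_mask"].values.astype(bool),
    )


def env_from_dataset(ds: xr.Dataset) -> EnvLayers:
    return EnvLayers(
        depth=ds["depth"].values,
        swh=ds["swh"].values,
        d_port=ds["d_port"].values,
        f_seq=ds["f_seq"].values,
        port_mask=ds["port_mask"].values.astype(bool),
        shipping_mask=ds["shipping_mask"].values.astype(bool),
        mpa_mask=ds["mpa_mask"].values.astype(bool),
    )


def yields_from_dataset(ds: xr.Dataset) -> YieldEnsemble:
    return YieldEnsemble(
        s_dw=ds["s_dw"].values,
        type_names=tuple(str(t) for t in ds["seaweed_type"].values),
        scenarios=tuple(str(s) for s in ds["scenario"].values),
        percentiles=tuple(int(p) for p in ds["percentile"].values),
        n_harv=ds["n_harv"].values,
        line_spacing_m=ds["line_spacing"].values,
        preferred_type=ds["preferred_type"].values.astype(int),
    )


def save_dataset(ds: xr.Dataset, path) -> None:
    """Write as classic NetCDF (engine='scipy'), text-tool friendly."""
    ds.to_netcdf(path, engine="scipy")


def load_dataset(path) -> xr.Dataset:
    return xr.load_dataset(path, engine="scipy")
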
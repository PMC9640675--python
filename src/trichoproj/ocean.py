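"""Era-labelled gridded ocean states and their seeded synthetic generator.

The generator emulates, statistically, the fields an Earth-system
biogeochemistry run would provide for an offline N2-fixation calculation:
surface pH on the total scale, phosphate and dissolved organic phosphorus,
total N2 fixation (NF, areal), the *Trichodesmium* contribution fraction
R_Tr, and auxiliary (non-P) nutrient limitation factors.  It makes no
attempt at dynamics: each field is a smooth latitude envelope times
seeded noise, rescaled to configured global targets, so that downstream
stages see realistically structured inputs with known integrals.

Draw order from the single seeded generator (fixed; part of the
reproducibility contract): pH, PO4, DOP, NF noise, R_Tr noise, then one
uniform field per auxiliary limitation factor in sorted name order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from trichoproj.errors import ConfigurationError, FormatError, ShapeError
from trichoproj.grid import GridGeometry, cell_areas_from_edges, generate_grid

ERA_HISTORICAL = "1981-2000"
ERA_FUTURE = "2081-2100"
ERAS = (ERA_HISTORICAL, ERA_FUTURE)

_GRAMS_PER_TG = 1e12


@dataclass
class GriddedField:
    """One named 2-D field on a grid, with units and an era label."""

    name: str
    units: str
    values: np.ndarray
    era: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class OceanState:
    """Bundle of the gridded fields one era of the projection consumes.

    Invariants (checked by :meth:`validate`): r_tr in [0, 1]; ph_t in
    (7, 9); po4, dop, nf non-negative; auxiliary limitation factors in
    [0, 1]; every field defined (finite) exactly on ocean cells.
    """

    era: str
    geometry: GridGeometry
    ph_t: GriddedField
    po4: GriddedField
    dop: GriddedField
    nf: GriddedField
    r_tr: GriddedField
    aux_limits: dict[str, GriddedField] = field(default_factory=dict)

    def fields(self) -> dict[str, GriddedField]:
        out = {
            "ph_t": self.ph_t,
            "po4": self.po4,
            "dop": self.dop,
            "nf": self.nf,
            "r_tr": self.r_tr,
        }
        for name, f in self.aux_limits.items():
            out[f"aux_limit_{name}"] = f
        return out

    def validate(self) -> None:
        mask = self.geometry.ocean_mask
        for key, f in self.fields().items():
            if f.values.shape != self.geometry.shape:
                raise ShapeError(f"{key} shape {f.values.shape} != grid {self.geometry.shape}")
            if not np.all(np.isfinite(f.values[mask])):
                raise ConfigurationError(f"{key} has non-finite values on ocean cells")
        ocean = mask
        ph = self.ph_t.values[ocean]
        if np.any((ph <= 7.0) | (ph >= 9.0)):
            raise ConfigurationError("ph_t outside (7, 9) on ocean cells")
        for key in ("po4", "dop", "nf"):
            if np.any(getattr(self, key).values[ocean] < 0):
                raise ConfigurationError(f"{key} negative on ocean cells")
        rt = self.r_tr.values[ocean]
        if np.any((rt < 0) | (rt > 1)):
            raise ConfigurationError("r_tr outside [0, 1] on ocean cells")
        for name, f in self.aux_limits.items():
            v = f.values[ocean]
            if np.any((v < 0) | (v > 1)):
                raise ConfigurationError(f"aux limit {name!r} outside [0, 1]")


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic-ocean generator.

    Global targets follow the published Earth-system numbers for the two
    eras: total marine N2 fixation of 155 Tg N yr-1 in 1981-2000 falling
    to 130 Tg N yr-1 by 2081-2100, with the *Trichodesmium* share set so
    the reference Trichodesmium integrals are 60 and 47.4 Tg N yr-1.
    Era-mean surface pH defaults (8.05 / 7.80) bracket the laboratory
    calibration interval [8.01, 7.81].
    """

    lat_resolution: float = 2.0
    lon_resolution: float = 2.5
    seed: int = 0
    nf_target_tg: dict[str, float] = field(
        default_factory=lambda: {ERA_HISTORICAL: 155.0, ERA_FUTURE: 130.0}
    )
    r_tr_target: dict[str, float] = field(
        default_factory=lambda: {ERA_HISTORICAL: 60.0 / 155.0, ERA_FUTURE: 47.4 / 130.0}
    )
    ph_mean: dict[str, float] = field(
        default_factory=lambda: {ERA_HISTORICAL: 8.05, ERA_FUTURE: 7.80}
    )
    ph_spread: float = 0.03
    # PO4 log-normal: median rises from oligotrophic-gyre values at low
    # latitude toward high-latitude maxima (mmol m-3).
    po4_median_gyre: float = 0.03
    po4_polar_boost: float = 1.2
    po4_lat_scale: float = 45.0
    po4_sigma: float = 0.6
    dop_po4_ratio: float = 2.0
    dop_sigma: float = 0.3
    # NF: tropical-peaked envelope times log-normal noise.
    nf_lat_scale: float = 25.0
    nf_sigma: float = 0.5
    # R_Tr: smooth latitude fraction plus noise.
    r_tr_lat_scale: float = 30.0
    r_tr_floor: float = 0.15
    r_tr_noise: float = 0.03
    aux_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"fe": (0.2, 0.9), "n": (0.3, 1.0)}
    )

    def __post_init__(self) -> None:
        for era, t in self.nf_target_tg.items():
            if t <= 0:
                raise ConfigurationError(f"NF target for {era} must be positive")
        for era, t in self.r_tr_target.items():
            if not 0 < t < 1:
                raise ConfigurationError(f"R_Tr target for {era} must lie in (0, 1)")

    def make_grid(self, ocean_mask: np.ndarray | None = None) -> GridGeometry:
        return generate_grid(self.lat_resolution, self.lon_resolution, ocean_mask)


def _lat_field(geometry: GridGeometry) -> np.ndarray:
    """Latitude of each cell centre, broadcast to the grid shape."""
    return np.broadcast_to(
        geometry.lat_centers[:, None], geometry.shape
    ).copy()


def generate_ocean_state(
    config: SyntheticConfig,
    era: str,
    geometry: GridGeometry | None = None,
) -> OceanState:
    """Draw one era's ocean state from the seeded generator.

    The same (config, era) pair always yields bit-identical output; the
    two eras use independent streams spawned from the one configured seed.
    """
    if era not in ERAS:
        raise ConfigurationError(f"unknown era {era!r}; expected one of {ERAS}")
    geom = config.make_grid() if geometry is None else geometry
    rng = np.random.default_rng([config.seed, ERAS.index(era)])
    mask = geom.ocean_mask
    lat = _lat_field(geom)
    shape = geom.shape

    # 1. pH on the total scale.
    ph = rng.normal(config.ph_mean[era], config.ph_spread, size=shape)
    ph = np.clip(ph, 7.0 + 1e-6, 9.0 - 1e-6)

    # 2-3. Phosphorus pools (mmol m-3), log-normal around a latitude-
    # dependent median: low in the subtropical gyres, high poleward.
    po4_median = config.po4_median_gyre + config.po4_polar_boost * (
        1.0 - np.exp(-((lat / config.po4_lat_scale) ** 2))
    )
    po4 = po4_median * np.exp(rng.normal(0.0, config.po4_sigma, size=shape))
    dop = config.dop_po4_ratio * po4 * np.exp(
        rng.normal(0.0, config.dop_sigma, size=shape)
    )

    # 4. N2 fixation: tropical envelope x log-normal noise, rescaled so the
    # ocean integral hits the configured global target exactly.
    envelope = np.exp(-((lat / config.nf_lat_scale) ** 2))
    nf = envelope * np.exp(rng.normal(0.0, config.nf_sigma, size=shape))
    integral_tg = float(np.sum(nf[mask] * geom.cell_area[mask]) / _GRAMS_PER_TG)
    nf *= config.nf_target_tg[era] / integral_tg

    # 5. R_Tr: smooth fraction peaked in the tropics plus noise, scaled to
    # the target area-weighted mean.  The floor keeps a nonzero high-
    # latitude share so scaling cannot push values past 1.
    base = config.r_tr_floor + np.exp(-((lat / config.r_tr_lat_scale) ** 2))
    base = base * (config.r_tr_target[era] / geom.area_weighted_mean(base))
    r_tr = np.clip(base + rng.normal(0.0, config.r_tr_noise, size=shape), 0.0, 1.0)
    mean = geom.area_weighted_mean(r_tr)
    r_tr = np.clip(r_tr * (config.r_tr_target[era] / mean), 0.0, 1.0)

    # 6+. Auxiliary limitation factors, uniform in configured ranges.
    aux: dict[str, GriddedField] = {}
    for name in sorted(config.aux_ranges):
        lo, hi = config.aux_ranges[name]
        vals = rng.uniform(lo, hi, size=shape)
        aux[name] = GriddedField(f"aux_limit_{name}", "1", _mask_land(vals, mask), era)

    state = OceanState(
        era=era,
        geometry=geom,
        ph_t=GriddedField("ph_t", "pH (total scale)", _mask_land(ph, mask), era),
        po4=GriddedField("po4", "mmol m-3", _mask_land(po4, mask), era),
        dop=GriddedField("dop", "mmol m-3", _mask_land(dop, mask), era),
        nf=GriddedField("nf", "g N m-2 yr-1", _mask_land(nf, mask), era),
        r_tr=GriddedField("r_tr", "1", _mask_land(r_tr, mask), era),
        aux_limits=aux,
    )
    state.validate()
    return state


def _mask_land(values: np.ndarray, ocean_mask: np.ndarray) -> np.ndarray:
    out = np.asarray(values, dtype=float).copy()
    out[~ocean_mask] = np.nan
    return out


# ---------------------------------------------------------------------------
# I/O: NetCDF-convention files (xarray, scipy backend) with a CSV fallback.

_REQUIRED_VARS = ("ph_t", "po4", "dop", "nf", "r_tr")


def state_to_dataset(state: OceanState) -> xr.Dataset:
    geom = state.geometry
    data = {}
    for key, f in state.fields().items():
        data[key] = xr.DataArray(
            f.values, dims=("lat", "lon"), attrs={"units": f.units}
        )
    data["ocean_mask"] = xr.DataArray(
        geom.ocean_mask.astype(np.int32), dims=("lat", "lon")
    )
    ds = xr.Dataset(
        data,
        coords={
            "lat": geom.lat_centers,
            "lon": geom.lon_centers,
            "lat_edges": ("lat_edge", geom.lat_edges),
            "lon_edges": ("lon_edge", geom.lon_edges),
        },
        attrs={"era": state.era},
    )
    return ds


def dataset_to_state(ds: xr.Dataset) -> OceanState:
    for var in _REQUIRED_VARS + ("ocean_mask",):
        if var not in ds:
            raise FormatError(f"state file missing required variable {var!r}")
    if "era" not in ds.attrs:
        raise FormatError("state file missing required attribute 'era'")
    if "lat_edges" not in ds.coords or "lon_edges" not in ds.coords:
        raise FormatError("state file missing required coordinate 'lat_edges'/'lon_edges'")
    era = str(ds.attrs["era"])
    lat_edges = np.asarray(ds["lat_edges"].values, dtype=float)
    lon_edges = np.asarray(ds["lon_edges"].values, dtype=float)
    mask = np.asarray(ds["ocean_mask"].values).astype(bool)
    geom = GridGeometry(
        lat_edges, lon_edges, cell_areas_from_edges(lat_edges, lon_edges), mask
    )

    def grab(name: str) -> GriddedField:
        da = ds[name]
        return GriddedField(name, str(da.attrs.get("units", "")), da.values, era)

    aux = {
        v[len("aux_limit_"):]: grab(v)
        for v in ds.data_vars
        if str(v).startswith("aux_limit_")
    }
    return OceanState(
        era=era,
        geometry=geom,
        ph_t=grab("ph_t"),
        po4=grab("po4"),
        dop=grab("dop"),
        nf=grab("nf"),
        r_tr=grab("r_tr"),
        aux_limits=aux,
    )


def write_state(state: OceanState, path) -> None:
    """Write a state to NetCDF (``.nc``) or one-row-per-cell CSV (``.csv``)."""
    path = str(path)
    if path.endswith(".csv"):
        _write_state_csv(state, path)
    else:
        state_to_dataset(state).to_netcdf(path, engine="scipy")


def read_state(path) -> OceanState:
    path = str(path)
    if path.endswith(".csv"):
        return _read_state_csv(path)
    with xr.open_dataset(path, engine="scipy") as ds:
        return dataset_to_state(ds.load())


def _write_state_csv(state: OceanState, path: str) -> None:
    geom = state.geometry
    n_lat, n_lon = geom.shape
    ii, jj = np.meshgrid(np.arange(n_lat), np.arange(n_lon), indexing="ij")
    cols: dict[str, np.ndarray] = {
        "lat_index": ii.ravel(),
        "lon_index": jj.ravel(),
        "lat": np.broadcast_to(geom.lat_centers[:, None], geom.shape).ravel(),
        "lon": np.broadcast_to(geom.lon_centers[None, :], geom.shape).ravel(),
        "ocean_mask": geom.ocean_mask.astype(int).ravel(),
    }
    units: dict[str, str] = {}
    for key, f in state.fields().items():
        cols[key] = f.values.ravel()
        units[key] = f.units
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# era={state.era}\n")
        fh.write(f"# lat_edges={','.join(repr(float(v)) for v in geom.lat_edges)}\n")
        fh.write(f"# lon_edges={','.join(repr(float(v)) for v in geom.lon_edges)}\n")
        for key, u in units.items():
            fh.write(f"# units:{key}={u}\n")
        df.to_csv(fh, index=False)


def _read_state_csv(path: str) -> OceanState:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    for needed in ("era", "lat_edges", "lon_edges"):
        if needed not in meta:
            raise FormatError(f"state CSV missing required header {needed!r}")
    for var in _REQUIRED_VARS + ("ocean_mask",):
        if var not in df.columns:
            raise FormatError(f"state CSV missing required variable {var!r}")
    lat_edges = np.array([float(v) for v in meta["lat_edges"].split(",")])
    lon_edges = np.array([float(v) for v in meta["lon_edges"].split(",")])
    shape = (len(lat_edges) - 1, len(lon_edges) - 1)
    mask = df["ocean_mask"].to_numpy().reshape(shape).astype(bool)
    geom = GridGeometry(
        lat_edges, lon_edges, cell_areas_from_edges(lat_edges, lon_edges), mask
    )
    era = meta["era"]

    def grab(name: str) -> GriddedField:
        return GriddedField(
            name,
            meta.get(f"units:{name}", ""),
            df[name].to_numpy().reshape(shape),
            era,
        )

    aux = {
        c[len("aux_limit_"):]: grab(c)
        for c in df.columns
        if c.startswith("aux_limit_")
    }
    return OceanState(
        era=era,
        geometry=geom,
        ph_t=grab("ph_t"),
        po4=grab("po4"),
        dop=grab("dop"),
        nf=grab("nf"),
        r_tr=grab("r_tr"),
        aux_limits=aux,
    )
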
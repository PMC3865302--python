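"""Gridded cell records: container, masking, log transforms, areas, IO.

The analysis operates on a table of grid-cell records, one row per cell:
centroid coordinates, mean annual burned area (km^2/yr), population density
(persons/km^2), a combustibility flag (cells intersecting water, ice or
artificial surfaces are non-combustible and excluded), a major anthrome
type, a continent label, and the latitude-corrected cell area.

Both burned area and population density are strongly right-skewed, so the
regression works on decimal (base-10) logarithms of both.  Cells with a
zero in either variable are, by default, dropped before the transform; a
floor policy (replace zeros with a small epsilon) is available instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0  # authalic sphere radius

ANTHROME_MAJOR_TYPES = (
    "DenseSettlement",
    "Villages",
    "Croplands",
    "Rangelands",
    "Forest",
    "Wildlands",
)
#: integer codes 1..6 used by the gridded writers
ANTHROME_CODES = {name: i + 1 for i, name in enumerate(ANTHROME_MAJOR_TYPES)}

CONTINENTS = ("Africa", "Asia", "NAmerica", "SAmerica", "Europe", "Australia")
CONTINENT_CODES = {name: i + 1 for i, name in enumerate(CONTINENTS)}

#: columns every raw cell table must carry
CELL_COLUMNS = (
    "lon",
    "lat",
    "burned_area",
    "pop_density",
    "combustible",
    "anthrome",
    "continent",
    "cell_area",
)


class MissingLayerError(ValueError):
    """A required layer/column is absent from an input file."""


class EmptyDatasetError(ValueError):
    """Masking and zero-handling removed every cell."""


class GridAlignmentError(ValueError):
    """Cell centroids do not sit on a regular grid compatible with the request."""


def cell_area(lat, resolution: float):
    """Latitude-corrected spherical area (km^2) of a square grid cell.

    A cell of angular width ``resolution`` centred at latitude ``lat`` has
    side lengths R*d (meridional) and R*d*cos(lat) (zonal) with d the
    resolution in radians, giving area (R*d)^2 * cos(lat).
    """
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) >= 90.0):
        raise ValueError("latitude must satisfy |lat| < 90")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    d = np.radians(resolution)
    area = (EARTH_RADIUS_KM * d) ** 2 * np.cos(np.radians(lat))
    return float(area) if area.ndim == 0 else area


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (np.asarray(lon1, dtype=float),
                                              np.asarray(lat1, dtype=float),
                                              np.asarray(lon2, dtype=float),
                                              np.asarray(lat2, dtype=float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def pairwise_distances_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Full symmetric matrix of great-circle distances between cell centroids."""
    lonr = np.radians(np.asarray(lon, dtype=float))
    latr = np.radians(np.asarray(lat, dtype=float))
    sin_dlat = np.sin((latr[:, None] - latr[None, :]) / 2.0)
    sin_dlon = np.sin((lonr[:, None] - lonr[None, :]) / 2.0)
    h = sin_dlat**2 + np.cos(latr)[:, None] * np.cos(latr)[None, :] * sin_dlon**2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def log10_transform(values, zero_policy: str = "drop", eps: float = 0.01) -> np.ndarray:
    """Decimal log of nonnegative values with an explicit zero policy.

    ``floor``: zeros become log10(eps).  ``drop``: zeros become NaN, flagging
    the entry for removal by the caller.  Negative input raises.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("log10_transform requires nonnegative values")
    if zero_policy not in ("drop", "floor"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if zero_policy == "floor" and eps <= 0:
        raise ValueError("floor policy requires eps > 0")
    out = np.full(v.shape, np.nan)
    pos = v > 0
    out[pos] = np.log10(v[pos])
    if zero_policy == "floor":
        out[~pos] = np.log10(eps)
    return out


@dataclass
class GridDataset:
    """The masked, transformed cell table a regression consumes.

    ``cells`` holds only retained cells (combustible, finite x and y) in a
    stable (lat, lon) order, with columns ``x`` (log10 population density)
    and ``y`` (log10 burned area) appended.  ``raw`` keeps the full
    pre-masking table so resolution aggregation can see non-combustible
    children.
    """

    resolution: float
    cells: pd.DataFrame
    zero_policy: str = "drop"
    eps: float = 0.01
    n_removed_mask: int = 0
    n_removed_zero: int = 0
    raw: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.cells)

    @property
    def x(self) -> np.ndarray:
        return self.cells["x"].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.cells["y"].to_numpy()

    @property
    def lon(self) -> np.ndarray:
        return self.cells["lon"].to_numpy()

    @property
    def lat(self) -> np.ndarray:
        return self.cells["lat"].to_numpy()

    def subset(self, mask) -> "GridDataset":
        """New dataset restricted to retained cells where ``mask`` is true."""
        sub = self.cells.loc[np.asarray(mask)].reset_index(drop=True)
        if len(sub) == 0:
            raise EmptyDatasetError("subset retains no cells")
        return GridDataset(self.resolution, sub, self.zero_policy, self.eps,
                           self.n_removed_mask, self.n_removed_zero, raw=None)

    def for_continent(self, continent: str) -> "GridDataset":
        return self.subset(self.cells["continent"].to_numpy() == continent)


def _validate_raw(raw: pd.DataFrame) -> pd.DataFrame:
    for col in CELL_COLUMNS:
        if col not in raw.columns:
            raise MissingLayerError(f"missing layer/column: {col!r}")
    lon = raw["lon"].to_numpy(dtype=float)
    lat = raw["lat"].to_numpy(dtype=float)
    if np.any((lon < -180) | (lon >= 180)):
        raise ValueError("lon out of [-180, 180)")
    if np.any(np.abs(lat) >= 90):
        raise ValueError("|lat| must be < 90")
    if np.any(raw["burned_area"].to_numpy(dtype=float) < 0):
        raise ValueError("burned_area must be >= 0")
    if np.any(raw["pop_density"].to_numpy(dtype=float) < 0):
        raise ValueError("pop_density must be >= 0")
    if np.any(raw["cell_area"].to_numpy(dtype=float) <= 0):
        raise ValueError("cell_area must be > 0")
    if np.any(raw["burned_area"].to_numpy(dtype=float)
              > raw["cell_area"].to_numpy(dtype=float) * (1 + 1e-9)):
        raise ValueError("burned_area exceeds cell_area")
    return raw


def build_dataset(raw_cells: pd.DataFrame, resolution: float,
                  zero_policy: str = "drop", eps: float = 0.01) -> GridDataset:
    """Mask non-combustible cells, apply the decimal-log transform, sort.

    Deterministic for a given input; raises :class:`EmptyDatasetError` if no
    cell survives.
    """
    raw = _validate_raw(raw_cells).copy()
    raw = raw.sort_values(["lat", "lon"], kind="mergesort").reset_index(drop=True)
    comb = raw["combustible"].to_numpy(dtype=bool)
    n_removed_mask = int((~comb).sum())
    kept = raw.loc[comb].reset_index(drop=True)

    y = log10_transform(kept["burned_area"].to_numpy(dtype=float), zero_policy, eps)
    x = log10_transform(kept["pop_density"].to_numpy(dtype=float), zero_policy, eps)
    finite = np.isfinite(x) & np.isfinite(y)
    n_removed_zero = int((~finite).sum())
    kept = kept.loc[finite].reset_index(drop=True)
    kept["x"] = x[finite]
    kept["y"] = y[finite]
    if len(kept) == 0:
        raise EmptyDatasetError("no cells remain after masking and zero handling")
    return GridDataset(resolution=resolution, cells=kept, zero_policy=zero_policy,
                       eps=eps, n_removed_mask=n_removed_mask,
                       n_removed_zero=n_removed_zero, raw=raw)


def _grid_indices(vals: np.ndarray, res: float) -> tuple[np.ndarray, float]:
    """Map centroid coordinates to integer cell indices on a regular grid."""
    origin = vals.min() - res / 2.0  # west/south edge of the covered block
    idx_f = (vals - origin) / res - 0.5
    idx = np.rint(idx_f).astype(int)
    if np.max(np.abs(idx_f - idx)) > 1e-6:
        raise GridAlignmentError("cell centroids are not aligned to a regular grid")
    return idx, origin


def aggregate_resolution(dataset: GridDataset, factor: int) -> GridDataset:
    """Coarsen the grid by an integer factor.

    Burned area sums over children; population density is the cell-area
    weighted mean; anthrome and continent are assigned by majority area; a
    parent is combustible if any child is.  Transforms are re-applied on the
    aggregated table under the dataset's own zero policy.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return dataset
    raw = dataset.raw if dataset.raw is not None else dataset.cells[list(CELL_COLUMNS)]
    res = dataset.resolution
    lon = raw["lon"].to_numpy(dtype=float)
    lat = raw["lat"].to_numpy(dtype=float)
    ix, west = _grid_indices(lon, res)
    iy, south = _grid_indices(lat, res)
    px, py = ix // factor, iy // factor

    df = raw.copy()
    df["_px"], df["_py"] = px, py
    new_res = res * factor

    def majority_by_area(sub: pd.DataFrame, col: str):
        labelled = sub.dropna(subset=[col])
        if len(labelled) == 0:
            return np.nan
        return labelled.groupby(col)["cell_area"].sum().idxmax()

    rows = []
    for (gx, gy), sub in df.groupby(["_px", "_py"], sort=True):
        a = sub["cell_area"].to_numpy(dtype=float)
        rows.append({
            "lon": west + (gx + 0.5) * new_res,
            "lat": south + (gy + 0.5) * new_res,
            "burned_area": float(sub["burned_area"].sum()),
            "pop_density": float(np.average(sub["pop_density"].to_numpy(dtype=float), weights=a)),
            "combustible": bool(sub["combustible"].any()),
            "anthrome": majority_by_area(sub, "anthrome"),
            "continent": majority_by_area(sub, "continent"),
            "cell_area": float(a.sum()),
        })
    agg = pd.DataFrame(rows)
    return build_dataset(agg, resolution=new_res,
                         zero_policy=dataset.zero_policy, eps=dataset.eps)


# ---------------------------------------------------------------------------
# IO: flat CSV table and NetCDF with named variables


def write_grid(dataset: GridDataset, path, format: str | None = None) -> None:
    """Write the raw cell table; CSV or NetCDF chosen by ``format`` or suffix."""
    path = Path(path)
    fmt = format or _infer_format(path)
    raw = dataset.raw if dataset.raw is not None else dataset.cells[list(CELL_COLUMNS)]
    raw = raw.sort_values(["lat", "lon"], kind="mergesort").reset_index(drop=True)
    if fmt == "csv":
        raw[list(CELL_COLUMNS)].to_csv(path, index=False)
    elif fmt == "netcdf":
        _write_netcdf(raw, path, dataset.resolution)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def read_grid(path, resolution: float | None = None, format: str | None = None,
              zero_policy: str = "drop", eps: float = 0.01) -> GridDataset:
    """Read a cell table and build the analysis dataset."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        raw = pd.read_csv(path)
        for col in CELL_COLUMNS:
            if col not in raw.columns:
                raise MissingLayerError(f"missing layer/column: {col!r}")
        if resolution is None:
            resolution = _infer_resolution(raw["lon"].to_numpy(dtype=float))
    elif fmt == "netcdf":
        raw, resolution = _read_netcdf(path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return build_dataset(raw, resolution=resolution, zero_policy=zero_policy, eps=eps)


def _infer_format(path: Path) -> str:
    if path.suffix.lower() == ".csv":
        return "csv"
    if path.suffix.lower() in (".nc", ".nc4", ".cdf"):
        return "netcdf"
    raise ValueError(f"cannot infer format from suffix {path.suffix!r}")


def _infer_resolution(lon: np.ndarray) -> float:
    uniq = np.unique(lon)
    if len(uniq) < 2:
        raise GridAlignmentError("cannot infer resolution from a single column of cells")
    return float(np.min(np.diff(uniq)))


def _write_netcdf(raw: pd.DataFrame, path: Path, resolution: float) -> None:
    import xarray as xr

    lon_vals = np.sort(raw["lon"].unique())
    lat_vals = np.sort(raw["lat"].unique())
    lon_idx = pd.Index(lon_vals)
    lat_idx = pd.Index(lat_vals)
    shape = (len(lat_vals), len(lon_vals))

    def grid_of(col, fill, dtype=float):
        g = np.full(shape, fill, dtype=dtype)
        i = lat_idx.get_indexer(raw["lat"])
        j = lon_idx.get_indexer(raw["lon"])
        g[i, j] = col
        return g

    anth = raw["anthrome"].map(lambda a: ANTHROME_CODES.get(a, 0)).to_numpy()
    cont = raw["continent"].map(lambda c: CONTINENT_CODES.get(c, 0)).to_numpy()
    ds = xr.Dataset(
        {
            "burned_area": (("lat", "lon"), grid_of(raw["burned_area"].to_numpy(dtype=float), np.nan)),
            "pop_density": (("lat", "lon"), grid_of(raw["pop_density"].to_numpy(dtype=float), np.nan)),
            "mask": (("lat", "lon"), grid_of(raw["combustible"].to_numpy(dtype=int), -1, dtype=int)),
            "anthrome": (("lat", "lon"), grid_of(anth, -1, dtype=int)),
            "continent": (("lat", "lon"), grid_of(cont, -1, dtype=int)),
        },
        coords={"lat": lat_vals, "lon": lon_vals},
        attrs={
            "resolution": resolution,
            "anthrome_codes": ",".join(ANTHROME_MAJOR_TYPES),
            "continent_codes": ",".join(CONTINENTS),
        },
    )
    ds.to_netcdf(path, engine="scipy")


def _read_netcdf(path: Path) -> tuple[pd.DataFrame, float]:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        for name in ("burned_area", "pop_density", "mask", "anthrome", "continent"):
            if name not in ds.variables:
                raise MissingLayerError(f"missing layer/column: {name!r}")
        df = ds.to_dataframe().reset_index()
        resolution = float(ds.attrs["resolution"])
    df = df.dropna(subset=["burned_area"]).reset_index(drop=True)
    code_to_anth = {v: k for k, v in ANTHROME_CODES.items()}
    code_to_cont = {v: k for k, v in CONTINENT_CODES.items()}
    raw = pd.DataFrame({
        "lon": df["lon"].astype(float),
        "lat": df["lat"].astype(float),
        "burned_area": df["burned_area"].astype(float),
        "pop_density": df["pop_density"].astype(float),
        "combustible": df["mask"].astype(int) == 1,
        "anthrome": df["anthrome"].astype(int).map(code_to_anth),
        "continent": df["continent"].astype(int).map(code_to_cont),
        "cell_area": cell_area(df["lat"].to_numpy(dtype=float), resolution),
    })
    return raw, resolution
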
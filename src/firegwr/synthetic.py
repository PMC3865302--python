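"""Synthetic gridded worlds with known spatially varying regression structure.

Real burned-area/population analyses cannot be validated against ground
truth; these generators plant the truth.  A world is a lon/lat grid whose
log10 burned area follows

    y(u, v) = beta0(u, v) + beta1(u, v) * x(u, v) + eps,   eps ~ N(0, sd^2)

with x the log10 population density drawn from a spatially smoothed
log-normal field, beta0/beta1 smooth coefficient surfaces, and a random
fraction of non-combustible holes.  The default surfaces make beta1 a
sigmoid along longitude crossing zero mid-grid (so positive and negative
fire-population relationships coexist, as on real continents) and beta0 a
linear ramp along latitude.

A separate generator plants continuous piecewise-linear ("broken stick")
conditional-quantile structure: burned area rising with population density
up to a threshold and declining beyond it.  The default threshold is
7 persons/km^2 (log10 ~ 0.845), the change point the continental analyses
repeatedly find.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .grid_data import (
    ANTHROME_MAJOR_TYPES,
    GridDataset,
    build_dataset,
    cell_area,
)


def _default_beta1(lon, lat, lon_mid, lon_halfspan):
    # sigmoid along longitude crossing zero mid-grid; amplitude 1.5 so
    # |slope| > 1 regions exist on both flanks, as over Africa/Asia
    return 1.5 * np.tanh((lon - lon_mid) / (0.3 * lon_halfspan))


def _default_beta0(lon, lat, lat_mid, lat_halfspan):
    # linear ramp in latitude, 0..1: south less fire-prone than north
    return 0.5 + 0.5 * (lat - lat_mid) / lat_halfspan


@dataclass
class SyntheticScenario:
    """Configuration of one synthetic world (a pure function of the seed)."""

    n_lon: int = 50
    n_lat: int = 50
    resolution: float = 1.0
    noise_sd: float = 0.3
    pop_logmean: float = 0.7   # log10 persons/km^2: median ~5 p/km^2
    pop_logsd: float = 0.6
    mask_fraction: float = 0.05
    seed: int = 0
    continent: str = "Africa"
    beta0_surface: Callable | None = None  # f(lon, lat) -> intercept
    beta1_surface: Callable | None = None  # f(lon, lat) -> slope
    stationary: bool = False
    beta0_const: float = 0.5
    beta1_const: float = 1.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.mask_fraction < 1):
            raise ValueError("mask_fraction must be in [0, 1)")
        if self.n_lon * self.n_lat < 10:
            raise ValueError("degenerate grid: need at least 10 cells")


@dataclass
class SyntheticTruth:
    """Ground truth returned alongside a simulated world."""

    beta0: np.ndarray  # per retained cell, aligned with dataset.cells
    beta1: np.ndarray
    noise_sd: float
    n_clipped: int = 0  # cells whose burned area hit the cell-area ceiling


def _grid_coords(sc: SyntheticScenario) -> tuple[np.ndarray, np.ndarray]:
    lon = (np.arange(sc.n_lon) + 0.5 - sc.n_lon / 2.0) * sc.resolution
    lat = (np.arange(sc.n_lat) + 0.5 - sc.n_lat / 2.0) * sc.resolution
    return np.meshgrid(lon, lat)


def _smooth3(grid: np.ndarray) -> np.ndarray:
    """3x3 moving average with edge replication (adds spatial autocorrelation)."""
    from scipy.ndimage import uniform_filter

    return uniform_filter(grid, size=3, mode="nearest")


def simulate_gwr_world(scenario: SyntheticScenario) -> tuple[GridDataset, SyntheticTruth]:
    """Simulate one world; returns the analysis dataset and its truth.

    The population field is built by smoothing a standard-normal grid and
    rescaling to the requested log-mean/log-sd, so the predictor has the
    spatial autocorrelation real population maps show.  Burned area is
    capped at the physical cell area.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    LON, LAT = _grid_coords(sc)

    z = _smooth3(rng.standard_normal(LON.shape))
    z = (z - z.mean()) / max(z.std(), 1e-12)
    x_log = sc.pop_logmean + sc.pop_logsd * z

    if sc.stationary:
        b0 = np.full(LON.shape, sc.beta0_const)
        b1 = np.full(LON.shape, sc.beta1_const)
    else:
        lon_mid, lat_mid = LON.mean(), LAT.mean()
        lon_half = max((LON.max() - LON.min()) / 2.0, 1e-9)
        lat_half = max((LAT.max() - LAT.min()) / 2.0, 1e-9)
        f0 = sc.beta0_surface or (lambda lo, la: _default_beta0(lo, la, lat_mid, lat_half))
        f1 = sc.beta1_surface or (lambda lo, la: _default_beta1(lo, la, lon_mid, lon_half))
        b0 = np.asarray(f0(LON, LAT), dtype=float)
        b1 = np.asarray(f1(LON, LAT), dtype=float)

    eps = rng.normal(0.0, sc.noise_sd, size=LON.shape) if sc.noise_sd > 0 else np.zeros(LON.shape)
    y_log = b0 + b1 * x_log + eps

    area = cell_area(LAT.ravel(), sc.resolution)
    burned = 10.0 ** y_log.ravel()
    n_clipped = int((burned > area).sum())
    burned = np.minimum(burned, area)

    combustible = rng.random(LON.size) >= sc.mask_fraction
    raw = pd.DataFrame({
        "lon": LON.ravel(),
        "lat": LAT.ravel(),
        "burned_area": burned,
        "pop_density": 10.0 ** x_log.ravel(),
        "combustible": combustible,
        "anthrome": assign_anthromes(LON.ravel(), LAT.ravel(), layout="blocks", seed=sc.seed),
        "continent": sc.continent,
        "cell_area": area,
    })
    raw["_b0"], raw["_b1"] = b0.ravel(), b1.ravel()
    ds = build_dataset(raw[list(raw.columns[:8])], resolution=sc.resolution)
    # align truth with retained cells (build_dataset sorts by lat, lon)
    key = pd.MultiIndex.from_arrays([raw["lat"], raw["lon"]])
    truth_tbl = pd.DataFrame({"b0": raw["_b0"].to_numpy(), "b1": raw["_b1"].to_numpy()},
                             index=key)
    sel = pd.MultiIndex.from_arrays([ds.cells["lat"], ds.cells["lon"]])
    aligned = truth_tbl.loc[sel]
    truth = SyntheticTruth(beta0=aligned["b0"].to_numpy(), beta1=aligned["b1"].to_numpy(),
                           noise_sd=sc.noise_sd, n_clipped=n_clipped)
    return ds, truth


def simulate_stationary_world(n: int, beta0: float, beta1: float, noise_sd: float,
                              seed: int, resolution: float = 1.0,
                              **scenario_kwargs) -> tuple[GridDataset, SyntheticTruth]:
    """Constant-coefficient world: the null model for nonstationarity tests.

    ``n`` is rounded up to the nearest full rectangle close to square; extra
    keyword arguments (population field parameters etc.) pass through to
    :class:`SyntheticScenario`.
    """
    n_lon = int(np.ceil(np.sqrt(n)))
    n_lat = int(np.ceil(n / n_lon))
    sc = SyntheticScenario(n_lon=n_lon, n_lat=n_lat, resolution=resolution,
                           noise_sd=noise_sd, mask_fraction=0.0, seed=seed,
                           stationary=True, beta0_const=beta0, beta1_const=beta1,
                           **scenario_kwargs)
    return simulate_gwr_world(sc)


# ---------------------------------------------------------------------------
# Broken-stick quantile structure


@dataclass
class BrokenStickScenario:
    """Piecewise-linear conditional-quantile data on the log10-log10 scale.

    The median of y given x follows the continuous polyline with the given
    breakpoints (log10 population density) and per-segment slopes.  With
    ``scale_slope`` > 0 the noise scale grows with x, so upper-quantile
    slopes differ from the median's (a location-scale family).
    """

    breakpoints: Sequence[float] = field(default_factory=lambda: [np.log10(7.0)])
    segment_slopes: Sequence[float] = field(default_factory=lambda: [0.8, -0.5])
    intercept: float = 0.0
    n: int = 2000
    noise_sd: float = 0.2
    scale_slope: float = 0.0
    x_mean: float = np.log10(7.0)
    x_sd: float = 0.7
    seed: int = 0

    def __post_init__(self):
        bp = list(self.breakpoints)
        if sorted(bp) != bp or len(set(bp)) != len(bp):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.segment_slopes) != len(bp) + 1:
            raise ValueError("need one more slope than breakpoints")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def polyline_value(x, intercept: float, breakpoints: Sequence[float],
                   slopes: Sequence[float]) -> np.ndarray:
    """Continuous piecewise-linear function via the hinge basis."""
    x = np.asarray(x, dtype=float)
    y = intercept + slopes[0] * x
    for c, (s_prev, s_next) in zip(breakpoints, zip(slopes, slopes[1:])):
        y = y + (s_next - s_prev) * np.maximum(x - c, 0.0)
    return y


def simulate_broken_stick(scenario: BrokenStickScenario) -> tuple[np.ndarray, np.ndarray]:
    """Draw (x, y) samples whose conditional median is the scenario polyline."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    x = rng.normal(sc.x_mean, sc.x_sd, size=sc.n)
    med = polyline_value(x, sc.intercept, sc.breakpoints, sc.segment_slopes)
    scale = sc.noise_sd * np.maximum(1.0 + sc.scale_slope * (x - sc.x_mean), 0.05)
    y = med + scale * rng.standard_normal(sc.n)
    return x, y


# ---------------------------------------------------------------------------
# Anthrome mosaics


def assign_anthromes(lon: np.ndarray, lat: np.ndarray, layout: str = "blocks",
                     seed: int = 0, n_blocks: int = 12) -> np.ndarray:
    """Label cells with the 6 major anthrome types in contiguous patches.

    ``bands``: 6 equal longitude bands.  ``blocks``: Voronoi patches around
    ``n_blocks`` random seed points, each patch one type, all 6 types
    guaranteed present when there are at least 6 patches.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    types = np.array(ANTHROME_MAJOR_TYPES)
    if layout == "bands":
        edges = np.linspace(lon.min(), lon.max() + 1e-9, 7)
        idx = np.clip(np.searchsorted(edges, lon, side="right") - 1, 0, 5)
        return types[idx]
    if layout == "blocks":
        rng = np.random.default_rng(seed)
        n_blocks = max(n_blocks, 6)
        cx = rng.uniform(lon.min(), lon.max(), n_blocks)
        cy = rng.uniform(lat.min(), lat.max(), n_blocks)
        # each seed point gets a type; first six cover all types
        block_type = np.concatenate([
            rng.permutation(6), rng.integers(0, 6, n_blocks - 6)])
        d2 = (lon[:, None] - cx[None, :]) ** 2 + (lat[:, None] - cy[None, :]) ** 2
        return types[block_type[np.argmin(d2, axis=1)]]
    raise ValueError(f"unknown layout {layout!r}")
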
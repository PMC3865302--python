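"""Per-continent orchestration: mask -> transform -> bandwidth -> local fit
-> inference -> cross-tabulation -> quantile thresholds.

Each continent is analysed independently (the kernel never reaches across a
continent boundary because the fit is run on that continent's cells only).
All randomness flows from one root seed through numpy SeedSequence
spawning, so a configured run is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .breakpoint import fit_broken_stick, threshold_in_density_units
from .crosstab import crosstab_anthromes
from .grid_data import GridDataset, aggregate_resolution, pairwise_distances_km, read_grid
from .gwr import KernelSpec, fit_gwr, fit_ols, select_bandwidth
from .inference import (classify_cells, corrected_alpha, local_t_tests,
                        monte_carlo_nonstationarity, summarize_run)

log = logging.getLogger("firegwr")

SUMMARY_COLUMNS = ["continent", "n", "pct_significant_slopes", "pct_positive_slopes",
                   "aic_ols", "aic_gwr", "adj_r2_ols", "adj_r2_gwr",
                   "bandwidth_k", "bandwidth_fraction",
                   "perm_p_slope", "perm_p_intercept"]


@dataclass
class RunConfig:
    input_path: str | None = None
    input_format: str | None = None
    zero_policy: str = "drop"
    eps: float = 0.01
    continents: list[str] | None = None
    k_range: tuple[int, int] | None = None
    xi0: float = 0.05
    n_perm: int = 99
    seed: int = 0
    quantile_levels: tuple[float, ...] = (0.5, 0.9)
    n_breaks: int = 1
    output_dir: str = "results"

    def __post_init__(self):
        for q in self.quantile_levels:
            if not (0.0 < q < 1.0):
                raise ValueError("quantile levels must lie in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Plain key-value config (``key = value`` lines, '#' comments)."""
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key in ("continents",):
                kwargs[key] = [v.strip() for v in val.split(",")]
            elif key in ("quantile_levels",):
                kwargs[key] = tuple(float(v) for v in val.split(","))
            elif key in ("k_range",):
                kwargs[key] = tuple(int(v) for v in val.split(","))
            elif key in ("eps", "xi0"):
                kwargs[key] = float(val)
            elif key in ("n_perm", "seed", "n_breaks"):
                kwargs[key] = int(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


@dataclass
class ContinentResult:
    continent: str
    summary: dict
    fit_table: pd.DataFrame
    crosstab: pd.DataFrame
    thresholds: list[dict]
    bandwidth_profile: dict[int, float]
    permutation_p: dict[str, float]


def _spawn_seed(root_seed: int, label: str) -> int:
    """Deterministic child seed below 2**31 derived from a labelled stream."""
    h = np.random.SeedSequence([root_seed, zlib.crc32(label.encode())])
    return int(h.generate_state(1)[0] % (2**31))


def run_continent(config: RunConfig, dataset: GridDataset, continent: str,
                  out_dir: Path | None = None) -> ContinentResult:
    """Full analysis chain for one continent's cells."""
    sub = dataset.for_continent(continent)
    log.info("%s: %d cells after masking", continent, sub.n)
    D = pairwise_distances_km(sub.lon, sub.lat)

    k_star, profile = select_bandwidth(sub, config.k_range, dist_matrix=D)
    log.info("%s: k*=%d (%.1f%% of observations)", continent, k_star, 100 * k_star / sub.n)
    fit = fit_gwr(sub, KernelSpec(k=k_star), dist_matrix=D)
    ols = fit_ols(sub)

    corr = corrected_alpha(config.xi0, fit.p_eff, 2, fit.n)
    tests = local_t_tests(fit, corr.alpha)
    sig_map = classify_cells(fit, tests)
    perm = monte_carlo_nonstationarity(
        sub, KernelSpec(k=k_star), n_perm=config.n_perm,
        seed=_spawn_seed(config.seed, "perm"), dist_matrix=D)
    perm_p = {name: r.p_value for name, r in perm.items()}

    summary = {"continent": continent, **summarize_run(fit, sig_map, ols),
               "perm_p_slope": perm_p["slope"], "perm_p_intercept": perm_p["intercept"]}
    ct = crosstab_anthromes(sig_map, sub.cells, basis="area")

    thresholds = []
    for tau in config.quantile_levels:
        bs = fit_broken_stick(sub.x, sub.y, tau=tau, n_breaks=config.n_breaks)
        thresholds.append({
            "tau": tau,
            "breakpoints_log10": bs.breakpoints,
            "thresholds_p_per_km2": threshold_in_density_units(bs),
            "slopes": bs.slopes,
            "loss": bs.loss,
        })

    fit_table = pd.DataFrame({
        "lon": sub.lon, "lat": sub.lat,
        "beta0": fit.beta0_hat, "beta1": fit.beta1_hat,
        "se0": fit.se0, "se1": fit.se1, "t0": fit.t0, "t1": fit.t1,
        "local_r2": fit.local_r2,
        "slope_class": sig_map["slope_class"],
        "intercept_class": sig_map["intercept_class"],
        "joint_class": sig_map["joint_class"],
    })

    result = ContinentResult(continent=continent, summary=summary,
                             fit_table=fit_table, crosstab=ct,
                             thresholds=thresholds, bandwidth_profile=profile,
                             permutation_p=perm_p)
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(res: ContinentResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = res.continent
    res.fit_table.to_csv(out_dir / f"{stem}_fit.csv", index=False)
    res.crosstab.to_csv(out_dir / f"{stem}_crosstab.csv")
    pd.DataFrame([res.summary]).to_csv(out_dir / f"{stem}_summary.csv", index=False)
    (out_dir / f"{stem}_thresholds.json").write_text(json.dumps(res.thresholds, indent=2))
    pd.DataFrame(sorted(res.bandwidth_profile.items()),
                 columns=["k", "aicc"]).to_csv(out_dir / f"{stem}_bandwidth_profile.csv", index=False)


def run_all(config: RunConfig, dataset: GridDataset,
            out_dir: Path | None = None) -> pd.DataFrame:
    """Run every requested continent; failures abort only that continent."""
    continents = config.continents or sorted(dataset.cells["continent"].dropna().unique())
    rows = []
    for cont in continents:
        try:
            res = run_continent(config, dataset, cont, out_dir=out_dir)
        except Exception as exc:  # continue with the other continents
            log.error("%s failed: %s", cont, exc)
            continue
        rows.append(res.summary)
    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(out_dir) / "summary.csv", index=False)
    return table


def run_resolution_sensitivity(config: RunConfig, dataset: GridDataset,
                               continent: str, factors: list[int],
                               out_dir: Path | None = None) -> pd.DataFrame:
    """Repeat the continent run on coarsened grids; one row per factor."""
    rows = []
    for factor in factors:
        if not isinstance(factor, (int, np.integer)) or factor < 1:
            raise ValueError(f"factor must be a positive integer, got {factor!r}")
        coarse = aggregate_resolution(dataset, factor) if factor > 1 else dataset
        res = run_continent(config, coarse, continent)
        rows.append({"factor": factor, "resolution": coarse.resolution, **res.summary})
    table = pd.DataFrame(rows)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(out_dir) / f"{continent}_resolution_sensitivity.csv", index=False)
    return table


def load_dataset(config: RunConfig) -> GridDataset:
    if config.input_path is None:
        raise ValueError("config has no input_path")
    return read_grid(config.input_path, format=config.input_format,
                     zero_policy=config.zero_policy, eps=config.eps)
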
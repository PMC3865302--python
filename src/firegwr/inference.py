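"""Significance machinery for the local regression.

Three pieces:

* a family-wise alpha correction — with thousands of per-cell t-tests the
  nominal level must shrink; the per-test level is the desired family-wise
  rate divided by the effective number of independent local tests,
  a = xi0 * p / p_e, where p_e is the fit's effective parameter count and
  p the parameters per local model (the correction is pluggable because
  several variants circulate in the literature);
* per-cell two-sided t-tests of the local slope and intercept against zero,
  with n - p_eff reference degrees of freedom;
* a Monte Carlo permutation test of coefficient nonstationarity: shuffle
  the (x, y) pairs over the fixed cell locations, refit at the same k, and
  compare the observed spatial variance of each local coefficient with its
  permutation distribution.

Significant cells are classified by sign into the four slope x intercept
combinations (both positive; positive slope, negative intercept; negative
slope, positive intercept; both negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid_data import GridDataset, pairwise_distances_km
from .gwr import GWRFit, KernelSpec, OLSFit, SingularFitError, _moment_fit, _weight_matrix


@dataclass
class AlphaCorrection:
    xi0: float
    p_e: float
    p: int
    n: int
    alpha: float


def corrected_alpha(xi0: float, p_e: float, p: int, n: int,
                    form=None) -> AlphaCorrection:
    """Per-test significance level controlling the family-wise rate xi0.

    Default form: a = xi0 * p / p_e (reduces to xi0 when p_e = p).  Pass
    ``form(xi0, p_e, p, n)`` to substitute another correction.
    """
    if p < 1 or p_e < p:
        raise ValueError("require p_e >= p >= 1")
    if n <= p_e:
        raise ValueError("require n > p_e")
    alpha = form(xi0, p_e, p, n) if form is not None else xi0 * p / p_e
    return AlphaCorrection(xi0=xi0, p_e=p_e, p=p, n=n, alpha=alpha)


@dataclass
class TTestResult:
    """Per-cell slope/intercept significance at a given per-test alpha."""

    alpha: float
    df: float
    crit: float
    sig_slope: np.ndarray      # bool per cell
    sig_intercept: np.ndarray
    unreliable: np.ndarray     # nonpositive SE; excluded from significant sets


def local_t_tests(fit: GWRFit, alpha: float) -> TTestResult:
    """Two-sided tests of beta-hat = 0 with t = beta-hat / se."""
    df = fit.n - fit.p_eff
    if df <= 0:
        raise ValueError("nonpositive residual degrees of freedom")
    crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    bad = (fit.se0 <= 0) | (fit.se1 <= 0) | ~np.isfinite(fit.se0) | ~np.isfinite(fit.se1)
    sig_slope = (np.abs(fit.t1) > crit) & ~bad
    sig_intercept = (np.abs(fit.t0) > crit) & ~bad
    return TTestResult(alpha=alpha, df=df, crit=crit, sig_slope=sig_slope,
                       sig_intercept=sig_intercept, unreliable=bad)


@dataclass
class PermutationResult:
    coefficient: str
    observed_variance: float
    null_variances: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    n_redrawn: int = 0


def monte_carlo_nonstationarity(dataset: GridDataset, kernel: KernelSpec,
                                n_perm: int = 99, seed: int = 0,
                                dist_matrix: np.ndarray | None = None
                                ) -> dict[str, PermutationResult]:
    """Permutation test of spatial variability in the local coefficients.

    Coordinates stay fixed; the (x, y) pairs are shuffled jointly across
    cells, preserving the x-y relationship while destroying its spatial
    arrangement.  p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("need n_perm >= 99")
    x, y = dataset.x, dataset.y
    D = dist_matrix if dist_matrix is not None else pairwise_distances_km(dataset.lon, dataset.lat)
    W = _weight_matrix(D, kernel)  # depends only on coordinates: reused

    b0, b1, _ = _moment_fit(W, x, y)
    obs = {"intercept": float(np.var(b0)), "slope": float(np.var(b1))}

    rng = np.random.default_rng(seed)
    null = {"intercept": np.empty(n_perm), "slope": np.empty(n_perm)}
    n_redrawn = 0
    m = 0
    while m < n_perm:
        perm = rng.permutation(len(x))
        try:
            pb0, pb1, _ = _moment_fit(W, x[perm], y[perm])
        except SingularFitError:
            n_redrawn += 1
            if n_redrawn > 10 * n_perm:
                raise
            continue
        null["intercept"][m] = np.var(pb0)
        null["slope"][m] = np.var(pb1)
        m += 1

    out = {}
    for name in ("intercept", "slope"):
        ge = int((null[name] >= obs[name]).sum())
        out[name] = PermutationResult(
            coefficient=name, observed_variance=obs[name],
            null_variances=null[name], p_value=(1 + ge) / (n_perm + 1),
            n_perm=n_perm, seed=seed, n_redrawn=n_redrawn)
    return out


JOINT_CLASSES = ("nonsignificant", "pos/pos", "pos/neg", "neg/pos", "neg/neg")


def classify_cells(fit: GWRFit, tests: TTestResult) -> pd.DataFrame:
    """Sign classification of significant cells (the mapped classes).

    Sign comes from the point estimate, significance from the test.  The
    joint class uses slope-sign/intercept-sign and requires both marginal
    tests significant; nonsignificant cells carry no sign.
    """
    n = len(fit.beta1_hat)
    slope_class = np.full(n, "nonsignificant", dtype=object)
    slope_class[tests.sig_slope & (fit.beta1_hat > 0)] = "positive"
    slope_class[tests.sig_slope & (fit.beta1_hat < 0)] = "negative"
    intercept_class = np.full(n, "nonsignificant", dtype=object)
    intercept_class[tests.sig_intercept & (fit.beta0_hat > 0)] = "positive"
    intercept_class[tests.sig_intercept & (fit.beta0_hat < 0)] = "negative"

    joint = np.full(n, "nonsignificant", dtype=object)
    both = tests.sig_slope & tests.sig_intercept
    joint[both & (fit.beta1_hat > 0) & (fit.beta0_hat > 0)] = "pos/pos"
    joint[both & (fit.beta1_hat > 0) & (fit.beta0_hat < 0)] = "pos/neg"
    joint[both & (fit.beta1_hat < 0) & (fit.beta0_hat > 0)] = "neg/pos"
    joint[both & (fit.beta1_hat < 0) & (fit.beta0_hat < 0)] = "neg/neg"
    return pd.DataFrame({"slope_class": slope_class,
                         "intercept_class": intercept_class,
                         "joint_class": joint})


def summarize_run(fit: GWRFit, sig_map: pd.DataFrame, ols: OLSFit) -> dict:
    """One summary row: n, % significant slopes, % positive of those,
    both information criteria and both adjusted R-squareds."""
    n = len(sig_map)
    sig = sig_map["slope_class"] != "nonsignificant"
    n_sig = int(sig.sum())
    pct_sig = 100.0 * n_sig / n
    pct_pos = (100.0 * (sig_map.loc[sig, "slope_class"] == "positive").mean()
               if n_sig > 0 else float("nan"))
    return {
        "n": n,
        "pct_significant_slopes": pct_sig,
        "pct_positive_slopes": pct_pos,
        "aic_ols": ols.aic,
        "aic_gwr": fit.aicc,
        "adj_r2_ols": ols.adj_r2,
        "adj_r2_gwr": fit.adj_r2,
        "bandwidth_k": fit.bandwidth_k,
        "bandwidth_fraction": fit.bandwidth_fraction,
    }
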
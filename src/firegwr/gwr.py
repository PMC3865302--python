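"""Geographically weighted regression with an adaptive Gaussian kernel.

At every cell i the model y = beta0(i) + beta1(i) * x is fit by weighted
least squares, weighting cell j by

    w_ij = exp(-0.5 * (d_ij / b_i)^2)

where d_ij is the great-circle distance between centroids and b_i, the
adaptive bandwidth, is the distance from i to its k-th nearest neighbour —
wide where cells are sparse, narrow where dense.  k is one number for the
whole fit, chosen by minimising the corrected Akaike information criterion

    AICc = 2 n ln(sigma_hat) + n ln(2 pi) + n (n + tr(S)) / (n - 2 - tr(S))

with S the hat matrix of the full fit, sigma_hat the maximum-likelihood
residual scale sqrt(RSS/n), and tr(S) measuring model complexity.  The
effective number of parameters is p_eff = 2 tr(S) - tr(S'S); it replaces
the parameter count in variance estimates and multiplicity corrections.

With a single predictor each local solve is a 2x2 system, so the whole fit
vectorises into weighted moment matrices: no per-cell Python loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid_data import GridDataset, pairwise_distances_km


class SingularFitError(ValueError):
    """A local weighted design was rank deficient."""

    def __init__(self, cell_index):
        self.cell_index = cell_index
        super().__init__(f"singular local fit at cell index {cell_index}")


@dataclass
class KernelSpec:
    """Adaptive Gaussian kernel: bandwidth = distance to the k-th neighbour.

    Give either ``k`` (a neighbour count) or ``fraction`` (a share of n,
    rounded).  ``kind='flat'`` is the uniform-weight override under which
    every local fit collapses to the global OLS fit.
    """

    kind: str = "adaptive_gaussian"
    k: int | None = None
    fraction: float | None = None

    def resolve_k(self, n: int) -> int:
        if self.kind == "flat":
            return n
        if self.k is not None:
            k = int(self.k)
        elif self.fraction is not None:
            k = int(round(self.fraction * n))
        else:
            raise ValueError("KernelSpec needs k or fraction")
        if not (3 <= k <= n):
            raise ValueError(f"k={k} outside [3, n={n}]")
        return k


@dataclass
class OLSFit:
    beta0: float
    beta1: float
    aic: float
    adj_r2: float
    sigma2: float
    n: int


@dataclass
class GWRFit:
    """Per-cell local estimates plus global complexity diagnostics."""

    beta0_hat: np.ndarray
    beta1_hat: np.ndarray
    se0: np.ndarray
    se1: np.ndarray
    t0: np.ndarray
    t1: np.ndarray
    local_r2: np.ndarray
    leverage: np.ndarray
    trS: float
    trStS: float
    p_eff: float
    sigma2_hat: float
    aicc: float
    adj_r2: float
    bandwidth_k: int
    n: int
    rss: float
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def bandwidth_fraction(self) -> float:
        return self.bandwidth_k / self.n


# ---------------------------------------------------------------------------
# kernel building blocks


def adaptive_bandwidth_distance(coords: tuple[np.ndarray, np.ndarray] | np.ndarray,
                                i: int, k: int,
                                dist_matrix: np.ndarray | None = None) -> float:
    """Distance (km) from cell i to its k-th nearest other cell.

    Duplicate coordinates can make the k-th neighbour distance zero; the
    fallback is the smallest positive neighbour distance.
    """
    D = dist_matrix if dist_matrix is not None else _coords_to_dist(coords)
    n = D.shape[0]
    if k > n - 1:
        raise ValueError(f"k={k} exceeds n-1={n - 1}")
    d = np.delete(D[i], i)
    d.sort()
    b = float(d[k - 1])
    if b <= 0.0:
        pos = d[d > 0]
        if len(pos) == 0:
            raise SingularFitError(i)
        b = float(pos[0])
    return b


def _coords_to_dist(coords) -> np.ndarray:
    lon, lat = coords
    return pairwise_distances_km(np.asarray(lon, dtype=float), np.asarray(lat, dtype=float))


def kernel_weights(coords, i: int, b_i: float,
                   dist_matrix: np.ndarray | None = None) -> np.ndarray:
    """Gaussian weights of every cell relative to cell i at bandwidth b_i."""
    if b_i <= 0:
        raise ValueError("bandwidth must be positive")
    D = dist_matrix if dist_matrix is not None else _coords_to_dist(coords)
    return np.exp(-0.5 * (D[i] / b_i) ** 2)


def _bandwidths(D: np.ndarray, k: int) -> np.ndarray:
    """Per-cell adaptive bandwidths; vectorised k-th neighbour distances."""
    n = D.shape[0]
    kk = min(k, n - 1)
    # partition excludes self-distance 0 at position 0
    part = np.partition(D, kk, axis=1)
    b = part[:, kk]
    if np.any(b <= 0):
        Ds = np.sort(D, axis=1)
        for i in np.nonzero(b <= 0)[0]:
            pos = Ds[i][Ds[i] > 0]
            if len(pos) == 0:
                raise SingularFitError(int(i))
            b[i] = pos[0]
    return b


def _weight_matrix(D: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    n = D.shape[0]
    if kernel.kind == "flat":
        return np.ones((n, n))
    if kernel.kind != "adaptive_gaussian":
        raise ValueError(f"unknown kernel kind {kernel.kind!r}")
    k = kernel.resolve_k(n)
    b = _bandwidths(D, k)
    return np.exp(-0.5 * (D / b[:, None]) ** 2)


# ---------------------------------------------------------------------------
# local weighted least squares


def local_wls(X: np.ndarray, y: np.ndarray, w: np.ndarray,
              i: int | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """One weighted least-squares solve: beta = (X'WX)^-1 X'Wy.

    Returns (beta_hat, hat_row, fitted_i): hat_row is the row of the hat
    matrix mapping y to the fitted value at the target cell i (the cell the
    weights are centred on; defaults to argmax weight).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.sum() <= 0:
        raise SingularFitError(i)
    XtW = X.T * w
    A = XtW @ X
    if abs(np.linalg.det(A)) < 1e-300 or np.linalg.cond(A) > 1e12:
        raise SingularFitError(i)
    Ainv = np.linalg.inv(A)
    beta = Ainv @ (XtW @ y)
    ii = int(np.argmax(w)) if i is None else i
    hat_row = X[ii] @ Ainv @ XtW
    return beta, hat_row, float(X[ii] @ beta)


def _moment_fit(W: np.ndarray, x: np.ndarray, y: np.ndarray):
    """All n local 2-parameter WLS solves at once via weighted moments."""
    Z = np.column_stack([np.ones_like(x), x, x * x, y, x * y, y * y])
    M = W @ Z
    S1, Sx, Sxx, Sy, Sxy, Syy = M.T
    det = S1 * Sxx - Sx * Sx
    if np.any(np.abs(det) < 1e-12 * np.maximum(S1 * Sxx, 1e-300)):
        raise SingularFitError(int(np.argmin(np.abs(det))))
    b1 = (S1 * Sxy - Sx * Sy) / det
    b0 = (Sxx * Sy - Sx * Sxy) / det
    return b0, b1, (S1, Sx, Sxx, Sy, Sxy, Syy, det)


def fit_gwr(dataset: GridDataset, kernel: KernelSpec,
            dist_matrix: np.ndarray | None = None,
            full_diagnostics: bool = True) -> GWRFit:
    """Fit the local regression at every cell.

    ``full_diagnostics=False`` skips the O(n^2) hat-matrix cross-trace and
    the standard errors (enough for bandwidth search, which only needs
    tr(S) and the RSS).
    """
    x, y = dataset.x, dataset.y
    n = len(x)
    k = kernel.resolve_k(n)
    if n < 3 or k < 3:
        raise ValueError("need n >= k >= 3")
    D = dist_matrix if dist_matrix is not None else pairwise_distances_km(dataset.lon, dataset.lat)
    W = _weight_matrix(D, kernel)
    b0, b1, (S1, Sx, Sxx, Sy, Sxy, Syy, det) = _moment_fit(W, x, y)

    fitted = b0 + b1 * x
    resid = y - fitted
    rss = float(resid @ resid)

    # hat diagonal: S_ii = w_ii * [1 x_i] A_i^{-1} [1 x_i]' ; w_ii = 1
    leverage = (Sxx - 2.0 * x * Sx + x * x * S1) / det
    trS = float(leverage.sum())

    sigma2_ml = rss / n
    aicc_val = aicc(n, math.sqrt(max(sigma2_ml, 1e-300)), trS)

    tss = float(((y - y.mean()) ** 2).sum())

    if full_diagnostics:
        # full hat matrix S_ij = w_ij * (c0_i + c1_i x_j)
        c0 = (Sxx - x * Sx) / det
        c1 = (x * S1 - Sx) / det
        S = W * (c0[:, None] + c1[:, None] * x[None, :])
        trStS = float((S * S).sum())
        p_eff = 2.0 * trS - trStS
        dof = n - p_eff
        sigma2_hat = rss / dof if dof > 0 else np.nan

        # Var(beta_i) = sigma2 * A^-1 (X'W^2 X) A^-1
        W2 = W * W
        Z2 = np.column_stack([np.ones_like(x), x, x * x])
        M2 = W2 @ Z2
        T1, Tx, Txx = M2.T
        v00 = (Sxx**2 * T1 - 2 * Sxx * Sx * Tx + Sx**2 * Txx) / det**2
        v11 = (Sx**2 * T1 - 2 * Sx * S1 * Tx + S1**2 * Txx) / det**2
        se0 = np.sqrt(np.maximum(sigma2_hat * v00, 0.0))
        se1 = np.sqrt(np.maximum(sigma2_hat * v11, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t0 = np.where(se0 > 0, b0 / se0, 0.0)
            t1 = np.where(se1 > 0, b1 / se1, 0.0)

        # local R^2: weighted, with the fit's own per-cell fitted values
        r2w = W @ (resid * resid)
        tssw = Syy - Sy * Sy / S1
        with np.errstate(divide="ignore", invalid="ignore"):
            loc_r2 = np.where(tssw > 0, 1.0 - r2w / tssw, np.nan)

        adj_r2 = 1.0 - (rss / dof) / (tss / (n - 1)) if dof > 0 and tss > 0 else np.nan
    else:
        trStS = np.nan
        p_eff = np.nan
        sigma2_hat = np.nan
        se0 = se1 = t0 = t1 = loc_r2 = np.full(n, np.nan)
        adj_r2 = np.nan

    return GWRFit(beta0_hat=b0, beta1_hat=b1, se0=se0, se1=se1, t0=t0, t1=t1,
                  local_r2=loc_r2, leverage=leverage, trS=trS, trStS=trStS,
                  p_eff=p_eff, sigma2_hat=sigma2_hat, aicc=aicc_val,
                  adj_r2=adj_r2, bandwidth_k=k, n=n, rss=rss, fitted=fitted)


def local_r2(dataset: GridDataset, fit: GWRFit, i: int,
             dist_matrix: np.ndarray | None = None) -> float:
    """Weighted coefficient of determination around cell i.

    1 - sum_j w_ij (y_j - yhat_j)^2 / sum_j w_ij (y_j - ybar_w)^2 with
    ybar_w the w-weighted mean; NaN when the weighted variance vanishes.
    """
    D = dist_matrix if dist_matrix is not None else pairwise_distances_km(dataset.lon, dataset.lat)
    kernel = KernelSpec(k=fit.bandwidth_k)
    b = _bandwidths(D, kernel.resolve_k(fit.n))
    w = np.exp(-0.5 * (D[i] / b[i]) ** 2)
    y = dataset.y
    resid = y - fit.fitted
    ybar_w = float(w @ y / w.sum())
    tssw = float(w @ (y - ybar_w) ** 2)
    if tssw <= 0:
        return float("nan")
    return 1.0 - float(w @ (resid * resid)) / tssw


# ---------------------------------------------------------------------------
# information criteria and bandwidth selection


def aicc(n: int, sigma_hat: float, trS: float) -> float:
    """Small-sample corrected AIC for a fit with hat-matrix trace trS."""
    if n <= trS + 2:
        raise ValueError("AICc undefined: n must exceed trS + 2")
    return (2.0 * n * math.log(sigma_hat) + n * math.log(2.0 * math.pi)
            + n * (n + trS) / (n - 2.0 - trS))


def fit_ols(dataset: GridDataset) -> OLSFit:
    """Global ordinary least squares baseline, Gaussian-likelihood AIC."""
    x, y = dataset.x, dataset.y
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    import statsmodels.api as sm

    res = sm.OLS(y, sm.add_constant(x)).fit()
    rss = float(res.ssr)
    sigma_ml = math.sqrt(rss / n)
    p = 2
    aic = 2.0 * n * math.log(max(sigma_ml, 1e-300)) + n * math.log(2.0 * math.pi) + n + 2.0 * (p + 1)
    return OLSFit(beta0=float(res.params[0]), beta1=float(res.params[1]),
                  aic=aic, adj_r2=float(res.rsquared_adj),
                  sigma2=rss / (n - p), n=n)


def _aicc_at_k(dataset: GridDataset, D: np.ndarray, k: int, cache: dict) -> float:
    if k not in cache:
        try:
            fit = fit_gwr(dataset, KernelSpec(k=k), dist_matrix=D, full_diagnostics=False)
            cache[k] = fit.aicc
        except (SingularFitError, ValueError):
            cache[k] = np.inf
    return cache[k]


def select_bandwidth(dataset: GridDataset, k_range: tuple[int, int] | None = None,
                     dist_matrix: np.ndarray | None = None,
                     method: str = "golden") -> tuple[int, dict[int, float]]:
    """Choose the neighbour count k minimising AICc.

    Golden-section search on integer k followed by an exhaustive +-2 sweep
    around the incumbent; ties break toward larger k (the smoother model).
    ``method='exhaustive'`` scans the whole range (the audit oracle).
    Returns (k_star, {k: AICc}).
    """
    n = dataset.n
    if k_range is None:
        k_lo = max(16, int(round(0.01 * n)))
        k_hi = max(k_lo + 2, int(round(0.25 * n)))
    else:
        k_lo, k_hi = k_range
    k_lo = max(k_lo, 3)
    k_hi = min(k_hi, n - 1)
    if k_lo > k_hi:
        raise ValueError(f"empty bandwidth range [{k_lo}, {k_hi}]")
    D = dist_matrix if dist_matrix is not None else pairwise_distances_km(dataset.lon, dataset.lat)
    cache: dict[int, float] = {}

    if method == "exhaustive":
        for k in range(k_lo, k_hi + 1):
            _aicc_at_k(dataset, D, k, cache)
    elif method == "golden":
        phi = (math.sqrt(5.0) - 1.0) / 2.0
        lo, hi = k_lo, k_hi
        a = int(round(hi - phi * (hi - lo)))
        b = int(round(lo + phi * (hi - lo)))
        while hi - lo > 3:
            fa = _aicc_at_k(dataset, D, a, cache)
            fb = _aicc_at_k(dataset, D, b, cache)
            if fa < fb:
                hi = b
            else:
                lo = a
            a = int(round(hi - phi * (hi - lo)))
            b = int(round(lo + phi * (hi - lo)))
        for k in range(lo, hi + 1):
            _aicc_at_k(dataset, D, k, cache)
        incumbent = _best_k(cache)
        for k in range(max(k_lo, incumbent - 2), min(k_hi, incumbent + 2) + 1):
            _aicc_at_k(dataset, D, k, cache)
    else:
        raise ValueError(f"unknown method {method!r}")

    if all(np.isinf(v) for v in cache.values()):
        raise SingularFitError(None)
    return _best_k(cache), dict(sorted(cache.items()))


def _best_k(cache: dict[int, float]) -> int:
    best = min(cache.values())
    # ties toward larger k
    return max(k for k, v in cache.items() if v == best)
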
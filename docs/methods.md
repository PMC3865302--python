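# Methods

## Model and estimator

The response is y = log₁₀ mean annual burned area (km²/yr) per grid cell,
the predictor x = log₁₀ population density (persons/km²); both raw fields
are strongly right-skewed, which the decimal log removes. The local model

    yᵢ = β₀(uᵢ, vᵢ) + β₁(uᵢ, vᵢ) xᵢ + εᵢ,  ε ~ N(0, σ²I)

is estimated at every cell by weighted least squares,
β̂ᵢ = (XᵀWᵢX)⁻¹XᵀWᵢy, with Gaussian weights wᵢⱼ = exp(−½ (dᵢⱼ/bᵢ)²).
Distances are great circles on a sphere of radius R = 6371.0 km; at
continental extents planar degrees would distort east-west distances by
large factors, so a spherical metric is the only defensible choice even
though a flat one would be cheaper. The adaptive bandwidth bᵢ is the
distance from cell i to its k-th nearest cell; a single k applies to the
whole fit. The kernel is untruncated: every observation enters every local
fit (an optional cutoff would change weights by < 10⁻⁷ beyond six
bandwidths but is not enabled by default).

With one predictor each local solve is a closed-form 2×2 system, so the
whole fit reduces to weighted moment matrices (one n×n weight matrix times
an n×6 moment block) with no per-cell loop. This is what makes the
permutation test and the bandwidth search affordable: the weight matrix
depends only on coordinates and is reused across all permutations and all
candidate fits at a given k.

Complexity is measured by the hat matrix S (Sᵢⱼ = wᵢⱼ·[1 xᵢ]Aᵢ⁻¹[1 xⱼ]ᵀ):
tr S, the cross-trace tr SᵀS, and the effective number of parameters
p_eff = 2 tr S − tr SᵀS. Residual variance is RSS/(n − p_eff); local
standard errors use Var(β̂ᵢ) = σ̂² Aᵢ⁻¹(XᵀWᵢ²X)Aᵢ⁻¹. Local R² is weighted:
1 − Σⱼwᵢⱼ(yⱼ−ŷⱼ)² / Σⱼwᵢⱼ(yⱼ−ȳ_w)², using the fit's own per-cell fitted
values; it is reported as missing where the weighted variance vanishes.

## Bandwidth selection

k minimises AICc = 2n ln σ̂ + n ln 2π + n(n + tr S)/(n − 2 − tr S) with
σ̂ the maximum-likelihood residual scale √(RSS/n). With this σ̂ the
formula reduces exactly to the classical small-sample AICc of a
2-parameter linear model when tr S = 2, so GWR and OLS values are
comparable on one scale (the OLS AIC likewise includes the n ln 2π
constant). The search is golden-section on integer k followed by an
exhaustive ±2 sweep around the incumbent; ties break toward larger k (the
smoother model). An exhaustive mode exists purely as an audit oracle. The
default range is [max(16, 0.01n), 0.25n]: below ~16 neighbours a
2-parameter weighted fit is too noisy to rank stably, and beyond a quarter
of the data the model is near-global. The AICc profile is returned (and
logged by the pipeline) so a flat or boundary-hugging profile is visible
rather than silent.

## Inference

*t-tests.* Each cell's slope and intercept are tested two-sided with
t = β̂/se against a reference t distribution with n − p_eff degrees of
freedom (consistent with the residual-variance denominator). The per-test
level is a = ξ₀·p/p_e — the family-wise rate ξ₀ (default 0.05) divided by
the effective number of independent local tests p_e/p. With p_e = p it
reduces to ξ₀. The correction function is pluggable because several
variants circulate (some involve n); the implemented default is the form
whose semantics match "divide the family-wise rate across effective
tests". Cells with nonpositive standard errors are flagged unreliable and
never counted significant.

*Permutation test.* Nonstationarity of each coefficient is tested by
shuffling the (x, y) pairs jointly across cell locations (coordinates
fixed), refitting at the same k, and recording the spatial variance of the
local coefficients; p = (1 + #{null ≥ observed})/(n_perm + 1), so p can
never be 0. Shuffling pairs preserves the x-y relationship and destroys
only its spatial arrangement — the hypothesis actually at issue. Singular
permuted fits are redrawn and counted. Maps are gated by the t-tests; the
permutation p is reported alongside (it answers "is there any spatial
variation", not "which cells").

A caveat measured by the test suite: pair permutation is exact only when
the pairs are exchangeable across locations. The synthetic population
field is spatially autocorrelated (as real population is), which makes the
test mildly anti-conservative — the pooled empirical size at nominal 0.05
over 500 stationary worlds in the acceptance suite is about 6–7%. Under an
exchangeable null (pairs pre-shuffled) the size is exact; a dedicated
property test verifies this. Conclusions that lean on p-values near the
threshold should keep this inflation in mind.

## Broken-stick quantile regression

Conditional quantiles of y given x are modelled as continuous piecewise
linear functions via the hinge basis {1, x, (x−c)₊, …}; coefficients for a
fixed breakpoint set minimise the check loss (statsmodels' iteratively
reweighted quantile solver, loss tolerance 10⁻⁹). Breakpoints are found by
exhaustive search over a candidate grid inside the central 90% of the x
range — the loss is piecewise linear in c, so a grid is exact to its
resolution and auditable against brute force, unlike smooth optimisation
over a non-smooth objective. Defaults: 101 candidates for one breakpoint,
31 per axis for two (the pairwise search grows quadratically). Candidates
leaving any segment under 10 points are skipped; ties break toward the
smallest breakpoint. Breakpoints convert to density units as 10^c
persons/km². No confidence intervals on breakpoints are provided (a
bootstrap hook is the natural extension).

## Data handling

Cell areas use the spherical latitude correction (RΔ)²cos(lat); summed
over a global grid this reproduces 4πR² to well under 0.5%. Whether an
ellipsoidal model was ever intended is unknowable from a printed area
table; the spherical form is self-consistent with the haversine metric.
Zero burned area or zero population under a decimal log is undefined; the
default policy drops such cells (an epsilon floor is available via
config), because a floor constant placed below the data range manufactures
an arbitrary cluster that can dominate a log-log regression. Aggregation
to coarser grids sums burned area, takes area-weighted mean population
density, assigns anthrome and continent by majority area, marks a parent
combustible if any child is, and re-applies the transform. Continent
membership is an input label, not computed from polygons. IO formats:
flat CSV (UTF-8, one cell per row) and NetCDF with named layers
{burned_area, pop_density, mask, anthrome, continent}; both round-trip
exactly and a missing layer raises an error naming it.

## Synthetic worlds

`simulate_gwr_world` emulates the structure of the real gridded inputs:
a log-normal population field given spatial autocorrelation by a 3×3
moving average (re-standardised to the target log-mean 0.7 and log-sd 0.6,
i.e. median ≈ 5 p/km²); a slope surface β₁ = 1.5·tanh along longitude
crossing zero mid-grid, so strongly positive and negative fire-population
regimes coexist as they do on real continents; an intercept ramp along
latitude; homoskedastic Gaussian noise (default sd 0.3 in log₁₀ units);
5% non-combustible holes; Voronoi-block anthrome mosaics. Burned area is
capped at the physical cell area (touches ≲ 0.3% of cells at the
defaults). The broken-stick generator plants a polyline with its
breakpoint at log₁₀(7) ≈ 0.845 — about 7 persons/km², the density at
which fire response typically reverses — with slopes +0.8/−0.5, noise sd
0.2, n = 2000, and an optional location-scale term so upper-quantile
slopes differ from the median's.

What the generators do *not* emulate: the real spatial autocorrelation
spectrum or marginal distributions of satellite burned area beyond
log-skewness, climate/vegetation covariates, coastline geometry, or any
dependence between the anthrome mosaic and the population field. Passing
recovery tests therefore demonstrates the estimator and inference
machinery are correct, not that the real-world data meet the model's
assumptions.

## Problem sizes and numerical choices

Default study sizes: 50×50 cells (≈ 2400 after masking) for surface
recovery, 20×20 for permutation-test replicates (100 worlds × 99
permutations), n = 2000 for quantile-threshold replicates. Local solves
reject designs with condition number above 10¹²; duplicate coordinates
fall back to the smallest positive neighbour distance for the bandwidth.
All generators and the pipeline are pure functions of their seed; the
pipeline derives child seeds from the root via SeedSequence with stable
labels, so identical configs give byte-identical outputs.

## Known limitations

Single predictor only (no semiparametric or multi-predictor GWR); Gaussian
kernel only; no spatially corrected standard errors beyond the effective
parameter count; the permutation-test anti-conservativeness above; no
breakpoint confidence intervals; GeoTIFF IO is not implemented (CSV and
NetCDF are).
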
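# firegwr

Spatially varying regression of burned area on human population density.

People change fire regimes in opposite directions in different places:
pastoralists burning rangeland increase the area burned as population
grows, while cropland expansion fragments fuels and suppresses fire. A
single global regression averages these opposing effects into noise.
`firegwr` implements the analysis chain that resolves them on a grid of
cells — for fire ecologists and biogeographers who want local, testable
estimates of the fire-population relationship, validated end to end on
synthetic worlds with known truth.

## The model

For cell *i* at location (uᵢ, vᵢ), with y = log₁₀ mean annual burned area
(km²/yr) and x = log₁₀ population density (persons/km²):

    yᵢ = β₀(uᵢ, vᵢ) + β₁(uᵢ, vᵢ) xᵢ + εᵢ,   ε ~ N(0, σ²I)

Geographically weighted regression (GWR) estimates β(uᵢ, vᵢ) by weighted
least squares centred on each cell, with adaptive Gaussian weights

    wᵢⱼ = exp(−½ (dᵢⱼ / bᵢ)²),   bᵢ = great-circle distance to the k-th nearest cell,

so the kernel widens where data are sparse. The single neighbour count k
is chosen by minimising the corrected Akaike criterion

    AICc = 2n ln σ̂ + n ln 2π + n (n + tr S) / (n − 2 − tr S),

where S is the hat matrix and σ̂² = RSS/n. Around the fit:

- per-cell t-tests of slope and intercept at a family-wise-corrected level
  a = ξ₀ · p / p_e, with p_e = 2 tr S − tr SᵀS the effective number of
  parameters;
- a Monte Carlo permutation test of coefficient nonstationarity (shuffle
  the (x, y) pairs over fixed locations, compare spatial variances of the
  local coefficients);
- sign classification of significant cells and area-weighted
  cross-tabulation against the six major anthrome (anthropogenic biome)
  types;
- continuous piecewise-linear ("broken stick") quantile regression at the
  50th and 90th percentiles, minimising the check loss
  ρ_τ(r) = r(τ − 1[r<0]) over a hinge basis, to locate the population
  density at which the fire response changes direction.

No external rasters are bundled; the `synthetic` module generates gridded
worlds with planted coefficient surfaces, noise, non-combustible holes and
anthrome mosaics, so every stage is testable against known truth.

## Worked example

```python
import numpy as np
from firegwr import (SyntheticScenario, simulate_gwr_world, KernelSpec,
                     fit_gwr, fit_ols, select_bandwidth)

ds, truth = simulate_gwr_world(SyntheticScenario(seed=1))
k_star, profile = select_bandwidth(ds)
fit = fit_gwr(ds, KernelSpec(k=k_star))
ols = fit_ols(ds)
print(k_star, round(np.corrcoef(truth.beta1, fit.beta1_hat)[0, 1], 3))
print(round(fit.adj_r2, 3), round(ols.adj_r2, 3))
```

prints

```
24 0.997
0.938 -0.0
```

The world has 2385 retained cells whose true slope surface runs from −1.5
in the west to +1.5 in the east. AICc picks a bandwidth of 24 neighbours
(1.0% of the observations); the estimated slope surface correlates 0.997
with the planted one. The global OLS fit explains nothing (adjusted R²
≈ 0.0) because the opposing local slopes cancel — exactly the failure mode
GWR exists to fix — while the local model reaches adjusted R² = 0.94.

The same chain is available as numbered drivers under `analysis/`
(simulation → fit → significance → anthromes → thresholds → resolution
sensitivity), each printing what it found and writing tables under
`results/`, and as a CLI (`firegwr simulate|fit|sensitivity|thresholds|crosstab`).

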
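# geodrivers

Spatiotemporal driving-force analysis for areal concentration panels — the
kind of question an air-quality epidemiologist asks of a city-level PM2.5
panel: *do concentrations cluster in space, which socio-economic and
meteorological factors explain the spatial pattern, and at what spatial
scale does each factor act?*

The package chains four classical spatial-statistics stages over a common
city-panel container, plus a ground-truth-known synthetic generator so that
every stage is testable without any external data:

1. **Spatial autocorrelation.** Global Moran's I over a binary contiguity
   matrix W (queen/rook from polygons, or an explicit adjacency list),

   `I = n Σᵢⱼ Wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / (Σᵢ(xᵢ−x̄)² · S₀)`, `E[I] = −1/(n−1)`,

   with analytic Z-scores (randomization or normality moments) and
   permutation inference; the local decomposition Iᵢ (which satisfies
   Σᵢ Iᵢ = S₀·I exactly) yields H–H "hot zone" / L–L "cold zone" / H–L /
   L–H cluster labels at the |Z| ≥ 1.96 and ≥ 2.58 tiers.
2. **Stratified heterogeneity (Geodetector).** The factor detector's
   q-statistic `q = 1 − Σₕ Nₕσₕ² / (Nσ²)` measures the variance share a
   categorical stratification explains (significance via the noncentral-F
   approximation); ecological and interaction detectors compare and overlay
   stratifications. Continuous covariates are discretized with exact
   natural breaks (Fisher dynamic program); polygon attributes can be
   resampled on a regular km lattice.
3. **Collinearity screening.** Pearson correlation matrix, single-linkage
   clustering on 1 − |r| to drop near-duplicate covariates, then variance
   inflation factors `VIF = 1/(1 − R²)` with a pass/fail threshold
   (default 5).
4. **Spatially varying-coefficient regression.** GWR with a Gaussian kernel
   `w = exp(−(d/b)²)` (fixed-distance or adaptive nearest-neighbour
   bandwidth) selected by corrected AICc, and multiscale GWR: backfitting
   with a separate AICc-optimal bandwidth per covariate, exact per-term
   hat-matrix ENP, and regional mean-coefficient summaries that flag each
   region's strongest driver.

## Worked example

```python
from geodrivers import (KernelSpec, compare_models, fit_gwr, fit_mgwr,
                        generate_panel, select_bandwidth)
from geodrivers.synthetic import multiscale_recovery_spec

spec = multiscale_recovery_spec(seed=1)     # 20x20 lattice, 3 known surfaces
panel, _, _, truth = generate_panel(spec)
coords, y, X = panel.coords(), panel.response(), panel.X()

bw = select_bandwidth(coords, y, X, mode="adaptive", standardize=True)
gwr = fit_gwr(coords, y, X, KernelSpec("adaptive", bw.bandwidth), standardize=True)
mgwr = fit_mgwr(coords, y, X, standardize=True)
print(bw.bandwidth, mgwr.bandwidths)
print(compare_models(gwr, mgwr).round(3))
```

prints (seed 1)

```
13.0 [400.  26.   9.]
                      GWR    MGWR
Analysis Index
Residual Squares   17.930  16.173
Effective Number   89.026  69.958
Sigma               0.240   0.221
AICc              126.260  24.940
R2                  0.955   0.960
R2Adjusted          0.942   0.951
```

The single GWR bandwidth (13 neighbours) has to compromise between a
constant intercept, a gradient and a sinusoidal coefficient surface; MGWR
assigns the constant surface a near-global bandwidth (400), the gradient an
intermediate one (26) and the sinusoid a local one (9), and wins on every
diagnostic. Each `examples/*.py` script walks one capability the same way
(autocorrelation, detectors, screening, regression, full pipeline, station
aggregation).

A thin CLI mirrors the pipeline:

```bash
geodrivers simulate --seed 3 --out panel.csv
geodrivers run-all --panel panel.csv --adjacency panel.adjacency.csv --seed 3 --out results/
```

All outputs are CSVs with a version/config-hash header plus a JSON run
sidecar; one seed controls every stochastic step, so a rerun from the same
configuration is file-identical.

## Layout

- `src/geodrivers/` — `panel` (I/O + temporal aggregation), `weights`,
  `moran`, `geodetector`, `screening`, `gwr`, `synthetic`, `pipeline`, `cli`
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, assumptions, numerical choices, limitations
- `tests/` — unit, property and acceptance suites
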
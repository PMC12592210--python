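# forestedge

Forest fragmentation creates edges, and biomass density near edges usually
differs from the forest interior.  `forestedge` quantifies these **edge
effects on aboveground biomass (AGB)** the way large-scale raster analyses
do it: per grid cell, sampled forest locations are fitted with a spatially
filtered log-linear regression

```
Y = β0 + β1 · log10(D) + ε
```

where `Y` is AGB density (Mg ha⁻¹), `D` the Euclidean distance (m) to the
nearest non-forest pixel, and `β1` — written ΔAGB/ΔD — is the edge-effect
slope (positive ⇒ biomass is lower near edges).  Spatial autocorrelation in
the residuals is absorbed by greedily selected Moran eigenvectors of the
point connectivity graph.  Per-cell slopes are trimmed, summarised with
inverse-CV weights, attributed to environmental drivers (weighted XGBoost +
exact TreeSHAP, evaluated with spatially buffered leave-one-out CV), and
converted into a counterfactual carbon account: edge pixels are assigned
the interior-equivalent density at the cell's *depth of edge influence*
`D*` (the mean edge distance of the top-decile-biomass points), and the
resulting "missing biomass" is aggregated to biome/global totals and
carbon (wood carbon fraction 0.476; roots optionally 22 % of total tree
biomass).

The package is aimed at landscape ecologists and carbon-accounting
researchers who want this pipeline **testable end to end**: a synthetic
fragmented-landscape generator with known ground truth (clearing geometry,
biomass law, planted covariate effects) stands in for global 30 m rasters,
so every stage has a parameter-recovery test.

## Worked example

One fragmented 128×128 cell at 30 m resolution, generated with a known
slope of 50 and correlated + white pixel noise, then analysed:

```python
import forestedge as fe
from forestedge.simulate import RandomFieldClearings, LandscapeTruth

land = fe.generate_forest_mask((128, 128), resolution=30,
                               clearing_spec=RandomFieldClearings(quantile=0.3,
                                                                  correlation_range=150),
                               seed=1)
truth = LandscapeTruth(beta0=100, beta1=50, noise_sd_white=20,
                       noise_sd_spatial=10, seed=1)
land, _ = fe.generate_biomass(land, truth)
dist = fe.distance_to_edge(land.forest_mask(), 30)
points = fe.sample_points(land, dist, cell_px=128, n_per_cell=500, seed=1)

res = fe.EdgeEffectModel.from_points(points).fit(seed=1)
print(res.summary())
```

```
Spatially filtered log-linear edge-effect regression
  response: biomass   n = 500   R^2 = 0.4516
                      coef    std err
  intercept (beta0)   82.7589     6.8804
  log10 D  (beta1)    57.2366     3.1372
  eigenvectors used: 9
  residual Moran's I: 0.1409 -> 0.0269  (p 0.005 -> 0.085)
  classification: negative_edge_effect
```

The fitted slope (57.2 ± 3.1) is close to the planted 50; nine Moran
eigenvectors reduced residual spatial autocorrelation from I = 0.14 to a
non-significant 0.03.  The classification is a *negative edge effect*
(biomass lower near edges).  Continuing into the carbon account:

```python
from forestedge.accounting import depth_of_edge_influence, counterfactual_cell

d_star, mode = depth_of_edge_influence(points["distance_m"].to_numpy(),
                                       points["agb_mg_ha"].to_numpy())
acc = counterfactual_cell(land.biomass, dist, 30, res.estimate(cell_id=0), d_star)
```

```
depth of edge influence: 297 m (top_decile)
actual 214,079 Mg | counterfactual 232,171 Mg | missing 18,092 Mg
```

i.e. if every pixel nearer than 297 m to an edge held the interior density
predicted at 297 m, this cell would store ~18 kt more biomass — about 8 %
of its counterfactual stock.

## Full pipeline and CLI

The multi-cell pipeline (simulate → sample → filter → fit → trim →
summarise → attribute → account → report) is driven by a YAML config and a
global seed:

```bash
forestedge all --config demo.yaml --seed 1 --out-dir runs/demo
```

Each stage writes checkpoints (CSV tables, TIFF rasters + JSON sidecars,
metrics JSON, PNG report) into the run directory and can be re-run
individually (`forestedge fit ...`).  Identical config + seed reproduces
byte-identical tables.

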
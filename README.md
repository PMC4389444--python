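# spatrisk

Kernel estimation of the **spatial relative risk function** (sRRF) from
case/control point patterns, with fixed and adaptive bandwidth regimes,
asymptotic tolerance contours for elevated risk, and an area-overlay
framework that scores detected risk regions against known truth.

The package is aimed at spatial epidemiologists — e.g. cancer-registry
analysts — who monitor small-area disease risk from individual case
locations and a spatial sample of population controls, and who need to
understand how the choice of kernel bandwidth regime changes what a risk
map detects.

## The model

Given case locations with density `f` and control locations with density
`g` over a planar study window, the sRRF is the log ratio of two
bivariate Gaussian kernel density estimates evaluated on a raster grid:

```
r̂(x) = log( f̂(x) / ĝ(x) ),     f̂(x) = (1/n) Σᵢ hᵢ⁻² K((x − Xᵢ)/hᵢ)
```

with Diggle's boundary correction (each kernel divided by its mass
inside the window). Two bandwidth regimes are implemented:

* **Fixed** — one bandwidth for all points, selected by Terrell's
  oversmoothing (maximal smoothing) principle on the pooled pattern,
  `h = C·σ̂·(n_f + n_g)^(−1/6)`, the largest smoothing consistent with
  the data's scale.
* **Adaptive (Abramson)** — per-point bandwidths
  `hᵢ = h₀ · f(Xᵢ)^(−1/2) / γ`, inversely proportional to the square
  root of a pilot density (least-squares cross-validation pilots,
  selected separately for cases and controls), geometric-mean-normalised
  so that GM(hᵢ) = h₀, with the global bandwidth h₀ selected by
  oversmoothing at the effective sample size `√(n_f·n_g)`. For equal
  samples, `h₀ = 2^(1/6) · h_fixed` exactly.

Pointwise significance of elevated risk (H₁: r(x) > 0) is assessed with
`z(x) = r̂(x)/√V̂(x)` referred to N(0, 1), where `V̂` is a finite-sample
kernel second-moment plug-in for the variance of the log ratio; the
α = 0.05 tolerance contours are the iso-lines of the one-sided p-value
surface. Sensitivity-scenario scalings S1–S4 (halving/doubling the pilot
and global bandwidths) are built in.

Because real registry data cannot ship with the package, a first-class
synthetic module reproduces the study design that makes the truth known:
community population counts are dasymetrically disaggregated onto a 20 m
grid proportionally to surface sealing (imperviousness), which ignores
building height and therefore *underestimates* residents of high-rise
urban cores and *overestimates* the low-rise surroundings. Census tracts
whose relative error `RE_b = ((ŷ_b − y_b)/y_b)·100` falls below −50 %
are the **true risk areas** (buffered by 500 m). Controls are sampled
from the biased grid, cases from the true population (constant
individual risk), so the case/control ratio is genuinely elevated
exactly where the population was undercounted. Detection is scored by
cell-wise overlay: `Se = TP/(TP+FN)`, `Sp = TN/(FP+TN)`,
`LR+ = Se/(1−Sp)`.

## Worked example

```python
import numpy as np
from spatrisk import RelativeRiskModel, generate_study

study = generate_study(seed=42)                 # synthetic region + risk areas
cases, controls = study.sample_patterns(rng=np.random.default_rng(42))
result = RelativeRiskModel(cases, controls, estimator="adaptive",
                           grid=study.analysis_grid).fit()
print(result.summary())
scores = result.evaluate(study.risk_areas)
print(f"Se = {scores.se:.2f}  Sp = {scores.sp:.2f}  LR+ = {scores.lr_plus:.2f}")
```

prints

```
Spatial relative risk function
==============================================
estimator:        adaptive (scenario none)
cases / controls: 2000 / 2000
window:           20000 m x 20000 m
grid:             100 x 100 @ 200 m
h fixed (OS):        1545.15 m
h0 global (OS'):     1734.37 m
pilot h (cases):      149.73 m
pilot h (ctrls):      319.79 m
log RR range:     [-0.873, 0.614]
alpha (1-sided):  0.05
significant area: 46.84 km^2 (11.7% of window)
masked cells:     0

Se = 0.53  Sp = 0.91  LR+ = 6.04
```

The oversmoothing bandwidth (1545 m) is an order of magnitude wider than
the LSCV pilots (150–320 m) — the conservative upper bound the OS
principle is designed to give. The adaptive fit detects 53 % of the true
risk area while flagging 9 % of the risk-free area; a fixed-bandwidth
fit of the same data is more conservative (lower sensitivity, higher
specificity), because its single oversmoothed bandwidth dilutes the
urban risk cores. `result.plot()` maps the log-RR surface with the
significant tolerance contours; `result.regions_geojson(path)` exports
them.

A command-line interface wraps the same pipeline:

```bash
spatrisk run --seed 7 --out results/run7          # full study, one seed
spatrisk generate --seed 7 --out data/            # region + patterns only
spatrisk estimate --cases data/cases.csv --controls data/controls.csv \
    --estimator adaptive --grid-from data/risk_mask.asc --out results/fit
spatrisk evaluate --significant results/fit/significant_mask.asc \
    --risk-mask data/risk_mask.asc
```

Point patterns are CSV (`x,y[,label]` in metres), rasters are plain-text
Esri ASCII grids, significant regions are GeoJSON, and run reports are
CSV plus a JSON metadata file carrying the seed and configuration hash.

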
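# Methods

## The spatial relative risk function

`spatrisk` estimates the log relative risk surface
`r̂(x) = log f̂(x) − log ĝ(x)` of a planar case/control point design.
Both densities are bivariate Gaussian kernel estimates evaluated at the
cell centres of a regular analysis raster, conditioned on their sample
sizes, and edge-corrected in Diggle's sense: the kernel of a point at
`Xᵢ` is divided by the Gaussian mass that falls inside the rectangular
study window (the product of two univariate normal interval
probabilities, computed with the point's own bandwidth in the adaptive
case). The estimate therefore integrates to ≈ 1 over the window, which
the test suite asserts at 2 %.

The underlying assumptions are the standard ones of the case/control
sRRF design: cases and controls are independent samples from two
intensity surfaces over the same window; under the null of constant
risk the two surfaces are proportional and `r(x) ≡ 0`; elevated risk is
a local excess of case density relative to the control (population)
density. Only *elevated* risk is tested (one-sided, `H₁: r(x) > 0`).

## Bandwidth selection

**Fixed regime.** One bandwidth for every observation, selected by the
maximal-smoothing (oversmoothing) principle on the pooled case+control
pattern: `h = C·σ̂·n_eff^(−1/6)` with `n_eff = n_f + n_g`. For the
bivariate Gaussian kernel the maximal-smoothing constant is
`C = (2500/1536)^(1/6) ≈ 1.0847`. The scale `σ̂` is the root of the mean
of the two marginal sample variances — a symmetric choice matching the
radially symmetric kernel; it is recorded in the selection's method
tags. Oversmoothing is deliberately conservative: it is an upper bound
on the useful amount of smoothing and suppresses accidental features,
at the price of diluting genuine small-scale structure.

**Adaptive (Abramson) regime.** Per-observation bandwidths
`hᵢ = h₀·f(Xᵢ)^(−1/2)/γ`, where `f` is a pilot density and `γ` is the
geometric mean of the `f(Xᵢ)^(−1/2)` terms, so that the geometric mean
of the `hᵢ` equals the global bandwidth `h₀` exactly (asserted at 1e-6
relative). Pilot bandwidths are least-squares cross-validation (LSCV)
selections made *separately* for cases and controls, which preserves
each pattern's spatial heterogeneity; the global bandwidth applies the
oversmoothing principle with the geometric-mean effective sample size
`√(n_f·n_g)`, so for equal samples `h₀ = 2^(1/6)·h_fixed`. Pilot
densities are evaluated exactly at the data points by direct kernel
summation (self term included) rather than off the analysis raster,
because LSCV pilots are routinely smaller than an analysis cell and a
gridded pilot would misstate them badly.

**LSCV.** The criterion
`LSCV(h) = ∫f̂² − (2/n)Σᵢ f̂₋ᵢ(Xᵢ)` has a closed form for Gaussian
kernels and is minimised over a 61-point log-spaced grid on
`[σ̂·n^(−1/2), 3·h_OS]` followed by bounded local refinement. All local
minima are reported; exact ties resolve to the largest bandwidth
(conservative). Two known pathologies are detected and flagged rather
than hidden: a global minimum on the lower boundary (the `h → 0`
degeneracy) and duplicated points, which drive it.

**Scenarios.** S1–S4 rescale the selected bandwidths for sensitivity
analysis: S1 halves pilot and global bandwidths, S4 doubles both, S2
halves the pilot and doubles the global, S3 the reverse; the fixed
estimator follows the global factor.

## Significance and tolerance contours

The pointwise test statistic is `z(x) = r̂(x)/√V̂(x)` referred to
N(0, 1); the α = 0.05 tolerance contours are the iso-lines of the
one-sided p surface, extracted by marching squares on the p raster
(padded with p = 1 so every contour closes) and assembled into shells
with holes by even–odd nesting depth.

Two variance estimators are provided.

* `variance="plugin"` (default): a finite-sample kernel second-moment
  estimate per surface, `V̂ar(f̂(x)) = Σᵢ wᵢ²Kᵢ(x)² − f̂(x)²/n`, with
  `V̂(x) = V̂ar(f̂)/f̂² + V̂ar(ĝ)/ĝ²`. Where the data are dense this
  converges to the familiar asymptotic `R(K)/(n h² f̂)` (the test suite
  checks agreement in dense regions), but at sparse fringe cells —
  where an estimate rests on one or two kernel tails — it remains
  honestly large instead of declaring near-zero variance.
* `variance="asymptotic"`: the textbook plug-in
  `V̂(x) = R(K)·[1/(n_f h_f(x)² f̂) + 1/(n_g h_g(x)² ĝ)]` with
  `R(K) = 1/(4π)`; for the adaptive estimator the local bandwidth
  surface is the Abramson rule applied to the gridded pilot,
  `h(x) = h₀·pilot(x)^(−1/2)/γ`, which makes the variance of each log
  density nearly constant in space — the variance stabilisation that
  motivates adaptive smoothing. This form is exact asymptotics but
  anti-conservative off the data mass; it is kept for reference and
  comparison.

The default is validated by a null calibration experiment (cases and
controls drawn from one surface; 200 replicates of n = 500 each; fixed
OS bandwidth): the mean empirical exceedance of z > 1.6449 across
interior cells is ≈ 0.057, within the nominal neighbourhood of 0.05.
No multiple-testing adjustment is applied across cells — the contours
are pointwise by construction, and the family-wise error over ~10⁴
cells is correspondingly larger; this matches standard tolerance-contour
practice and is a documented property, not an oversight.

Numerical choices: kernels are truncated at 5 bandwidths (neglected
mass < 4·10⁻⁶ per point); densities are floored at 10⁻¹² m⁻² before
the log ratio and cells where both densities sit at the floor are
masked; pilot densities are floored at 10⁻¹² m⁻² before the −½ power;
edge factors are clamped at 10⁻¹² before division; the one-sided 5 %
critical value is 1.6449.

## The synthetic study generator

The generator emulates a risk-surface construction in which "true risk
areas" arise from a *population denominator error* rather than planted
disease excess. A study window (default 20 km × 20 km) is partitioned
into 36 communities of 9 census tracts each. The ancillary covariate is
a surface-sealing raster (20 m cells): a rural background of 6–10 %
sealing, and six two-tier towns placed at community centres — a
low-rise sprawl belt (radius ≈ 1.15–1.4 km, sealing 55 %, building
height factor 1) around a compact high-rise core (radius ≈ 450–550 m,
sealing 80 %, height factor 7–9 with a flat-topped profile). A total
population of 250 000 (one age stratum) is allocated to communities in
proportion to built volume (sealing × height).

The *true* population spreads each community's count proportionally to
sealing × height; the *biased* dasymetric estimate uses sealing alone —
deliberately ignoring building height, the single bias source. Both are
mass-preserving per community (asserted to 0.5 person). Tract relative
errors then fall out of the geometry: high-rise core tracts are
underestimated beyond −50 % (≈ 6 tracts per realisation), sprawl and
rural tracts of mixed communities are overestimated, and purely rural
communities are unbiased. Tracts with `RE_b < −50 %` (a fixed-percent
threshold; a quantile mode is also available since the two need not
coincide on synthetic data) are unioned, buffered by 500 m and
rasterised by cell-centre membership onto the analysis grid
(default 200 m) as the true risk-area mask — about 6–7 % of the window.
Tracts with zero true population are excluded from the ranking (the
relative error is undefined there) with a warning.

Controls are drawn from the biased grid, cases from the true population
(constant individual risk), in a 1:1 design with n = 2000 by default:
a cell is chosen with probability proportional to its weight and the
point placed uniformly inside it. Sampling, like everything else, is
driven by a single seeded generator recorded in the run metadata.

Default problem sizes (window, grid resolutions, sample size, replicate
counts in the acceptance workloads) were chosen as the smallest
realisation that preserves the scale relationships of the emulated
study design — oversmoothing bandwidths an order of magnitude above the
LSCV pilots and several times the risk-core diameter, clustered
patterns with nearest-neighbour ratios below 1, risk areas a small
fraction of the window — while keeping a full replicate batch a
desk-scale computation.

What the generator does *not* emulate, and what passing tests therefore
do not show: real case patterns carry disease-specific geography
(screening uptake, occupational exposure, reporting variation) that is
only partially aligned with the population-denominator bias, whereas
synthetic cases follow the true population exactly (constant risk).
Detection of the synthetic risk areas is consequently power-limited
rather than alignment-limited, and absolute sensitivities here do not
transfer to real registry data; the fixed-versus-adaptive *contrast* is
the quantity of interest. One documented consequence: halving both
adaptive bandwidths (scenario S1) raises specificity but lowers
sensitivity in this synthetic design, because sharper estimates can
only shrink significant regions when every risk area already coincides
with a dense, well-detected case cluster; reported real-data behaviour,
where halving improved both, requires the partial alignment above.

## Scoring

Detected regions are compared with the true risk mask cell-by-cell on
the analysis raster (boundary cells assigned by cell-centre
membership, so TP+FP+FN+TN equals the window area to one cell), giving
Se, Sp and `LR+ = Se/(1−Sp)`; LR+ is reported as infinity when Sp = 1.
The raster overlay is deterministic and scale-controlled, in contrast
to polygon-exact overlay whose precision depends on contour
interpolation. The nearest-neighbour ratio diagnostic divides the mean
nearest-neighbour distance by the Clark–Evans CSR expectation
`1/(2√λ)`, uncorrected by default (a Donnelly edge-adjusted variant is
available behind a flag).

## Known limitations

* Rectangular windows only in the closed-form edge correction; the
  design carries a raster-quadrature generalisation for polygonal
  windows but the synthetic study does not exercise it.
* The asymptotic variance option should not be used for mapping
  significance into sparsely populated fringes (see above).
* LSCV inherits its documented instabilities (multiple minima,
  degeneracy under ties); the selector reports them but cannot repair
  them.
* Decreased-risk regions (r(x) < 0) are not tested or contoured.
* No age/sex stratification; one population stratum throughout.
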
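"""The spatial relative risk function and its significance surfaces.

The spatial relative risk function is the log ratio of the case and
control kernel density surfaces,

    r_hat(x) = log( f_hat(x) / g_hat(x) ),

estimated on a raster grid. Significance of locally elevated risk
(H0: r(x) = 0 against H1: r(x) > 0) is assessed pointwise with a z
statistic built from the plug-in asymptotic variance of the log ratio,

    V_hat(x) = R(K) * [ 1 / (n_f h_f(x)^2 f_hat(x))
                      + 1 / (n_g h_g(x)^2 g_hat(x)) ],

with R(K) = 1/(4*pi) for the bivariate Gaussian kernel, and z(x) referred
to N(0, 1). One-sided upper p-values below alpha delimit the tolerance
contours of significantly elevated risk. No multiple-testing adjustment
is applied across cells; the contours are pointwise by construction.

The module is organised around :class:`RelativeRiskModel` (built from a
case and a control point pattern) whose :meth:`~RelativeRiskModel.fit`
returns a :class:`RelativeRiskResult` carrying the fitted surfaces, the
bandwidths used, the significant regions, and evaluation helpers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr
from shapely.geometry import Polygon, mapping
from skimage import measure

from .bandwidth import BandwidthSpec, select_bandwidths
from .density import (
    DensitySurface,
    adaptive_bandwidths,
    adaptive_kde,
    fixed_kde,
    kde_at_points,
)
from .grids import RasterGrid, Window
from .patterns import PointPattern

__all__ = [
    "plugin_z",
    "RelativeRiskModel",
    "RelativeRiskResult",
    "log_relative_risk",
    "asymptotic_z",
    "tolerance_contours",
]

#: Roughness R(K) of the bivariate standard Gaussian kernel.
RK_GAUSSIAN = 1.0 / (4.0 * np.pi)

#: Densities are floored at this value (per m^2) before the ratio; cells
#: where both densities sit at the floor are masked from testing.
DENSITY_FLOOR = 1e-12

ONE_SIDED_Z_095 = 1.6448536269514722  # standard-normal 0.95 quantile


def log_relative_risk(f_surface: DensitySurface, g_surface: DensitySurface,
                      floor: float = DENSITY_FLOOR) -> RasterGrid:
    """Cellwise log ratio of case to control density surfaces.

    Both densities are floored at ``floor`` before division. The surfaces
    must share the same grid.
    """
    fg, gg = f_surface.grid, g_surface.grid
    if fg.shape != gg.shape or fg.window != gg.window or fg.cell_size != gg.cell_size:
        raise ValueError("case and control surfaces are on different grids")
    f = np.maximum(f_surface.values, floor)
    g = np.maximum(g_surface.values, floor)
    return fg.like(np.log(f) - np.log(g))


def _adaptive_h_surface(pilot: DensitySurface, per_point_h: np.ndarray,
                        pilot_at_points: np.ndarray, h0: float,
                        floor: float = 1e-12) -> np.ndarray:
    """Local bandwidth surface h(x) = h0 * pilot(x)^(-1/2) / gamma.

    Extends the Abramson per-point rule to all grid cells using the same
    geometric-mean normaliser gamma as the data points, so that
    h(X_i) = h_i at the observations. Plugging this h(x) into the
    asymptotic variance makes the variance of the log density nearly
    constant in space — the variance stabilisation that motivates the
    adaptive estimator.
    """
    inv_root = np.maximum(pilot_at_points, floor) ** -0.5
    log_gamma = float(np.mean(np.log(inv_root)))
    f = np.maximum(pilot.values, floor)
    return h0 * f ** -0.5 * np.exp(-log_gamma)


def asymptotic_z(log_rr: RasterGrid, f_surface: DensitySurface,
                 g_surface: DensitySurface, n_f: int, n_g: int,
                 h_f, h_g, floor: float = DENSITY_FLOOR) -> RasterGrid:
    """Pointwise z statistic of the log relative risk.

    ``h_f`` and ``h_g`` are the bandwidth surfaces (scalars for the fixed
    estimator, arrays of the grid shape for the adaptive one) entering the
    plug-in asymptotic variance. Cells where both densities sit at the
    evaluation floor are masked (NaN).
    """
    f = np.maximum(f_surface.values, floor)
    g = np.maximum(g_surface.values, floor)
    h_f = np.broadcast_to(np.asarray(h_f, dtype=float), f.shape)
    h_g = np.broadcast_to(np.asarray(h_g, dtype=float), g.shape)
    var = RK_GAUSSIAN * (1.0 / (n_f * h_f ** 2 * f) + 1.0 / (n_g * h_g ** 2 * g))
    z = log_rr.values / np.sqrt(var)
    both_floored = (f_surface.values <= floor) & (g_surface.values <= floor)
    z = np.where(both_floored, np.nan, z)
    return log_rr.like(z)


def plugin_z(log_rr: RasterGrid, f_surface: DensitySurface,
             g_surface: DensitySurface,
             floor: float = DENSITY_FLOOR) -> RasterGrid:
    """z statistic with the finite-sample plug-in variance of the log ratio.

    Uses Var(log f_hat) ~ Var(f_hat)/f_hat^2 with the kernel
    second-moment variance carried by each :class:`DensitySurface`. This
    agrees with the asymptotic form R(K)/(n h^2 f) wherever the data are
    dense, but remains honest in sparse fringes where a cell's estimate
    rests on one or two kernels and the asymptotic variance would be
    grossly optimistic. Cells that no kernel reaches are masked (NaN).
    """
    if f_surface.variance is None or g_surface.variance is None:
        raise ValueError("density surfaces carry no variance estimates")
    f = np.maximum(f_surface.values, floor)
    g = np.maximum(g_surface.values, floor)
    var = f_surface.variance / f ** 2 + g_surface.variance / g ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        z = log_rr.values / np.sqrt(var)
    untouched = (f_surface.values <= floor) & (g_surface.values <= floor)
    z = np.where(untouched | (var <= 0), np.nan, z)
    return log_rr.like(z)


def _assemble_polygons(rings: list[np.ndarray]) -> list[Polygon]:
    """Nest closed marching-squares rings into shells with holes.

    A ring contained in an odd number of other rings is a hole of its
    smallest enclosing shell; even-depth rings are shells.
    """
    polys = []
    for ring in rings:
        if len(ring) >= 4:
            p = Polygon(ring)
            if p.is_valid and p.area > 0:
                polys.append(p)
            elif not p.is_valid:
                p = p.buffer(0)
                if p.area > 0:
                    polys.append(p)
    if not polys:
        return []
    order = np.argsort([-p.area for p in polys])
    polys = [polys[i] for i in order]
    depth = np.zeros(len(polys), dtype=int)
    parent = np.full(len(polys), -1)
    for i in range(len(polys)):
        for j in range(i):  # polys[j] is larger
            if polys[j].contains(polys[i].representative_point()):
                depth[i] += 1
                parent[i] = j if parent[i] < 0 or polys[parent[i]].area > polys[j].area else parent[i]
    shells = {}
    for i, p in enumerate(polys):
        if depth[i] % 2 == 0:
            shells[i] = [p, []]
    for i, p in enumerate(polys):
        if depth[i] % 2 == 1:
            # attach to the smallest enclosing even-depth ring
            enclosing = [j for j in shells if polys[j].contains(p.representative_point())]
            if enclosing:
                host = min(enclosing, key=lambda j: polys[j].area)
                shells[host][1].append(p.exterior)
    out = []
    for shell, holes in shells.values():
        poly = Polygon(shell.exterior, holes)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.area > 0:
            out.append(poly)
    return out


def tolerance_contours(p_raster: RasterGrid, alpha: float) -> list[Polygon]:
    """Iso-lines of the p-value surface at level ``alpha`` as polygons.

    Contours are extracted by marching squares on the cell-centre p
    raster, padded with p = 1 so every contour closes; the polygons
    enclose the significant (p < alpha) area, with non-significant
    islands represented as holes. ``alpha >= 1`` is a degenerate sentinel
    returning the whole window.
    """
    if not 0 < alpha:
        raise ValueError("alpha must be positive")
    if alpha >= 1.0:
        return [p_raster.window.as_polygon()]
    padded = np.pad(np.nan_to_num(p_raster.values, nan=1.0), 1, constant_values=1.0)
    rings = measure.find_contours(padded, alpha)
    w, d = p_raster.window, p_raster.cell_size
    xy_rings = []
    for ring in rings:
        x = w.xmin + (ring[:, 1] - 0.5) * d
        y = w.ymax - (ring[:, 0] - 0.5) * d
        x = np.clip(x, w.xmin, w.xmax)
        y = np.clip(y, w.ymin, w.ymax)
        xy_rings.append(np.column_stack([x, y]))
    return _assemble_polygons(xy_rings)


class RelativeRiskModel:
    """Kernel estimator of the spatial relative risk function.

    Parameters
    ----------
    cases, controls : PointPattern
        Case and control locations sharing one observation window.
    estimator : {"fixed", "adaptive"}
        Fixed bandwidth (one h for all points, oversmoothing selection on
        the pooled pattern) or adaptive Abramson bandwidths (LSCV pilots
        per pattern, oversmoothing global bandwidth with geometric-mean
        effective sample size).
    cell_size : float, optional
        Analysis grid resolution in metres (default: window width / 100).
    grid : RasterGrid, optional
        Explicit analysis grid; overrides ``cell_size``.
    bandwidths : BandwidthSpec, optional
        Pre-selected bandwidths; selected from the data when omitted.
    scenario : str
        Sensitivity scenario scaling ("none", "S1".."S4") applied to the
        selected or supplied bandwidths.
    alpha : float
        One-sided significance level for the tolerance contours.
    edge_correction : bool
        Apply Diggle's boundary correction (per-point bandwidth for the
        adaptive estimator).
    variance : {"plugin", "asymptotic"}
        Variance entering the z statistic: the finite-sample kernel
        second-moment plug-in (default) or the purely asymptotic
        R(K)/(n h(x)^2 f_hat(x)) form with local bandwidth surfaces.

    Examples
    --------
    >>> model = RelativeRiskModel(cases, controls, estimator="adaptive")
    >>> result = model.fit()
    >>> print(result.summary())
    """

    def __init__(self, cases: PointPattern, controls: PointPattern,
                 estimator: str = "adaptive", cell_size: float | None = None,
                 grid: RasterGrid | None = None,
                 bandwidths: BandwidthSpec | None = None,
                 scenario: str = "none", alpha: float = 0.05,
                 edge_correction: bool = True, variance: str = "plugin",
                 density_floor: float = DENSITY_FLOOR):
        if cases.window != controls.window:
            raise ValueError("cases and controls must share one window")
        if estimator not in ("fixed", "adaptive"):
            raise ValueError("estimator must be 'fixed' or 'adaptive'")
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.cases = cases
        self.controls = controls
        self.estimator = estimator
        self.window = cases.window
        if grid is None:
            if cell_size is None:
                cell_size = self.window.width / 100.0
            grid = RasterGrid.full(self.window, cell_size)
        self.grid = grid
        self.bandwidths = bandwidths
        self.scenario = scenario
        self.alpha = alpha
        self.edge_correction = "diggle" if edge_correction else "none"
        if variance not in ("plugin", "asymptotic"):
            raise ValueError("variance must be 'plugin' or 'asymptotic'")
        self.variance = variance
        self.density_floor = density_floor

    @classmethod
    def from_dataframe(cls, df, x: str = "x", y: str = "y",
                       label: str = "label", case_label: str = "case",
                       control_label: str = "control",
                       window: Window | None = None, **kwargs) -> "RelativeRiskModel":
        """Build a model from a long DataFrame of labelled coordinates."""
        coords = df[[x, y]].to_numpy(dtype=float)
        if window is None:
            window = Window(coords[:, 0].min(), coords[:, 1].min(),
                            coords[:, 0].max(), coords[:, 1].max())
        cases = PointPattern(df.loc[df[label] == case_label, [x, y]].to_numpy(float),
                             window, "case")
        controls = PointPattern(df.loc[df[label] == control_label, [x, y]].to_numpy(float),
                                window, "control")
        return cls(cases, controls, **kwargs)

    def fit(self) -> "RelativeRiskResult":
        """Estimate the surfaces and extract significant regions."""
        from .bandwidth import scale_bandwidths

        spec = self.bandwidths
        if spec is None:
            spec = select_bandwidths(self.cases, self.controls)
        if self.scenario != "none" and spec.scenario != self.scenario:
            spec = scale_bandwidths(spec, self.scenario)

        n_f, n_g = self.cases.n, self.controls.n
        if self.estimator == "fixed":
            f = fixed_kde(self.cases, spec.h_fixed, self.grid, self.edge_correction)
            g = fixed_kde(self.controls, spec.h_fixed, self.grid, self.edge_correction)
            h_f_surf = spec.h_fixed
            h_g_surf = spec.h_fixed
        else:
            # pilot densities: exact at the data points (bandwidths can be
            # far below the grid resolution), gridded for the h(x) surface
            pf_at = kde_at_points(self.cases, spec.h_pilot_f, self.cases.coords,
                                  edge_correction=self.edge_correction)
            pg_at = kde_at_points(self.controls, spec.h_pilot_g,
                                  self.controls.coords,
                                  edge_correction=self.edge_correction)
            h_i_f = adaptive_bandwidths(self.cases, pf_at, spec.h0_global)
            h_i_g = adaptive_bandwidths(self.controls, pg_at, spec.h0_global)
            f = adaptive_kde(self.cases, h_i_f, self.grid, self.edge_correction)
            g = adaptive_kde(self.controls, h_i_g, self.grid, self.edge_correction)
            f.bandwidths = spec
            g.bandwidths = spec
            pilot_f = fixed_kde(self.cases, spec.h_pilot_f, self.grid,
                                self.edge_correction)
            pilot_g = fixed_kde(self.controls, spec.h_pilot_g, self.grid,
                                self.edge_correction)
            h_f_surf = _adaptive_h_surface(pilot_f, h_i_f, pf_at, spec.h0_global)
            h_g_surf = _adaptive_h_surface(pilot_g, h_i_g, pg_at, spec.h0_global)

        log_rr = log_relative_risk(f, g, self.density_floor)
        if self.variance == "plugin":
            z = plugin_z(log_rr, f, g, self.density_floor)
        else:
            z = asymptotic_z(log_rr, f, g, n_f, n_g, h_f_surf, h_g_surf,
                             self.density_floor)
        p_vals = np.where(np.isnan(z.values), 1.0, 1.0 - ndtr(z.values))
        p = self.grid.like(p_vals)
        sig_mask = self.grid.like((p_vals < self.alpha).astype(float))
        regions = tolerance_contours(p, self.alpha)
        return RelativeRiskResult(
            model=self, bandwidths=spec, f_surface=f, g_surface=g,
            log_rr=log_rr, z=z, p=p, alpha=self.alpha,
            significant_mask=sig_mask, significant_regions=regions,
            masked_cells=int(np.isnan(z.values).sum()),
        )


@dataclass
class RelativeRiskResult:
    """Fitted relative-risk surfaces with significance information."""

    model: RelativeRiskModel
    bandwidths: BandwidthSpec
    f_surface: DensitySurface
    g_surface: DensitySurface
    log_rr: RasterGrid
    z: RasterGrid
    p: RasterGrid
    alpha: float
    significant_mask: RasterGrid      # 1.0 where p < alpha
    significant_regions: list = field(default_factory=list)
    masked_cells: int = 0

    @property
    def estimator(self) -> str:
        return self.model.estimator

    @property
    def scenario(self) -> str:
        return self.bandwidths.scenario

    def significant_area(self) -> float:
        """Area (m^2) of the significantly elevated region."""
        return float(self.significant_mask.values.sum()
                     * self.significant_mask.cell_area)

    def evaluate(self, risk_mask) -> "ConfusionAreas":
        """Score the significant region against a known risk-area mask."""
        from .evaluation import overlay_confusion

        return overlay_confusion(self.significant_mask, risk_mask,
                                 estimator=self.estimator,
                                 scenario=self.scenario)

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        b = self.bandwidths
        w = self.model.window
        lines = [
            "Spatial relative risk function",
            "=" * 46,
            f"estimator:        {self.estimator} (scenario {self.scenario})",
            f"cases / controls: {self.f_surface.pattern_n} / {self.g_surface.pattern_n}",
            f"window:           {w.width:.0f} m x {w.height:.0f} m",
            f"grid:             {self.log_rr.shape[0]} x {self.log_rr.shape[1]} "
            f"@ {self.log_rr.cell_size:.0f} m",
            f"h fixed (OS):     {b.h_fixed:10.2f} m",
            f"h0 global (OS'):  {b.h0_global:10.2f} m",
            f"pilot h (cases):  {b.h_pilot_f:10.2f} m",
            f"pilot h (ctrls):  {b.h_pilot_g:10.2f} m",
            f"log RR range:     [{np.nanmin(self.log_rr.values):.3f}, "
            f"{np.nanmax(self.log_rr.values):.3f}]",
            f"alpha (1-sided):  {self.alpha}",
            f"significant area: {self.significant_area() / 1e6:.2f} km^2 "
            f"({100 * self.significant_area() / w.area:.1f}% of window)",
            f"masked cells:     {self.masked_cells}",
        ]
        return "\n".join(lines)

    def regions_geojson(self, path=None, **properties) -> dict:
        """Significant regions as a GeoJSON FeatureCollection."""
        feats = [
            {
                "type": "Feature",
                "geometry": mapping(poly),
                "properties": {"alpha": self.alpha, "estimator": self.estimator,
                               "scenario": self.scenario, **properties},
            }
            for poly in self.significant_regions
        ]
        fc = {"type": "FeatureCollection", "features": feats}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(fc, fh)
        return fc

    def plot(self, ax=None, show_contours: bool = True, risk_mask=None):
        """Map of the log relative-risk surface with tolerance contours."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        w = self.model.window
        extent = (w.xmin, w.xmax, w.ymin, w.ymax)
        vmax = np.nanmax(np.abs(self.log_rr.values))
        im = ax.imshow(self.log_rr.values, extent=extent, origin="upper",
                       cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        plt.colorbar(im, ax=ax, label="log relative risk")
        if show_contours:
            for poly in self.significant_regions:
                xs, ys = poly.exterior.xy
                ax.plot(xs, ys, color="black", lw=1.2)
        if risk_mask is not None:
            vals = getattr(risk_mask, "mask", risk_mask)
            grid = vals if isinstance(vals, RasterGrid) else risk_mask
            ax.contour(grid.values, levels=[0.5], colors="purple",
                       linestyles="dotted",
                       extent=extent, origin="upper")
        ax.set_xlabel("x [m]")
        ax.set_ylabel("y [m]")
        ax.set_title(f"{self.estimator} sRRF, alpha={self.alpha}")
        return ax
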
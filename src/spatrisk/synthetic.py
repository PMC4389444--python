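"""Synthetic study regions with dasymetric population bias.

The generator emulates a study design in which "true risk areas" are not
planted as excess disease risk but arise from a *population denominator
error*: a fine population grid is produced by dasymetric disaggregation
of community-level counts proportionally to a surface-sealing
(imperviousness) raster. Because sealing alone ignores building height,
this is known to grossly underestimate residents in urban centres and
overestimate them in rural surroundings. Census tracts whose estimated
count falls short of their true count by more than a threshold (relative
error below -50% by default) are declared true risk areas and buffered
for smoother borders.

Controls are then sampled proportionally from the *biased* grid while
cases are sampled from the *true* population surface (constant
individual risk), so the case/control density ratio is genuinely
elevated exactly where the population was underestimated.

The synthetic truth adds an explicit building-height multiplier raster
(>= 1 in urban cores) that the disaggregation deliberately ignores —
this is the single bias source, and it makes the true tract populations
available exactly, which a real study must approximate with reference
census data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .grids import RasterGrid, Window
from .patterns import PointPattern

__all__ = [
    "RegionConfig",
    "PolygonLayer",
    "BiasedGrid",
    "RiskAreaMask",
    "StudyRegion",
    "SyntheticStudy",
    "rasterize_ids",
    "disaggregate_population",
    "make_true_population",
    "relative_error",
    "derive_risk_areas",
    "sample_point_pattern",
    "generate_study",
]


@dataclass
class RegionConfig:
    """Parameters of the synthetic study region.

    Defaults give a 20 km x 20 km window with a 6 x 6 community grid
    (each split into 3 x 3 census tracts), three circular urban cores of
    high sealing and building-height factor 3-6 on a low-sealing rural
    background, a 20 m population grid, and a 200 m analysis grid.
    """

    window_size: float = 20_000.0          # m, square window
    pop_cell_size: float = 20.0            # m, population grid
    analysis_cell_size: float = 200.0      # m, KDE / overlay grid
    n_communities: int = 6                 # per axis -> 36 communities
    n_tracts: int = 3                      # per axis per community -> 324 tracts
    n_cores: int = 6
    core_radius: tuple[float, float] = (450.0, 550.0)     # m, high-rise core
    core_sealing: float = 80.0             # % in the core
    sprawl_radius: tuple[float, float] = (1150.0, 1400.0)  # m, low-rise belt
    sprawl_sealing: float = 55.0           # % in the sprawl belt
    rural_sealing: tuple[float, float] = (6.0, 10.0)      # % uniform background
    height_peak: tuple[float, float] = (7.0, 9.0)         # multiplier in the core
    core_jitter: float = 150.0             # m around the community centre
    total_population: float = 250_000.0    # persons (single age stratum)
    re_threshold: float = -50.0            # % relative error cut for risk areas
    threshold_mode: str = "percent"        # "percent" | "quantile"
    re_quantile: float = 0.75              # used in quantile mode
    buffer_m: float = 500.0
    n_cases: int = 2000
    control_ratio: float = 1.0             # controls per case (1:1 design)


@dataclass
class PolygonLayer:
    """A set of polygons with integer ids and optional counts."""

    ids: np.ndarray
    polygons: list[Polygon]
    counts: np.ndarray | None = None
    parent_ids: np.ndarray | None = None   # e.g. community of each tract

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
            if np.any(self.counts < 0):
                raise ValueError("polygon counts must be non-negative")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class BiasedGrid:
    """Dasymetric population estimate (persons per cell) on the fine grid."""

    estimate: RasterGrid
    cell_size: float = 20.0


@dataclass
class RiskAreaMask:
    """True risk areas derived from the tract relative-error distribution."""

    tract_re: pd.Series                 # RE_b (%) indexed by tract id; NaN = excluded
    selected_tracts: np.ndarray         # tract ids below the threshold
    threshold: float                    # the cut actually applied (%)
    threshold_mode: str
    buffer_m: float
    buffered: Polygon | None            # buffered union of selected tracts
    mask: RasterGrid                    # 1.0 inside risk areas, on the analysis grid

    def area(self) -> float:
        return float(self.mask.values.sum() * self.mask.cell_area)


@dataclass
class StudyRegion:
    """A synthetic study area with known truth.

    ``true_population`` is the unobserved ground truth (sealing x height
    renormalised per community); the dasymetric estimate that a real
    study would work with lives in a companion :class:`BiasedGrid`.
    """

    window: Window
    communities: PolygonLayer
    tracts: PolygonLayer
    sealing: RasterGrid                # % in [0, 100]
    height_factor: RasterGrid          # >= 1
    true_population: RasterGrid        # persons per cell
    community_id_raster: np.ndarray    # int, shape of the population grid
    tract_id_raster: np.ndarray

    def tract_table(self, biased: BiasedGrid) -> pd.DataFrame:
        """Per-tract true and estimated counts with relative errors."""
        tid = self.tract_id_raster.ravel()
        n = len(self.tracts)
        y_true = np.bincount(tid, self.true_population.values.ravel(), minlength=n)
        y_hat = np.bincount(tid, biased.estimate.values.ravel(), minlength=n)
        re = relative_error(y_hat, y_true)
        return pd.DataFrame({
            "id": self.tracts.ids,
            "community_id": self.tracts.parent_ids,
            "y_true": y_true,
            "y_hat": y_hat,
            "re_percent": re,
        })


@dataclass
class SyntheticStudy:
    """One realised synthetic study: region, biased grid, risk areas."""

    config: RegionConfig
    seed: int
    region: StudyRegion
    biased: BiasedGrid
    tract_table: pd.DataFrame
    risk_areas: RiskAreaMask
    analysis_grid: RasterGrid

    def tracts_geojson(self, path=None) -> dict:
        """Tract polygons with counts and relative errors as GeoJSON."""
        import json

        from shapely.geometry import mapping

        table = self.tract_table.set_index("id")
        feats = []
        for tid, poly in zip(self.region.tracts.ids, self.region.tracts.polygons):
            row = table.loc[tid]
            re = row["re_percent"]
            feats.append({
                "type": "Feature",
                "geometry": mapping(poly),
                "properties": {
                    "id": int(tid),
                    "y_true": float(row["y_true"]),
                    "y_hat": float(row["y_hat"]),
                    "re_percent": None if np.isnan(re) else float(re),
                },
            })
        fc = {"type": "FeatureCollection", "features": feats}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(fc, fh)
        return fc

    def sample_patterns(self, rng=None, n_cases: int | None = None,
                        control_ratio: float | None = None
                        ) -> tuple[PointPattern, PointPattern]:
        """Draw case and control patterns (cases from the true population,
        controls from the biased estimate — the paper-style design)."""
        if rng is None:
            rng = np.random.default_rng(self.seed + 1)
        n_f = n_cases if n_cases is not None else self.config.n_cases
        ratio = control_ratio if control_ratio is not None else self.config.control_ratio
        n_g = max(1, round(n_f * ratio))
        cases = sample_point_pattern(self.region.true_population, n_f, rng, "case")
        controls = sample_point_pattern(self.biased.estimate, n_g, rng, "control")
        return cases, controls


# ---------------------------------------------------------------------------
# rasterisation helpers

def rasterize_ids(layer: PolygonLayer, grid: RasterGrid) -> np.ndarray:
    """Assign each grid cell (by centre) the id of the polygon containing it.

    Cells outside every polygon get -1.
    """
    X, Y = grid.cell_centers()
    out = np.full(grid.shape, -1, dtype=int)
    xs, ys = grid.x_centers, grid.y_centers
    for pid, poly in zip(layer.ids, layer.polygons):
        minx, miny, maxx, maxy = poly.bounds
        jj = np.flatnonzero((xs >= minx - grid.cell_size) & (xs <= maxx + grid.cell_size))
        ii = np.flatnonzero((ys >= miny - grid.cell_size) & (ys <= maxy + grid.cell_size))
        if not len(jj) or not len(ii):
            continue
        sub = np.ix_(ii, jj)
        inside = shapely.contains_xy(poly, X[sub].ravel(), Y[sub].ravel())
        view = out[sub]
        view[inside.reshape(view.shape)] = pid
        out[sub] = view
    return out


def _grid_partition_ids(window: Window, grid: RasterGrid, nx: int, ny: int) -> np.ndarray:
    """Fast id raster for an axis-aligned nx x ny partition of the window."""
    dx = window.width / nx
    dy = window.height / ny
    ix = np.clip(((grid.x_centers - window.xmin) / dx).astype(int), 0, nx - 1)
    iy = np.clip(((grid.y_centers - window.ymin) / dy).astype(int), 0, ny - 1)
    return (iy[:, None] * nx + ix[None, :])


# ---------------------------------------------------------------------------
# dasymetric disaggregation

def _mass_preserving_spread(weights: RasterGrid, id_raster: np.ndarray,
                            counts: np.ndarray, what: str) -> RasterGrid:
    w = weights.values.ravel()
    ids = id_raster.ravel()
    n = counts.shape[0]
    if np.any(counts < 0):
        raise ValueError(f"negative {what} count")
    totals = np.bincount(ids[ids >= 0], w[ids >= 0], minlength=n)
    bad = np.flatnonzero((totals <= 0) & (counts > 0))
    if bad.size:
        raise ValueError(
            f"{what} {bad[0]} has positive population but zero total weight "
            "(no sealed surface to spread it over)"
        )
    scale = np.divide(counts, totals, out=np.zeros(n), where=totals > 0)
    cell_scale = np.where(ids >= 0, scale[np.clip(ids, 0, n - 1)], 0.0)
    return weights.like((w * cell_scale).reshape(weights.shape))


def disaggregate_population(communities, sealing: RasterGrid,
                            cell_size: float | None = None,
                            id_raster: np.ndarray | None = None) -> BiasedGrid:
    """Dasymetric disaggregation of community counts by sealing alone.

    Each community's count is spread over its cells proportionally to the
    sealing value. This deliberately ignores building height — the bias
    source of the whole study — so urban populations come out too low and
    rural ones too high, while community totals are preserved exactly.
    """
    if id_raster is None:
        id_raster = rasterize_ids(communities, sealing)
    est = _mass_preserving_spread(sealing, id_raster, communities.counts, "community")
    return BiasedGrid(est, cell_size or sealing.cell_size)


def make_true_population(communities, sealing: RasterGrid,
                         height_factor: RasterGrid,
                         cell_size: float | None = None,
                         id_raster: np.ndarray | None = None) -> RasterGrid:
    """Ground-truth population surface: sealing x height, renormalised.

    Cell weights are sealing times the building-height multiplier
    (>= 1), renormalised per community to its count; with height factor
    identically 1 the result equals :func:`disaggregate_population`
    exactly.
    """
    if np.any(height_factor.values < 1.0):
        raise ValueError("height factor must be >= 1 everywhere")
    if id_raster is None:
        id_raster = rasterize_ids(communities, sealing)
    weights = sealing.like(sealing.values * height_factor.values)
    return _mass_preserving_spread(weights, id_raster, communities.counts, "community")


def relative_error(estimated_b, true_b):
    """Percent relative error ((y_hat - y) / y) * 100 of tract counts.

    Tracts with a true count of zero are undefined; they return NaN (with
    a warning) and are excluded from any threshold ranking downstream.
    """
    y_hat = np.asarray(estimated_b, dtype=float)
    y = np.asarray(true_b, dtype=float)
    scalar = y.ndim == 0
    y_hat, y = np.atleast_1d(y_hat), np.atleast_1d(y)
    zero = y == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} tract(s) with zero true population excluded "
            "from the relative-error analysis", stacklevel=2,
        )
    re = np.full(y.shape, np.nan)
    np.divide(y_hat - y, y, out=re, where=~zero)
    re *= 100.0
    return float(re[0]) if scalar else re


# ---------------------------------------------------------------------------
# risk areas

def derive_risk_areas(tracts: PolygonLayer, tract_re, analysis_grid: RasterGrid,
                      threshold: float = -50.0, buffer_m: float = 500.0,
                      mode: str = "percent", quantile: float = 0.75) -> RiskAreaMask:
    """Select, buffer and rasterise the true risk areas.

    Tracts whose relative error lies below the threshold are selected; in
    ``quantile`` mode the threshold is the given quantile of the
    ascending finite relative-error distribution instead of a fixed
    percent. The union of selected tract polygons is buffered (smoother
    borders) and rasterised by cell-centre membership onto the analysis
    grid. NaN relative errors (zero-population tracts) never select.
    """
    re = pd.Series(np.asarray(tract_re, dtype=float), index=tracts.ids)
    if mode == "percent":
        cut = float(threshold)
    elif mode == "quantile":
        cut = float(re.dropna().quantile(quantile))
    else:
        raise ValueError("mode must be 'percent' or 'quantile'")
    selected = re.index[(re < cut).fillna(False)].to_numpy()
    mask = analysis_grid.like(np.zeros(analysis_grid.shape))
    buffered = None
    if selected.size == 0:
        warnings.warn("no tract below the relative-error threshold: "
                      "empty risk-area mask", stacklevel=2)
    else:
        keep = np.isin(tracts.ids, selected)
        union = unary_union([p for p, k in zip(tracts.polygons, keep) if k])
        buffered = union.buffer(buffer_m, quad_segs=32) if buffer_m > 0 else union
        X, Y = analysis_grid.cell_centers()
        inside = shapely.contains_xy(buffered, X.ravel(), Y.ravel())
        mask = analysis_grid.like(inside.reshape(analysis_grid.shape).astype(float))
    return RiskAreaMask(re, selected, cut, mode, buffer_m, buffered, mask)


# ---------------------------------------------------------------------------
# sampling

def sample_point_pattern(weight_raster: RasterGrid, n: int, rng,
                         label: str = "points") -> PointPattern:
    """Draw n points with cell probabilities proportional to a weight raster.

    A cell is chosen (with replacement) with probability proportional to
    its weight and the point is then placed uniformly within the cell, so
    the empirical cell frequencies converge to the normalised weights.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    w = weight_raster.values.ravel()
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero weight raster")
    idx = rng.choice(w.size, size=n, p=w / total)
    rows, cols = np.unravel_index(idx, weight_raster.shape)
    d = weight_raster.cell_size
    win = weight_raster.window
    x = win.xmin + (cols + rng.uniform(size=n)) * d
    y = win.ymax - (rows + rng.uniform(size=n)) * d
    x = np.clip(x, win.xmin, win.xmax)
    y = np.clip(y, win.ymin, win.ymax)
    return PointPattern(np.column_stack([x, y]), win, label)


# ---------------------------------------------------------------------------
# the generator

def _build_partition(window: Window, nx_comm: int, nx_tract: int
                     ) -> tuple[PolygonLayer, PolygonLayer]:
    dxc = window.width / nx_comm
    dyc = window.height / nx_comm
    comm_polys, comm_ids = [], []
    tract_polys, tract_ids, tract_parents = [], [], []
    tid = 0
    for iy in range(nx_comm):
        for ix in range(nx_comm):
            cid = iy * nx_comm + ix
            x0 = window.xmin + ix * dxc
            y0 = window.ymin + iy * dyc
            comm_polys.append(box(x0, y0, x0 + dxc, y0 + dyc))
            comm_ids.append(cid)
            dxt, dyt = dxc / nx_tract, dyc / nx_tract
            for ty in range(nx_tract):
                for tx in range(nx_tract):
                    tract_polys.append(box(x0 + tx * dxt, y0 + ty * dyt,
                                           x0 + (tx + 1) * dxt, y0 + (ty + 1) * dyt))
                    tract_ids.append(tid)
                    tract_parents.append(cid)
                    tid += 1
    communities = PolygonLayer(np.array(comm_ids), comm_polys)
    tracts = PolygonLayer(np.array(tract_ids), tract_polys,
                          parent_ids=np.array(tract_parents))
    return communities, tracts


def generate_study(config: RegionConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate one synthetic study region with known risk areas.

    Deterministic given ``seed``. The steps mirror the study design:
    build sealing and (unobserved) building-height rasters with urban
    cores, distribute a total population to communities in proportion to
    their built volume, derive the true population surface and the
    sealing-only dasymetric estimate, compute tract relative errors,
    select and buffer risk-area tracts, and prepare the analysis grid.
    """
    cfg = config or RegionConfig()
    rng = np.random.default_rng(seed)
    w = Window(0.0, 0.0, cfg.window_size, cfg.window_size)
    communities, tracts = _build_partition(w, cfg.n_communities, cfg.n_tracts)

    pop_grid = RasterGrid.full(w, cfg.pop_cell_size)
    X, Y = pop_grid.cell_centers()

    # Rural background sealing, then two-tier towns: a low-rise sprawl
    # belt (high sealing, single-storey) around a compact high-rise core
    # (high sealing, height factor ~8). Sealing-only disaggregation
    # shifts the core's true population out into the belt and the
    # countryside: core tracts come out deeply underestimated (the risk
    # areas) while sprawl and rural tracts are overestimated.
    sealing_vals = rng.uniform(*cfg.rural_sealing, size=pop_grid.shape)
    height_vals = np.ones(pop_grid.shape)
    dc = cfg.window_size / cfg.n_communities
    nodes = [((i + 0.5) * dc, (j + 0.5) * dc)
             for i in range(cfg.n_communities)
             for j in range(cfg.n_communities)]
    picks = rng.choice(len(nodes), size=min(cfg.n_cores, len(nodes)),
                       replace=False)
    for k in picks:
        cx = nodes[k][0] + rng.uniform(-cfg.core_jitter, cfg.core_jitter)
        cy = nodes[k][1] + rng.uniform(-cfg.core_jitter, cfg.core_jitter)
        r_core = rng.uniform(*cfg.core_radius)
        r_sprawl = rng.uniform(*cfg.sprawl_radius)
        peak = rng.uniform(*cfg.height_peak)
        d2 = (X - cx) ** 2 + (Y - cy) ** 2
        # flat-topped profiles: near-plateau interior, sharp fringe
        p_sprawl = np.clip(1.0 - (d2 / r_sprawl ** 2) ** 4, 0.0, 1.0)
        p_core = np.clip(1.0 - (d2 / r_core ** 2) ** 4, 0.0, 1.0)
        sealing_vals = np.maximum(sealing_vals, cfg.sprawl_sealing * p_sprawl)
        sealing_vals = np.maximum(sealing_vals, cfg.core_sealing * p_core)
        height_vals = np.maximum(height_vals, 1.0 + (peak - 1.0) * p_core)
    sealing = pop_grid.like(np.clip(sealing_vals, 0.0, 100.0))
    height = pop_grid.like(height_vals)

    comm_ids = _grid_partition_ids(w, pop_grid, cfg.n_communities, cfg.n_communities)
    tract_ids_x = _grid_partition_ids(w, pop_grid,
                                      cfg.n_communities * cfg.n_tracts,
                                      cfg.n_communities * cfg.n_tracts)
    # renumber the fine partition to match the nested tract ids
    nxt = cfg.n_communities * cfg.n_tracts
    ix = tract_ids_x % nxt
    iy = tract_ids_x // nxt
    cid = (iy // cfg.n_tracts) * cfg.n_communities + (ix // cfg.n_tracts)
    tid = (cid * cfg.n_tracts ** 2
           + (iy % cfg.n_tracts) * cfg.n_tracts + (ix % cfg.n_tracts))

    # community counts proportional to built volume (sealing x height)
    volume = sealing.values * height.values
    comm_volume = np.bincount(comm_ids.ravel(), volume.ravel(),
                              minlength=len(communities))
    raw = cfg.total_population * comm_volume / comm_volume.sum()
    counts = np.floor(raw)
    remainder = raw - counts
    short = int(round(cfg.total_population - counts.sum()))
    if short > 0:
        counts[np.argsort(-remainder)[:short]] += 1
    communities.counts = counts

    true_pop = make_true_population(communities, sealing, height,
                                    id_raster=comm_ids)
    biased = disaggregate_population(communities, sealing,
                                     cfg.pop_cell_size, id_raster=comm_ids)

    region = StudyRegion(w, communities, tracts, sealing, height, true_pop,
                         comm_ids, tid)
    table = region.tract_table(biased)
    analysis_grid = RasterGrid.full(w, cfg.analysis_cell_size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-population tracts are expected
        risk = derive_risk_areas(tracts, table["re_percent"].to_numpy(),
                                 analysis_grid, cfg.re_threshold, cfg.buffer_m,
                                 cfg.threshold_mode, cfg.re_quantile)
    return SyntheticStudy(cfg, seed, region, biased, table, risk, analysis_grid)
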
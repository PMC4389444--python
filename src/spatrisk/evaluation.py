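"""Area-overlay scoring of detected risk regions and point-pattern diagnostics.

The detected (significant tolerance-contour) region is cross-tabulated
against the known true risk-area mask cell by cell on the analysis
raster, boundary cells being assigned by cell-centre membership. From the
four areas TP, FP, FN, TN follow sensitivity Se = TP/(TP+FN),
specificity Sp = TN/(FP+TN) and the positive likelihood ratio
LR+ = Se/(1-Sp): how many times more likely a significant contour is
inside a true risk area than outside it.

The nearest-neighbour ratio compares the mean distance of each point to
its closest neighbour with the expectation 1/(2*sqrt(lambda)) under
complete spatial randomness (Clark-Evans, uncorrected); < 1 indicates
clustering, > 1 dispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .grids import RasterGrid, Window
from .patterns import PointPattern

__all__ = [
    "ConfusionAreas",
    "NNDiagnostics",
    "overlay_confusion",
    "positive_likelihood_ratio",
    "nn_ratio",
]


@dataclass
class ConfusionAreas:
    """TP/FP/FN/TN areas (m^2) and derived detection scores for one run."""

    tp: float
    fp: float
    fn: float
    tn: float
    estimator: str = ""
    scenario: str = "none"

    @property
    def se(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom > 0 else float("nan")

    @property
    def sp(self) -> float:
        denom = self.fp + self.tn
        return self.tn / denom if denom > 0 else float("nan")

    @property
    def lr_plus(self) -> float:
        return positive_likelihood_ratio(self.se, self.sp)

    def as_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "scenario": self.scenario,
            "tp_m2": self.tp,
            "fp_m2": self.fp,
            "fn_m2": self.fn,
            "tn_m2": self.tn,
            "sensitivity": round(self.se, 2),
            "specificity": round(self.sp, 2),
            "lr_plus": round(self.lr_plus, 2) if math.isfinite(self.lr_plus) else float("inf"),
        }


def _as_bool_values(mask) -> RasterGrid:
    if isinstance(mask, RasterGrid):
        return mask
    # RiskAreaMask-like object
    inner = getattr(mask, "mask", None)
    if isinstance(inner, RasterGrid):
        return inner
    raise TypeError("expected a RasterGrid or an object with a .mask RasterGrid")


def overlay_confusion(significant, risk_mask, window: Window | None = None,
                      estimator: str = "", scenario: str = "none") -> ConfusionAreas:
    """Cross-tabulate detected against true risk areas on the analysis grid.

    Both inputs are boolean-valued rasters (nonzero = member) on the same
    grid. Areas are cell counts times cell area, so
    TP + FP + FN + TN equals the window area to within one cell.
    """
    sig = _as_bool_values(significant)
    truth = _as_bool_values(risk_mask)
    if sig.shape != truth.shape or sig.window != truth.window \
            or sig.cell_size != truth.cell_size:
        raise ValueError("significant and risk-area rasters are on different grids")
    s = sig.values.astype(bool)
    t = truth.values.astype(bool)
    a = sig.cell_area
    return ConfusionAreas(
        tp=float(np.sum(s & t)) * a,
        fp=float(np.sum(s & ~t)) * a,
        fn=float(np.sum(~s & t)) * a,
        tn=float(np.sum(~s & ~t)) * a,
        estimator=estimator,
        scenario=scenario,
    )


def positive_likelihood_ratio(se: float, sp: float) -> float:
    """LR+ = Se / (1 - Sp); infinity when Sp = 1 (no false positives)."""
    if not (0 <= se <= 1):
        raise ValueError("sensitivity must be in [0, 1]")
    if not (0 <= sp <= 1):
        raise ValueError("specificity must be in [0, 1]")
    if sp == 1.0:
        return float("inf")
    return se / (1.0 - sp)


@dataclass
class NNDiagnostics:
    """Nearest-neighbour clustering diagnostic of one point pattern."""

    mean_nn_distance: float
    expected_csr_distance: float

    @property
    def nn_ratio(self) -> float:
        return self.mean_nn_distance / self.expected_csr_distance


def nn_ratio(pattern: PointPattern, window: Window | None = None,
             edge_corrected: bool = False) -> NNDiagnostics:
    """Clark-Evans nearest-neighbour ratio against complete spatial randomness.

    Mean observed nearest-neighbour distance divided by the CSR
    expectation ``1/(2*sqrt(lambda))`` with intensity
    ``lambda = n / area``. By default no edge correction is applied;
    ``edge_corrected=True`` applies the Donnelly boundary-adjusted
    expectation for a rectangular window.
    """
    if pattern.n < 2:
        raise ValueError("nearest-neighbour ratio needs at least 2 points")
    window = window or pattern.window
    dist, _ = cKDTree(pattern.coords).query(pattern.coords, k=2)
    mean_nn = float(dist[:, 1].mean())
    lam = pattern.n / window.area
    expected = 0.5 / math.sqrt(lam)
    if edge_corrected:
        # Donnelly (1978) edge adjustment for rectangular windows
        perimeter = 2.0 * (window.width + window.height)
        n = pattern.n
        expected = (0.5 * math.sqrt(window.area / n)
                    + (0.0514 + 0.041 / math.sqrt(n)) * perimeter / n)
    return NNDiagnostics(mean_nn, expected)
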
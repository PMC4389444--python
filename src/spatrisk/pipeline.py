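"""End-to-end study orchestration: generate, select, estimate, test, score.

One :func:`run_study` call realises the full experiment on a synthetic
study region — generate the region and its true risk areas, sample cases
(from the true population) and controls (from the biased dasymetric
grid), select bandwidths, fit the requested estimators and scenarios,
and score every run against the known risk areas — returning an
:class:`ExperimentReport` with the confusion table, the bandwidth table
and nearest-neighbour diagnostics. Everything is deterministic given the
configured seed; the configuration hash and seeds are embedded in all
outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bandwidth import BandwidthSpec, select_bandwidths
from .evaluation import nn_ratio
from .risk import RelativeRiskModel, RelativeRiskResult
from .synthetic import RegionConfig, SyntheticStudy, generate_study

__all__ = ["ExperimentConfig", "ExperimentReport", "run_study",
           "replicate_summary", "run_replicates"]

_ESTIMATORS = ("fixed", "adaptive")


@dataclass
class ExperimentConfig:
    """Configuration of one study (or a batch of seeded replicates)."""

    region: RegionConfig = field(default_factory=RegionConfig)
    seed: int = 0
    n_cases: int | None = None           # None -> region default
    control_ratio: float | None = None
    estimators: tuple[str, ...] = _ESTIMATORS
    scenarios: tuple[str, ...] = ("none",)
    alpha: float = 0.05
    variance: str = "plugin"
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        ratio = (self.control_ratio if self.control_ratio is not None
                 else self.region.control_ratio)
        if ratio <= 0:
            raise ValueError("control ratio must be positive")
        for est in self.estimators:
            if est not in _ESTIMATORS:
                raise ValueError(f"unknown estimator {est!r}")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["region"] = asdict(self.region)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        region = d.pop("region", {})
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        for key in ("estimators", "scenarios"):
            if key in known and known[key] is not None:
                known[key] = tuple(known[key])
        reg_known = {k: v for k, v in region.items()
                     if k in RegionConfig.__dataclass_fields__}
        for key in ("core_radius", "sprawl_radius", "rural_sealing", "height_peak"):
            if key in reg_known and reg_known[key] is not None:
                reg_known[key] = tuple(reg_known[key])
        return cls(region=RegionConfig(**reg_known), **known)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=True)

    def hash(self) -> str:
        """Configuration fingerprint; excludes the seed so that seeded
        replicates of one configuration share a hash."""
        d = self.to_dict()
        d.pop("seed", None)
        blob = json.dumps(d, sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ExperimentReport:
    """All tabular outputs of one study run."""

    config: ExperimentConfig
    seed: int
    config_hash: str
    confusion: pd.DataFrame       # one row per estimator x scenario
    bandwidths: pd.DataFrame      # Table-1-style row
    diagnostics: pd.DataFrame     # NN ratios per pattern
    risk_area_m2: float
    version: str = __version__

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in (("confusion", self.confusion),
                         ("bandwidths", self.bandwidths),
                         ("diagnostics", self.diagnostics)):
            df.to_csv(out / f"{name}.csv", index=False)
        meta = {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "risk_area_m2": self.risk_area_m2,
            "version": self.version,
            "config": self.config.to_dict(),
        }
        with open(out / "run_metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2, default=float)


def _bandwidth_row(spec: BandwidthSpec, n_f: int, n_g: int) -> dict:
    return {
        "n_f": n_f,
        "n_g": n_g,
        "os_h_pooled": spec.h_fixed,
        "lscv_h_f": spec.h_pilot_f,
        "lscv_h_g": spec.h_pilot_g,
        "os_prime_h_pooled": spec.h0_global,
    }


def run_study(config: ExperimentConfig | None = None, seed: int | None = None,
              out_dir=None, study: SyntheticStudy | None = None,
              keep_results: bool = False) -> ExperimentReport:
    """Run one full study: generate, sample, select, fit, test, score.

    Deterministic given the seed. ``study`` may be passed to reuse an
    already generated region (the seed then only drives sampling). With
    ``keep_results`` the fitted :class:`RelativeRiskResult` objects are
    attached to the report as ``report.results`` keyed by
    (estimator, scenario).
    """
    config = config or ExperimentConfig()
    seed = config.seed if seed is None else seed
    chash = config.hash()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if study is None:
            study = generate_study(config.region, seed=seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        cases, controls = study.sample_patterns(
            rng=rng, n_cases=config.n_cases, control_ratio=config.control_ratio)
        spec = select_bandwidths(cases, controls)

        rows, results = [], {}
        for est in config.estimators:
            for scen in config.scenarios:
                model = RelativeRiskModel(
                    cases, controls, estimator=est, bandwidths=spec,
                    scenario=scen, alpha=config.alpha,
                    variance=config.variance,
                    grid=study.analysis_grid)
                res = model.fit()
                conf = res.evaluate(study.risk_areas)
                row = conf.as_dict()
                row.update(seed=seed, config_hash=chash)
                rows.append(row)
                if keep_results:
                    results[(est, scen)] = res

        diag = pd.DataFrame([
            {"pattern": "cases", "n": cases.n,
             "nn_ratio": nn_ratio(cases).nn_ratio},
            {"pattern": "controls", "n": controls.n,
             "nn_ratio": nn_ratio(controls).nn_ratio},
        ])
    bw = pd.DataFrame([_bandwidth_row(spec, cases.n, controls.n)])
    report = ExperimentReport(
        config=config, seed=seed, config_hash=chash,
        confusion=pd.DataFrame(rows), bandwidths=bw, diagnostics=diag,
        risk_area_m2=study.risk_areas.area(),
    )
    if keep_results:
        report.results = results
    if out_dir is not None:
        report.write(out_dir)
        if keep_results:
            from pathlib import Path
            for (est, scen), res in results.items():
                stem = Path(out_dir) / f"{est}_{scen}"
                res.log_rr.to_ascii(f"{stem}_log_rr.asc")
                res.z.to_ascii(f"{stem}_z.asc")
                res.p.to_ascii(f"{stem}_p.asc")
                res.regions_geojson(f"{stem}_significant.geojson",
                                    config_hash=chash, seed=seed)
    return report


def run_replicates(config: ExperimentConfig,
                   n_replicates: int | None = None) -> list[ExperimentReport]:
    """Run seeded replicates ``seed, seed+1, ...`` of one configuration."""
    n = n_replicates or config.n_replicates
    return [run_study(replace(config, seed=config.seed + k))
            for k in range(n)]


def replicate_summary(reports: list[ExperimentReport]) -> pd.DataFrame:
    """Mean and spread of Se/Sp/LR+ per estimator and scenario.

    Adds the fraction of replicates in which the adaptive estimator's
    sensitivity is at least the fixed estimator's (per scenario, where
    both were run).
    """
    if len(reports) < 2:
        raise ValueError("replicate summary needs at least 2 reports")
    hashes = {r.config_hash for r in reports}
    if len(hashes) > 1:
        raise ValueError("replicates come from heterogeneous configurations")
    conf = pd.concat([r.confusion for r in reports], ignore_index=True)
    num = conf.replace({"lr_plus": {float("inf"): np.nan}})
    grouped = num.groupby(["estimator", "scenario"], sort=False).agg(
        se_mean=("sensitivity", "mean"), se_sd=("sensitivity", "std"),
        sp_mean=("specificity", "mean"), sp_sd=("specificity", "std"),
        lr_plus_mean=("lr_plus", "mean"), lr_plus_sd=("lr_plus", "std"),
        n_replicates=("sensitivity", "size"),
    ).reset_index()
    # fraction of seeds with adaptive Se >= fixed Se, per scenario
    fracs = {}
    for scen, sub in conf.groupby("scenario", sort=False):
        wide = sub.pivot_table(index="seed", columns="estimator",
                               values="sensitivity")
        if {"adaptive", "fixed"} <= set(wide.columns):
            fracs[scen] = float((wide["adaptive"] >= wide["fixed"]).mean())
    grouped["frac_adaptive_se_ge_fixed"] = grouped["scenario"].map(fracs)
    return grouped
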
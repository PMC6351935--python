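"""End-to-end orchestration: networks -> E2SFCA -> SPAR -> shortage ->
spatial statistics, per travel mode, with reproducible file outputs.

A run is described by a :class:`RunConfig`; :func:`run_pipeline` executes
each stage for each requested mode and (optionally) writes CSV reports, a
full-precision JSON results file, and a manifest with the config hash and
per-file checksums.  Two runs with the same config and seed produce
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .e2sfca import (AccessRecord, DecayScheme, accessibility_analysis,
                     shortage_summary)
from .modes import (SpeedMap, build_multimodal_network, build_road_network,
                    build_walk_network, generate_crosswalks)
from .network import TravelNetwork
from .spatial_stats import (MoranResult, OlsFit, SpatialLagFit,
                            build_knn_weights, build_queen_weights,
                            correlation_filter, fit_ols, fit_spatial_lag,
                            morans_i)
from .synth import CityBundle, CityConfig, generate_city

__all__ = ["RunConfig", "ModeResult", "PipelineResult", "build_mode_networks",
           "run_pipeline"]

log = logging.getLogger("spar_access")

MODES = ("drive", "walk", "multimodal")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Input layers come either from a synthetic-city config (``city``) or a
    directory of GeoJSON layers (``layers_dir``); exactly one must be
    set.
    """

    seed: int
    city: Optional[CityConfig] = None
    layers_dir: Optional[str] = None
    modes: List[str] = field(default_factory=lambda: list(MODES))
    scheme: DecayScheme = field(default_factory=DecayScheme)
    speeds: SpeedMap = field(default_factory=SpeedMap)
    snap_max_dist_m: float = 500.0
    link_max_dist_m: float = 100.0
    boarding_penalty_min: float = 0.0
    crosswalk_radius_m: float = 18.0
    weights_type: str = "knn"  # or "queen"
    knn_k: int = 8
    n_perm: int = 999
    alpha: float = 0.05
    corr_cutoff: float = 0.70
    out_dir: Optional[str] = None

    def validate(self) -> None:
        if (self.city is None) == (self.layers_dir is None):
            raise ValueError("exactly one of city / layers_dir must be set")
        if self.layers_dir is not None and not os.path.isdir(self.layers_dir):
            raise ValueError(f"layers_dir does not exist: {self.layers_dir}")
        bad = set(self.modes) - set(MODES)
        if bad:
            raise ValueError(f"unknown modes: {sorted(bad)}")
        if self.weights_type not in ("knn", "queen"):
            raise ValueError(f"unknown weights_type {self.weights_type!r}")


@dataclass
class ModeResult:
    mode: str
    records: List[AccessRecord]
    access_table: pd.DataFrame
    shortage: Dict[str, float]
    moran_spar: MoranResult
    moran_resid: MoranResult
    retained_covariates: List[str]
    ols: OlsFit
    lag: SpatialLagFit
    network_summary: Dict[str, float]


@dataclass
class PipelineResult:
    config: RunConfig
    bundle: CityBundle
    per_mode: Dict[str, ModeResult]
    shortage_table: pd.DataFrame
    output_files: Dict[str, str] = field(default_factory=dict)


def build_mode_networks(bundle: CityBundle, speeds: SpeedMap,
                        modes: List[str],
                        boarding_penalty_min: float = 0.0,
                        link_max_dist_m: float = 100.0,
                        crosswalk_radius_m: float = 18.0,
                        ) -> Dict[str, TravelNetwork]:
    """Build the requested mode networks from a city bundle."""
    nets: Dict[str, TravelNetwork] = {}
    if "drive" in modes:
        nets["drive"] = build_road_network(bundle.roads, speeds)
    if "walk" in modes or "multimodal" in modes:
        crosswalks = generate_crosswalks(bundle.sidewalks, bundle.intersections,
                                         bundle.roads, radius_m=crosswalk_radius_m)
        walk = build_walk_network(bundle.sidewalks, bundle.trails, [],
                                  crosswalks, speeds)
        if "walk" in modes:
            nets["walk"] = walk
        if "multimodal" in modes:
            nets["multimodal"] = build_multimodal_network(
                walk, bundle.transit_layer(), speeds,
                boarding_penalty_min=boarding_penalty_min,
                link_max_dist_m=link_max_dist_m)
    return nets


def _fmt(x) -> str:
    """Fixed 6-significant-digit formatting for stable CSV golden files."""
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _write_csv(df: pd.DataFrame, path: str) -> None:
    df = df.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(_fmt)
    df.to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage for every requested mode; see module docstring."""
    config.validate()
    t0 = time.perf_counter()
    if config.city is not None:
        bundle = generate_city(config.city)
    else:
        from .geojson_io import read_bundle
        bundle = read_bundle(config.layers_dir)
    log.info("layers ready: %d DAs, %d clinics (%.1fs)", len(bundle.das),
             len(bundle.clinics), time.perf_counter() - t0)

    nets = build_mode_networks(
        bundle, config.speeds, config.modes,
        boarding_penalty_min=config.boarding_penalty_min,
        link_max_dist_m=config.link_max_dist_m,
        crosswalk_radius_m=config.crosswalk_radius_m)

    # spatial weights shared by all per-mode statistics
    if config.weights_type == "queen":
        W = build_queen_weights([bundle.da_polygons[p.id] for p in bundle.das])
    else:
        W = build_knn_weights([p.location for p in bundle.das], k=config.knn_k)

    cov = pd.DataFrame([p.covariates for p in bundle.das],
                       index=[p.id for p in bundle.das])
    if cov.isnull().any().any() or cov.empty:
        raise ValueError("stage covariates: DAs carry no covariate table")
    retained = correlation_filter(cov, cutoff=config.corr_cutoff)

    pop_by_id = {p.id: p for p in bundle.das}
    per_mode: Dict[str, ModeResult] = {}
    shortage_rows = []
    for mode in config.modes:
        net = nets[mode]
        stage = f"stage e2sfca[{mode}]"
        t1 = time.perf_counter()
        try:
            records, ratios = accessibility_analysis(
                net, bundle.clinics, bundle.das, config.scheme,
                snap_max_dist_m=config.snap_max_dist_m)
        except ValueError as exc:
            raise RuntimeError(f"{stage}: {exc}") from exc
        spars = np.array([r.spar for r in records])
        shortage = shortage_summary(records, pop_by_id)
        shortage_rows.append({"mode": mode, **shortage})

        y = spars
        X = cov[retained]
        moran_spar = morans_i(y, W, n_perm=config.n_perm, seed=config.seed)
        ols = fit_ols(y, X)
        moran_resid = morans_i(ols.residuals, W, n_perm=config.n_perm,
                               seed=config.seed)
        lag = fit_spatial_lag(y, X, W)

        table = pd.DataFrame({
            "location_id": [r.location_id for r in records],
            "mode": mode,
            "a_index": [r.a_index for r in records],
            "spar": [r.spar for r in records],
            "quantile_class": [r.quantile_class for r in records],
            "population": [pop_by_id[r.location_id].population for r in records],
            "area_km2": [pop_by_id[r.location_id].area_km2 for r in records],
        })
        per_mode[mode] = ModeResult(
            mode=mode, records=records, access_table=table, shortage=shortage,
            moran_spar=moran_spar, moran_resid=moran_resid,
            retained_covariates=retained, ols=ols, lag=lag,
            network_summary={
                "nodes": net.n_nodes(), "edges": net.n_edges(),
                "components": net.n_components(), "total_km": net.total_km(),
            })
        log.info("%s done: %d shortage DAs, Moran %.3f (%.1fs)", stage,
                 int((spars == 0).sum()), moran_spar.i_value,
                 time.perf_counter() - t1)

    shortage_table = pd.DataFrame(shortage_rows)
    result = PipelineResult(config=config, bundle=bundle, per_mode=per_mode,
                            shortage_table=shortage_table)
    if config.out_dir is not None:
        _write_reports(result, config.out_dir)
    return result


def _regression_frame(mr: ModeResult) -> pd.DataFrame:
    rows = []
    for name in mr.lag.coefficients.index:
        rows.append({
            "mode": mr.mode, "variable": name,
            "Estimate": mr.lag.coefficients[name],
            "Std. Error": mr.lag.std_errors[name],
            "z-Value": mr.lag.z_values[name],
            "p-Value": mr.lag.p_values[name],
        })
    return pd.DataFrame(rows)


def _write_reports(result: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    files: Dict[str, str] = {}

    access = pd.concat([mr.access_table for mr in result.per_mode.values()],
                       ignore_index=True)
    files["access"] = os.path.join(out_dir, "access.csv")
    _write_csv(access, files["access"])

    files["shortage"] = os.path.join(out_dir, "shortage.csv")
    _write_csv(result.shortage_table, files["shortage"])

    moran = pd.DataFrame([
        {"mode": mr.mode, "series": which,
         "morans_i": res.i_value, "expected": res.expected,
         "p_value": res.p_perm, "n_perm": res.n_perm}
        for mr in result.per_mode.values()
        for which, res in (("spar", mr.moran_spar), ("ols_residuals", mr.moran_resid))
    ])
    files["moran"] = os.path.join(out_dir, "moran.csv")
    _write_csv(moran, files["moran"])

    reg = pd.concat([_regression_frame(mr) for mr in result.per_mode.values()],
                    ignore_index=True)
    files["regression"] = os.path.join(out_dir, "regression.csv")
    _write_csv(reg, files["regression"])

    footer = pd.DataFrame([
        {"mode": mr.mode, "rho": mr.lag.rho, "rho_se": mr.lag.rho_std_error,
         "LR": mr.lag.lr_stat, "LR_p": mr.lag.lr_p, "AIC": mr.lag.aic,
         "AIC_ols": -2 * mr.ols.log_likelihood + 2 * (len(mr.ols.coefficients) + 1),
         "logLik": mr.lag.log_likelihood}
        for mr in result.per_mode.values()
    ])
    files["regression_summary"] = os.path.join(out_dir, "regression_summary.csv")
    _write_csv(footer, files["regression_summary"])

    # full-precision supplementary report
    report = {
        mode: {
            "shortage": mr.shortage,
            "moran_spar": dataclasses.asdict(mr.moran_spar),
            "moran_residuals": dataclasses.asdict(mr.moran_resid),
            "rho": mr.lag.rho, "lr_stat": mr.lag.lr_stat, "lr_p": mr.lag.lr_p,
            "aic": mr.lag.aic,
            "coefficients": mr.lag.coefficients.to_dict(),
            "retained_covariates": mr.retained_covariates,
            "network": mr.network_summary,
        }
        for mode, mr in result.per_mode.items()
    }
    files["results"] = os.path.join(out_dir, "results.json")
    with open(files["results"], "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")

    cfg = dataclasses.asdict(result.config)
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "seed": result.config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "files": {
            name: {
                "path": os.path.basename(path),
                "sha256": hashlib.sha256(open(path, "rb").read()).hexdigest(),
            }
            for name, path in files.items()
        },
    }
    mpath = os.path.join(out_dir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    files["manifest"] = mpath
    result.output_files = files
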
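"""End-to-end analysis pipeline.

One seeded, configured run performs: data acquisition (synthetic generation
or CSV input) → non-detect resolution → eco-exergy indicators and
aggregates → collinearity screening → gradient-boosted models for both
indicators (eco-exergy and specific eco-exergy) with relative influence and
partial dependence for the top-three predictors → adequacy evaluation on a
held-out split → inverse-distance-weighted annual maps → a machine-readable
manifest.

The modeling unit is the (site, month) row: indicator values are paired
with the same row's abiotic predictors, 396 rows under the default design.
Models are fitted on a seeded 75% split and judged on the held-out 25%.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .boosting import GBMConfig, fit_gbm, partial_dependence, relative_influence
from .censoring import CensoringPolicy, resolve_table
from .errors import ConfigurationError
from .evaluation import AdequacyThresholds, adequacy
from .exergy import BetaTable, ConversionFactors, aggregate, compute_indicators
from .screening import DEFAULT_RETAIN_POLICY, pearson_matrix, select_predictors
from .spatial import GridSpec, idw_grid, write_esri_ascii
from .synthetic import (LakeDesign, apply_censoring, generate_abiotic,
                        generate_plankton, generate_stations, taihu_design,
                        taihu_lods, taihu_response_spec, taihu_variable_specs)

__all__ = ["RunConfig", "run"]

log = logging.getLogger("lakehealth")

TARGETS = ("Ex_kJ_per_L", "Ex_sp_kJ_per_g")


@dataclass
class RunConfig:
    """Full configuration of a pipeline run.

    Exactly one data source: either ``synthetic=True`` (the default Taihu-
    style design) or the three input CSV paths.  ``seed`` drives every
    random stage through documented substreams.
    """

    synthetic: bool = True
    monitoring_csv: str | None = None
    plankton_csv: str | None = None
    stations_csv: str | None = None
    lods: dict = field(default_factory=taihu_lods)
    policy: CensoringPolicy = field(default_factory=CensoringPolicy)
    betas: BetaTable = field(default_factory=BetaTable)
    conversions: ConversionFactors = field(default_factory=ConversionFactors)
    screening_threshold: float = 0.7
    screening_alpha: float = 0.05
    retain_policy: tuple = DEFAULT_RETAIN_POLICY
    exclude_predictors: tuple = ("Chla",)
    gbm: GBMConfig = field(default_factory=GBMConfig)
    thresholds: AdequacyThresholds = field(default_factory=AdequacyThresholds)
    holdout_fraction: float = 0.25
    grid_cell_size: float = 1.0
    noise_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        paths = [self.monitoring_csv, self.plankton_csv, self.stations_csv]
        if self.synthetic and any(paths):
            raise ConfigurationError(
                "configure either synthetic generation or input paths, not both")
        if not self.synthetic:
            if not all(paths):
                raise ConfigurationError(
                    "non-synthetic runs need monitoring, plankton and "
                    "stations CSV paths")
            for p in paths:
                if not Path(p).exists():
                    raise ConfigurationError(f"input file not found: {p}")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ConfigurationError("holdout_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "policy" in kwargs:
            kwargs["policy"] = CensoringPolicy(**kwargs["policy"])
        if "betas" in kwargs:
            kwargs["betas"] = BetaTable(**kwargs["betas"])
        if "conversions" in kwargs:
            kwargs["conversions"] = ConversionFactors(**kwargs["conversions"])
        if "gbm" in kwargs:
            kwargs["gbm"] = GBMConfig(**kwargs["gbm"])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = AdequacyThresholds(**kwargs["thresholds"])
        if "retain_policy" in kwargs:
            kwargs["retain_policy"] = tuple(kwargs["retain_policy"])
        if "exclude_predictors" in kwargs:
            kwargs["exclude_predictors"] = tuple(kwargs["exclude_predictors"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "synthetic": self.synthetic,
            "monitoring_csv": self.monitoring_csv,
            "plankton_csv": self.plankton_csv,
            "stations_csv": self.stations_csv,
            "lods": dict(self.lods),
            "policy": {"drop_threshold": self.policy.drop_threshold,
                       "random_threshold": self.policy.random_threshold},
            "betas": {g: getattr(self.betas, g)
                      for g in ("algae", "protozoa", "rotifera",
                                "cladocera", "copepoda")},
            "conversions": {"f_phy": self.conversions.f_phy,
                            "f_zoo": self.conversions.f_zoo,
                            "detritus_energy": self.conversions.detritus_energy},
            "screening_threshold": self.screening_threshold,
            "screening_alpha": self.screening_alpha,
            "retain_policy": list(self.retain_policy),
            "exclude_predictors": list(self.exclude_predictors),
            "gbm": self.gbm.to_dict(),
            "thresholds": {"nse_min": self.thresholds.nse_min,
                           "rsr_max": self.thresholds.rsr_max,
                           "pbias_abs_max": self.thresholds.pbias_abs_max},
            "holdout_fraction": self.holdout_fraction,
            "grid_cell_size": self.grid_cell_size,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


def _sub_seed(seed: int, salt: int) -> int:
    """Derive a documented 31-bit substream seed from the master seed."""
    return int(np.random.SeedSequence((seed, salt)).generate_state(1)[0] % 2**31)


def _acquire(config: RunConfig):
    if config.synthetic:
        design = taihu_design()
        abiotic = generate_abiotic(design, taihu_variable_specs(), seed=config.seed)
        stations = generate_stations(design, seed=config.seed)
        plankton = generate_plankton(
            abiotic, taihu_response_spec(noise_sd=config.noise_sd),
            seed=config.seed)
        censored = apply_censoring(abiotic, config.lods, seed=config.seed)
        return censored.table, plankton, stations
    monitoring = pd.read_csv(config.monitoring_csv)
    plankton = pd.read_csv(config.plankton_csv)
    stations = pd.read_csv(config.stations_csv)
    return monitoring, plankton, stations


def run(config: RunConfig, out_dir) -> Path:
    """Execute the full pipeline; returns the run directory.

    Any stage failure raises with a stage-labeled error; outputs produced
    by earlier stages are retained in the run directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "outputs": [],
    }

    def _save_df(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False)
        manifest["outputs"].append(name)

    stage = "acquire"
    try:
        monitoring, plankton, stations = _acquire(config)
        manifest["stages"][stage] = {"rows_monitoring": len(monitoring),
                                     "rows_plankton": len(plankton),
                                     "n_stations": len(stations)}
        log.info("acquire: %d monitoring rows, %d plankton rows",
                 len(monitoring), len(plankton))
        _save_df(monitoring, "monitoring_censored.csv")
        _save_df(plankton, "plankton.csv")
        _save_df(stations, "stations.csv")

        stage = "censoring"
        resolved, report = resolve_table(
            monitoring, config.lods, config.policy,
            seed=_sub_seed(config.seed, 1))
        report.to_json(out / "censoring_report.json")
        manifest["outputs"].append("censoring_report.json")
        manifest["stages"][stage] = {
            "dropped": report.dropped,
            "strategies": {e["variable"]: e["strategy"]
                           for e in report.variables},
            "warnings": report.warnings,
        }
        _save_df(resolved, "monitoring_resolved.csv")

        stage = "exergy"
        indicators = compute_indicators(plankton, config.betas,
                                        config.conversions)
        indicators = indicators.merge(
            stations[["site_id", "sub_region"]]
            if "sub_region" in stations.columns else stations[["site_id"]],
            on="site_id", how="left")
        _save_df(indicators, "indicators.csv")
        for col in TARGETS:
            _save_df(aggregate(indicators, "month", col),
                     f"aggregate_monthly_{col}.csv")
            if "sub_region" in indicators.columns:
                _save_df(aggregate(indicators, "sub_region", col),
                         f"aggregate_subregion_{col}.csv")
        manifest["stages"][stage] = {"rows": len(indicators)}

        stage = "screening"
        matrix = pearson_matrix(resolved)
        matrix.r.to_csv(out / "correlation_matrix.csv", index_label="variable")
        manifest["outputs"].append("correlation_matrix.csv")
        predictors = select_predictors(
            matrix, config.retain_policy, config.screening_threshold,
            config.screening_alpha, exclude=config.exclude_predictors)
        with open(out / "predictors.json", "w") as fh:
            json.dump(predictors, fh, indent=2)
        manifest["outputs"].append("predictors.json")
        manifest["stages"][stage] = {"predictors": predictors}
        log.info("screening: %d predictors retained", len(predictors))

        stage = "boosting"
        model_data = indicators.merge(resolved, on=["site_id", "month"],
                                      how="inner")
        n = len(model_data)
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 23)))
        n_test = max(1, int(round(config.holdout_fraction * n)))
        test_idx = np.zeros(n, dtype=bool)
        test_idx[rng.choice(n, size=n_test, replace=False)] = True
        manifest["stages"][stage] = {"n_train": int(n - n_test),
                                     "n_test": int(n_test), "targets": {}}
        for t_i, target in enumerate(TARGETS):
            gbm_cfg = GBMConfig(**{**config.gbm.to_dict(),
                                   "seed": _sub_seed(config.seed, 100 + t_i)})
            X_train = model_data.loc[~test_idx, predictors]
            y_train = model_data.loc[~test_idx, target].to_numpy(dtype=float)
            model = fit_gbm(X_train, y_train, gbm_cfg)
            model.to_json(out / f"model_{target}.json")
            manifest["outputs"].append(f"model_{target}.json")
            pd.DataFrame({
                "iteration": np.arange(1, len(model.train_curve) + 1),
                "train_mse": model.train_curve,
                "cv_mse": model.cv_curve,
            }).to_csv(out / f"error_curves_{target}.csv", index=False)
            manifest["outputs"].append(f"error_curves_{target}.csv")

            infl = relative_influence(model)
            infl.to_csv(out / f"influence_{target}.csv",
                        index_label="predictor")
            manifest["outputs"].append(f"influence_{target}.csv")

            top3 = list(infl.index[:3])
            for v in top3:
                _save_df(partial_dependence(model, X_train, [v]),
                         f"pdp1_{target}_{v}.csv")
            for i in range(3):
                for j in range(i + 1, 3):
                    _save_df(
                        partial_dependence(model, X_train, [top3[i], top3[j]],
                                           grid_size=20),
                        f"pdp2_{target}_{top3[i]}_{top3[j]}.csv")

            stage = "evaluation"
            X_test = model_data.loc[test_idx, predictors]
            y_test = model_data.loc[test_idx, target].to_numpy(dtype=float)
            report = adequacy(y_test, model.predict(X_test), config.thresholds)
            report.to_json(out / f"adequacy_{target}.json")
            manifest["outputs"].append(f"adequacy_{target}.json")
            manifest["stages"]["boosting"]["targets"][target] = {
                "best_iteration": model.best_iteration,
                "top3": top3,
                "adequacy": report.to_dict(),
            }
            log.info("%s: best_iter=%d NSE=%.3f RSR=%.3f PBIAS=%.1f%%",
                     target, model.best_iteration, report.nse, report.rsr,
                     report.pbias_percent)
            stage = "boosting"

        stage = "spatial"
        annual = indicators.groupby("site_id", as_index=False)[
            list(TARGETS)].mean()
        st = stations.merge(annual, on="site_id", how="inner")
        pad = config.grid_cell_size
        grid = GridSpec(st["x"].min() - pad, st["x"].max() + pad,
                        st["y"].min() - pad, st["y"].max() + pad,
                        config.grid_cell_size)
        for target in TARGETS:
            sv = st.rename(columns={target: "value"})[["x", "y", "value"]]
            surface = idw_grid(sv, grid)
            _save_df(surface, f"idw_{target}.csv")
            write_esri_ascii(surface, grid, out / f"idw_{target}.asc")
            manifest["outputs"].append(f"idw_{target}.asc")
        manifest["stages"][stage] = {"grid_cells": len(surface)}
    except Exception as exc:
        try:
            labeled = type(exc)(f"[stage: {stage}] {exc}")
        except Exception:
            labeled = RuntimeError(f"[stage: {stage}] {exc}")
        raise labeled from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
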
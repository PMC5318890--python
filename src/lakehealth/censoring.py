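"""Three-tier handling of below-detection-limit (non-detect) records.

Environmental laboratories report concentrations below the limit of
detection (LOD) as non-detects.  The treatment applied here depends on how
heavily a variable is censored:

* **drop** — variables censored beyond ``drop_threshold`` (default 50%)
  carry too little quantitative information and are excluded outright
  (e.g. nitrite at 92.4% non-detects);
* **random_normal** — moderately censored variables (fraction above
  ``random_threshold``, default 10%) have each non-detect replaced by a
  draw from Normal(LOD/2, LOD/4): about 95% of that distribution's mass
  lies in [0, LOD], and draws outside are clamped to the nearest bound
  (no redrawing), so every imputed value lies in [0, LOD];
* **half_lod** — lightly censored variables get the deterministic LOD/2
  substitute.

The numeric tier thresholds are a policy choice, not a measured quantity;
the defaults classify censoring fractions of 92.4% / 38.9% / 23.0% /
7.6% / 2.5% as drop / random / random / half-LOD / half-LOD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "CensoringPolicy",
    "CensoringReport",
    "validate_lods",
    "classify_variable",
    "substitute_half_lod",
    "impute_random_normal",
    "resolve_table",
]


@dataclass(frozen=True)
class CensoringPolicy:
    """Tier boundaries on the non-detect fraction."""

    drop_threshold: float = 0.50
    random_threshold: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.random_threshold < self.drop_threshold <= 1.0:
            raise ConfigurationError(
                "require 0 < random_threshold < drop_threshold <= 1")


def validate_lods(lods: Mapping[str, float]) -> dict[str, float]:
    """Check that every detection limit is strictly positive."""
    for var, lod in lods.items():
        if not lod > 0:
            raise ConfigurationError(f"LOD for {var!r} must be > 0")
    return dict(lods)


def classify_variable(fraction_nondetect: float,
                      policy: CensoringPolicy | None = None) -> str:
    """Assign a non-detect strategy from the censored fraction.

    Returns one of ``"drop"``, ``"random_normal"``, ``"half_lod"``,
    ``"none"``.
    """
    if policy is None:
        policy = CensoringPolicy()
    f = float(fraction_nondetect)
    if not 0.0 <= f <= 1.0:
        raise ValidationError("fraction_nondetect must be in [0, 1]")
    if f > policy.drop_threshold:
        return "drop"
    if f > policy.random_threshold:
        return "random_normal"
    if f > 0.0:
        return "half_lod"
    return "none"


def substitute_half_lod(record, lod: float) -> float:
    """Deterministic LOD/2 substitute for one flagged non-detect.

    ``record`` may be anything with a truthy ``below_lod`` attribute or
    item, or simply ``True``; passing an unflagged record is a misuse error.
    """
    flagged = record
    if hasattr(record, "below_lod"):
        flagged = record.below_lod
    elif isinstance(record, Mapping):
        flagged = record.get("below_lod", False)
    if not flagged:
        raise ValidationError("record is not flagged below the LOD")
    if not lod > 0:
        raise ConfigurationError("LOD must be > 0")
    return lod / 2.0


def impute_random_normal(lod: float, n: int, seed: int = 0,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` imputed concentrations for non-detects under one LOD.

    Draws come from Normal(LOD/2, LOD/4); negative draws are set to zero and
    draws above the LOD are set to the LOD, clamping each draw once.  The
    symmetric clamping preserves the LOD/2 mean.
    """
    if not lod > 0:
        raise ConfigurationError("LOD must be > 0")
    if n < 1:
        raise ValidationError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
    draws = rng.normal(lod / 2.0, lod / 4.0, int(n))
    return np.clip(draws, 0.0, lod)


@dataclass
class CensoringReport:
    """Per-variable censoring summary and chosen strategies."""

    variables: list[dict] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"variables": self.variables, "dropped": self.dropped,
                "warnings": self.warnings}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def strategy_of(self, variable: str) -> str:
        for entry in self.variables:
            if entry["variable"] == variable:
                return entry["strategy"]
        raise KeyError(variable)


def resolve_table(table: pd.DataFrame, lods: Mapping[str, float],
                  policy: CensoringPolicy | None = None,
                  seed: int = 0) -> tuple[pd.DataFrame, CensoringReport]:
    """Resolve every flagged non-detect in a monitoring table.

    Expects the censored-table convention: NaN values accompanied by a
    boolean ``<var>_below_lod`` column.  Returns a complete table (flag
    columns removed, dropped variables excluded) and a report listing each
    variable's non-detect count, fraction, strategy, and summary means
    before (detects only) and after resolution.

    Imputation draws are made independently per non-detect record in table
    order from a generator seeded by ``seed``, so results are reproducible
    given seed and row order.  A table with no flags is returned unchanged.
    """
    if policy is None:
        policy = CensoringPolicy()
    out = table.copy()
    report = CensoringReport()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 19)))
    n = len(out)

    flag_cols = [c for c in out.columns if c.endswith("_below_lod")]
    flagged_vars = [c[: -len("_below_lod")] for c in flag_cols]
    for var in flagged_vars:
        if var not in out.columns:
            raise ConfigurationError(
                f"flag column for {var!r} without a value column")

    lods = validate_lods(lods)
    all_dropped = True
    for var in flagged_vars:
        flags = out[f"{var}_below_lod"].to_numpy(dtype=bool)
        n_nd = int(flags.sum())
        if n_nd > 0 and var not in lods:
            raise ConfigurationError(f"variable {var!r} flagged but has no LOD")
        fraction = n_nd / n if n else 0.0
        strategy = classify_variable(fraction, policy)
        detects = out.loc[~flags, var].to_numpy(dtype=float)
        mean_detects = float(np.nanmean(detects)) if detects.size else float("nan")
        if strategy == "drop":
            out = out.drop(columns=[var, f"{var}_below_lod"])
            report.dropped.append(var)
            mean_after = float("nan")
        else:
            if strategy == "half_lod":
                out.loc[flags, var] = lods[var] / 2.0
            elif strategy == "random_normal":
                out.loc[flags, var] = impute_random_normal(
                    lods[var], n_nd, rng=rng)
            out = out.drop(columns=[f"{var}_below_lod"])
            mean_after = float(out[var].mean())
            all_dropped = False
        report.variables.append({
            "variable": var,
            "n": n,
            "n_nondetect": n_nd,
            "fraction": fraction,
            "strategy": strategy,
            "lod": lods.get(var),
            "mean_detects_only": mean_detects,
            "mean_after_resolution": mean_after,
        })

    if flagged_vars and all_dropped:
        report.warnings.append(
            "all censored variables exceeded the drop threshold; "
            "no censored predictors remain")
    value_cols = [c for c in out.columns
                  if c not in ("site_id", "sub_region", "month")]
    if out[value_cols].select_dtypes("number").isna().any().any():
        raise ValidationError(
            "missing values remain after resolution; "
            "table contains NaNs without matching below-LOD flags")
    return out, report
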
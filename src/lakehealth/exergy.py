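"""Eco-exergy and specific eco-exergy of a plankton community.

Eco-exergy measures the work energy stored in an ecosystem's biomass plus
the information embedded in its organisms' genomes, relative to a detritus
baseline.  For a plankton sample with wet-weight biomasses C (mg/L),

    Ex [J/L] = 18.7 * ( beta_alg * f_phy * sum C_phy
                        + f_zoo * (beta_pro * sum C_pro
                                   + beta_rot * sum C_rot
                                   + beta_cla * sum C_cla
                                   + beta_cop * sum C_cop) )

where 18.7 kJ/g is the chemical exergy of detritus (18.7 J/mg with C in
mg/L), f_phy = 0.16 and f_zoo = 0.06 convert wet weight to the reference
dry/C biomass, and the dimensionless beta weights (algae 20, protozoa 39,
rotifers 163, cladocerans 232, copepods 232) express genetic information
content relative to detritus (beta = 1).

Specific (structural) eco-exergy is eco-exergy per unit total converted
biomass,

    Ex_sp [kJ/g] = Ex / C_total,   C_total = f_phy * sum C_phy + f_zoo * sum C_zoo,

i.e. 18.7 times the biomass-weighted mean beta: it rises when more highly
developed organisms dominate, and falls toward the algal floor
(20 * 18.7 = 374 kJ/g) under bloom conditions — which is why the pair
(high Ex, low Ex_sp) signals eutrophication.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedIndicatorError, ValidationError
from .synthetic import GROUPS, ZOO_GROUPS

__all__ = [
    "BetaTable",
    "ConversionFactors",
    "DEFAULT_BETAS",
    "DEFAULT_CONVERSIONS",
    "DETRITUS_ENERGY_KJ_PER_G",
    "eco_exergy_density",
    "specific_eco_exergy",
    "compute_indicators",
    "aggregate",
]

DETRITUS_ENERGY_KJ_PER_G = 18.7


@dataclass(frozen=True)
class BetaTable:
    """Genetic-information weighting factors per taxon group (detritus = 1)."""

    algae: float = 20.0
    protozoa: float = 39.0
    rotifera: float = 163.0
    cladocera: float = 232.0
    copepoda: float = 232.0

    def __post_init__(self) -> None:
        for g in GROUPS:
            if getattr(self, g) < 1.0:
                raise ConfigurationError(
                    f"beta for {g} must be >= 1 (detritus baseline)")

    def __getitem__(self, group: str) -> float:
        if group not in GROUPS:
            raise ValidationError(f"unknown taxon group {group!r}")
        return getattr(self, group)


@dataclass(frozen=True)
class ConversionFactors:
    """Wet weight → reference (dry/C) biomass factors and detritus energy.

    The conversion factors are treated as a single wet-to-reference-biomass
    scaling; the literature uses "dry weight" and "C-biomass" loosely for
    these empirical constants, and the choice rescales both indicators
    systematically without affecting any statistical conclusion.
    """

    f_phy: float = 0.16
    f_zoo: float = 0.06
    detritus_energy: float = DETRITUS_ENERGY_KJ_PER_G  # kJ/g == J/mg

    def __post_init__(self) -> None:
        if not (0.0 < self.f_phy <= 1.0 and 0.0 < self.f_zoo <= 1.0):
            raise ConfigurationError("conversion factors must be in (0, 1]")
        if self.detritus_energy <= 0:
            raise ConfigurationError("detritus energy must be positive")

    def factor(self, group: str) -> float:
        if group == "algae":
            return self.f_phy
        if group in ZOO_GROUPS:
            return self.f_zoo
        raise ValidationError(f"unknown taxon group {group!r}")


DEFAULT_BETAS = BetaTable()
DEFAULT_CONVERSIONS = ConversionFactors()


def _group_sums(sample: pd.DataFrame) -> pd.Series:
    """Sum wet biomass per taxon group, validating groups and signs."""
    if len(sample) == 0:
        return pd.Series(dtype=float)
    bio = sample["wet_biomass_mg_per_L"].to_numpy(dtype=float)
    if np.isnan(bio).any() or (bio < 0).any():
        raise ValidationError("biomass must be non-negative and non-missing")
    unknown = set(sample["group"]) - set(GROUPS)
    if unknown:
        raise ValidationError(f"unknown taxon groups: {sorted(unknown)}")
    return sample.groupby("group")["wet_biomass_mg_per_L"].sum()


def _converted_biomass(sums: pd.Series, conv: ConversionFactors) -> float:
    return float(sum(conv.factor(g) * b for g, b in sums.items()))


def eco_exergy_density(sample: pd.DataFrame,
                       betas: BetaTable = DEFAULT_BETAS,
                       conv: ConversionFactors = DEFAULT_CONVERSIONS) -> float:
    """Eco-exergy density of one sample, in J/L.

    ``sample`` is a long table with ``group`` and ``wet_biomass_mg_per_L``
    columns (one row per taxon).  An empty sample has zero eco-exergy.
    """
    sums = _group_sums(sample)
    ex = sum(betas[g] * conv.factor(g) * b for g, b in sums.items())
    return conv.detritus_energy * float(ex)


def specific_eco_exergy(sample: pd.DataFrame,
                        betas: BetaTable = DEFAULT_BETAS,
                        conv: ConversionFactors = DEFAULT_CONVERSIONS) -> float:
    """Specific eco-exergy of one sample, in kJ/g of converted biomass.

    Undefined (raises) for a zero-biomass community — the indicator is a
    ratio and a silent 0 or infinity would corrupt aggregates.
    """
    sums = _group_sums(sample)
    c_total = _converted_biomass(sums, conv)
    if c_total <= 0.0:
        raise UndefinedIndicatorError(
            "specific eco-exergy is undefined for zero total biomass")
    return eco_exergy_density(sample, betas, conv) / c_total


def compute_indicators(plankton: pd.DataFrame,
                       betas: BetaTable = DEFAULT_BETAS,
                       conv: ConversionFactors = DEFAULT_CONVERSIONS) -> pd.DataFrame:
    """Per-(site, month) indicator table from a long plankton table.

    Returns columns ``site_id, month, Ex_kJ_per_L, Ex_sp_kJ_per_g,
    C_total_mg_per_L``.  Samples with zero total biomass get NaN specific
    eco-exergy (flagged, not silently zero) — they cannot occur with the
    synthetic generator, whose biomasses are strictly positive.
    """
    rows = []
    for (site, month), sample in plankton.groupby(["site_id", "month"], sort=True):
        sums = _group_sums(sample)
        ex = eco_exergy_density(sample, betas, conv)
        c_total = _converted_biomass(sums, conv)
        rows.append({
            "site_id": site,
            "month": month,
            "Ex_kJ_per_L": ex / 1000.0,
            "Ex_sp_kJ_per_g": ex / c_total if c_total > 0 else np.nan,
            "C_total_mg_per_L": c_total,
        })
    return pd.DataFrame(rows)


def aggregate(values: pd.DataFrame, by: str | list[str], column: str,
              lower: float = 2.5, upper: float = 97.5) -> pd.DataFrame:
    """Group means with percentile uncertainty bands across members.

    ``by`` is typically ``"month"`` or ``"sub_region"``.  The band is the
    [lower, upper] percentile of the member (site, month) values — a
    single-member group returns a degenerate band.  Empty groups (possible
    with pre-defined categoricals) are skipped with a warning.
    """
    import warnings

    out = []
    for key, grp in values.groupby(by, sort=True, observed=False):
        vals = grp[column].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"group {key!r} is empty; skipped")
            continue
        row = {}
        if isinstance(by, str):
            row[by] = key
        else:
            row.update(dict(zip(by, key)))
        row.update({
            "mean": float(vals.mean()),
            "lower": float(np.percentile(vals, lower)),
            "upper": float(np.percentile(vals, upper)),
            "n": int(vals.size),
        })
        out.append(row)
    return pd.DataFrame(out)
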
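"""Collinearity screening of candidate predictors.

Strongly correlated predictor pairs (|R| above a threshold, significant at
a two-tailed level) carry redundant information and destabilize variable-
importance attribution in boosted trees, so one member of each pair is
removed before modeling.  Which member survives is governed by an ordered
preference list; the default prefers dissolved nutrient fractions over the
totals that contain them and water temperature over dissolved oxygen (whose
seasonal signal temperature already carries).

Chlorophyll-a is excluded from the default candidate set: it is a proxy for
the phytoplankton biomass from which the eco-exergy indicators themselves
are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError

__all__ = [
    "CorrelationMatrix",
    "DEFAULT_RETAIN_POLICY",
    "pearson_matrix",
    "strong_pairs",
    "select_predictors",
    "load_taihu_correlations",
]

#: Survivor preference when a strong pair must lose a member: dissolved
#: fractions over totals, temperature over oxygen.  Variables earlier in
#: the list win.
DEFAULT_RETAIN_POLICY: tuple[str, ...] = (
    "NH4-N", "NO3-N", "PO4-P", "WTEMP", "TSS", "pH", "WIND", "SOLR",
    "WD", "SDD", "PREC", "NOISE", "DO", "TN", "TP", "DTP", "NO2-N",
)


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson R with two-tailed p-values at a common n."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    @property
    def variables(self) -> list[str]:
        return list(self.r.columns)


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p-value of Pearson R via the exact t transform,
    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return p


def pearson_matrix(table: pd.DataFrame,
                   variables: Sequence[str] | None = None) -> CorrelationMatrix:
    """Pearson correlation matrix over complete rows of ``table``.

    Zero-variance variables are excluded with a warning; fewer than three
    complete rows is an error (no degrees of freedom for the t test).
    """
    if variables is None:
        variables = [c for c in table.columns
                     if c not in ("site_id", "sub_region", "month")
                     and not c.endswith("_below_lod")
                     and pd.api.types.is_numeric_dtype(table[c])]
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ConfigurationError(f"variables not in table: {missing}")
    data = table.loc[:, list(variables)].dropna()
    n = len(data)
    if n < 3:
        raise ValidationError("need at least 3 complete rows")
    keep = []
    for v in variables:
        if np.std(data[v].to_numpy(dtype=float)) == 0.0:
            warnings.warn(f"variable {v!r} has zero variance; excluded")
        else:
            keep.append(v)
    X = data.loc[:, keep].to_numpy(dtype=float)
    r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    p = _p_from_r(r, n)
    np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=keep, columns=keep),
        p=pd.DataFrame(p, index=keep, columns=keep),
        n=n,
    )


def strong_pairs(matrix: CorrelationMatrix, threshold: float = 0.7,
                 alpha: float = 0.05) -> list[tuple[str, str, float, float]]:
    """Unordered pairs with |R| strictly above ``threshold`` and p < alpha.

    The absolute value matters: a strongly *negative* correlation (e.g.
    temperature vs dissolved oxygen) is just as redundant.  Sorted by |R|
    descending.
    """
    out = []
    cols = matrix.variables
    for i, a in enumerate(cols):
        for j in range(i):
            b = cols[j]
            r = float(matrix.r.iloc[i, j])
            p = float(matrix.p.iloc[i, j])
            if abs(r) > threshold and p < alpha:
                out.append((b, a, r, p))
    out.sort(key=lambda t: -abs(t[2]))
    return out


def select_predictors(matrix: CorrelationMatrix,
                      retain_policy: Sequence[str] = DEFAULT_RETAIN_POLICY,
                      threshold: float = 0.7,
                      alpha: float = 0.05,
                      exclude: Sequence[str] = ("Chla",)) -> list[str]:
    """Filtered predictor list after removing one member of each strong pair.

    Pairs are processed in order of their preferred member's rank (then by
    |R| descending); a pair acts only while both members are still
    retained, and a variable once removed stays removed.  The result keeps
    the matrix's variable order.
    """
    rank = {v: i for i, v in enumerate(retain_policy)}
    candidates = [v for v in matrix.variables if v not in set(exclude)]
    pairs = [pr for pr in strong_pairs(matrix, threshold, alpha)
             if pr[0] in candidates and pr[1] in candidates]
    for a, b, _, _ in pairs:
        if a not in rank or b not in rank:
            raise ConfigurationError(
                f"strong pair ({a}, {b}) has a member missing from the "
                "retain policy")
    pairs.sort(key=lambda t: (min(rank[t[0]], rank[t[1]]), -abs(t[2])))
    removed: set[str] = set()
    for a, b, _, _ in pairs:
        if a in removed or b in removed:
            continue
        removed.add(a if rank[a] > rank[b] else b)
    return [v for v in candidates if v not in removed]


def load_taihu_correlations(n: int = 396) -> CorrelationMatrix:
    """The published 2013 Taihu 15-variable correlation matrix.

    R values are as printed (two decimals); p-values are recovered from R
    and the sample size through the exact t transform.
    """
    with resources.files("lakehealth.data").joinpath(
            "taihu_2013_correlations.csv").open() as fh:
        r = pd.read_csv(fh, index_col="variable")
    p = pd.DataFrame(_p_from_r(r.to_numpy(dtype=float), n),
                     index=r.index, columns=r.columns)
    np.fill_diagonal(p.values, 0.0)
    return CorrelationMatrix(r=r, p=p, n=n)
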
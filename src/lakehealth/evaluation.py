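"""Model-adequacy statistics in the hydrologic-modeling tradition.

For observations O and predictions P:

    NSE   = 1 - sum (O - P)^2 / sum (O - Obar)^2      (1 perfect, 0 = mean)
    RSR   = RMSE / sd(O)  =  sqrt(1 - NSE)
    PBIAS = 100 * sum (O - P) / sum O                  (% ; negative =
                                                        overprediction)
    R^2   = squared Pearson correlation of O and P

A prediction is judged adequate when NSE > 0.5, RSR <= 0.7 and PBIAS lies
within +/-25%; the thresholds are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = ["AdequacyThresholds", "AdequacyReport", "adequacy"]


@dataclass(frozen=True)
class AdequacyThresholds:
    nse_min: float = 0.5
    rsr_max: float = 0.7
    pbias_abs_max: float = 25.0


@dataclass
class AdequacyReport:
    """Computed statistics plus pass/fail flags against the thresholds."""

    r_squared: float
    nse: float
    rsr: float
    pbias_percent: float
    n: int
    pass_nse: bool
    pass_rsr: bool
    pass_pbias: bool

    @property
    def passes(self) -> bool:
        return self.pass_nse and self.pass_rsr and self.pass_pbias

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "nse": self.nse,
            "rsr": self.rsr,
            "pbias_percent": self.pbias_percent,
            "n": self.n,
            "pass_nse": self.pass_nse,
            "pass_rsr": self.pass_rsr,
            "pass_pbias": self.pass_pbias,
            "passes": self.passes,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def adequacy(observed: Sequence[float], predicted: Sequence[float],
             thresholds: AdequacyThresholds | None = None) -> AdequacyReport:
    """Compute NSE, RSR, PBIAS and R^2 and judge them against thresholds.

    Undefined cases raise rather than returning sentinel values: NSE/RSR
    need nonzero observation variance, PBIAS a nonzero observation sum.
    """
    if thresholds is None:
        thresholds = AdequacyThresholds()
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValidationError("observed and predicted must be equal-length vectors")
    if o.size < 2:
        raise ValidationError("need at least 2 observations")
    ss_obs = float(np.sum((o - o.mean()) ** 2))
    if ss_obs == 0.0:
        raise ValidationError("NSE/RSR undefined: observations have zero variance")
    obs_sum = float(o.sum())
    if obs_sum == 0.0:
        raise ValidationError("PBIAS undefined: observations sum to zero")
    ss_err = float(np.sum((o - p) ** 2))
    nse = 1.0 - ss_err / ss_obs
    rsr = float(np.sqrt(ss_err) / np.sqrt(ss_obs))
    pbias = 100.0 * float(np.sum(o - p)) / obs_sum
    if np.std(p) == 0.0:
        r2 = 0.0  # constant prediction carries no linear association
    else:
        r2 = float(np.corrcoef(o, p)[0, 1] ** 2)
    return AdequacyReport(
        r_squared=r2,
        nse=nse,
        rsr=rsr,
        pbias_percent=pbias,
        n=int(o.size),
        pass_nse=nse > thresholds.nse_min,
        pass_rsr=rsr <= thresholds.rsr_max,
        pass_pbias=abs(pbias) <= thresholds.pbias_abs_max,
    )
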
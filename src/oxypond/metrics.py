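"""Model-evaluation statistics: RMSE, MAE, Pearson R and Willmott's D.

RMSE and MAE carry the units of the target (mg/L here).  Pearson's R is
the usual product-moment correlation.  Willmott's index of agreement,

    D = 1 - sum (O_i - P_i)^2 / sum (|O_i - Obar| + |P_i - Obar|)^2,

uses the OBSERVED mean in both absolute deviations (the standard form);
D <= 1 with equality iff the prediction is perfect.  Undefined cases
(zero variance for R, zero denominator for D) return NaN with a warning
instead of raising, so a metrics table can always be assembled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np


def _check_pair(obs, pred):
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError(f"obs and pred must be equal-length 1-D, got "
                         f"{obs.shape} vs {pred.shape}")
    if len(obs) < 1:
        raise ValueError("need at least one observation")
    return obs, pred


def rmse(obs, pred) -> float:
    obs, pred = _check_pair(obs, pred)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def mae(obs, pred) -> float:
    obs, pred = _check_pair(obs, pred)
    return float(np.mean(np.abs(pred - obs)))


def pearson_r(obs, pred) -> float:
    obs, pred = _check_pair(obs, pred)
    if len(obs) < 2:
        warnings.warn("Pearson R undefined for a single point", stacklevel=2)
        return math.nan
    do = obs - obs.mean()
    dp = pred - pred.mean()
    denom = np.sqrt((do ** 2).sum() * (dp ** 2).sum())
    if denom == 0:
        warnings.warn("Pearson R undefined: a series has zero variance",
                      stacklevel=2)
        return math.nan
    return float((do * dp).sum() / denom)


def willmott_d(obs, pred) -> float:
    obs, pred = _check_pair(obs, pred)
    obar = obs.mean()
    denom = ((np.abs(obs - obar) + np.abs(pred - obar)) ** 2).sum()
    if denom == 0:
        warnings.warn("Willmott D undefined: all values identical", stacklevel=2)
        return math.nan
    return float(1.0 - ((obs - pred) ** 2).sum() / denom)


@dataclass
class MetricsReport:
    """The four statistics for one model on one sample set."""

    rmse: float
    mae: float
    r: float
    d: float
    n: int
    model: str = ""
    split: str = ""

    @classmethod
    def compute(cls, obs, pred, model: str = "", split: str = "") -> "MetricsReport":
        obs, pred = _check_pair(obs, pred)
        return cls(rmse=rmse(obs, pred), mae=mae(obs, pred),
                   r=pearson_r(obs, pred), d=willmott_d(obs, pred),
                   n=len(obs), model=model, split=split)

    def as_row(self) -> dict:
        return {"model": self.model, "split": self.split, "rmse": self.rmse,
                "mae": self.mae, "r": self.r, "d": self.d, "n": self.n}


# ---------------------------------------------------------------------
# comparison-report summary arithmetic


@dataclass
class ComparisonSummary:
    """Summary lines of a multi-model comparison table.

    ``baseline_mean_rmse`` averages the trial-count RBF testing RMSEs;
    ``reduction_pct`` is the relative improvement of the proposed model's
    RMSE over that mean, in percent.
    """

    baseline_mean_rmse: float
    reduction_pct: float
    baseline_rmses: list = field(default_factory=list)
    proposed_rmse: float = math.nan


def summarize_comparison(baseline_rmses, proposed_rmse: float,
                         ndigits: int = 4) -> ComparisonSummary:
    """Mean baseline RMSE and percent reduction of the proposed model.

    The mean is rounded to ``ndigits`` before the reduction is taken, so
    the two summary numbers are mutually consistent at printed precision.
    """
    baseline_rmses = [float(v) for v in baseline_rmses]
    if not baseline_rmses:
        raise ValueError("need at least one baseline RMSE")
    mean = round(float(np.mean(baseline_rmses)), ndigits)
    reduction = 100.0 * (mean - float(proposed_rmse)) / mean
    return ComparisonSummary(
        baseline_mean_rmse=mean,
        reduction_pct=round(reduction, 2),
        baseline_rmses=baseline_rmses,
        proposed_rmse=float(proposed_rmse),
    )
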
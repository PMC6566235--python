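"""Agreement statistics for observed-vs-predicted GI or GL.

Reports the Pearson correlation, per-column means and sample SDs, the
median absolute residual, and Bland–Altman limits of agreement with the
products falling outside them.  Differences are taken as observed minus
predicted, so an under-predicted product has a positive difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .model_core import GlycoError

__all__ = ["ValidationReport", "agreement_report"]


@dataclass(frozen=True)
class ValidationReport:
    n: int
    pearson_r: float
    mean_observed: float
    sd_observed: float
    mean_predicted: float
    sd_predicted: float
    median_abs_residual: float
    ba_mean_diff: float
    ba_lower: float
    ba_upper: float
    outlier_ids: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "mean_observed": self.mean_observed,
            "sd_observed": self.sd_observed,
            "mean_predicted": self.mean_predicted,
            "sd_predicted": self.sd_predicted,
            "median_abs_residual": self.median_abs_residual,
            "ba_mean_diff": self.ba_mean_diff,
            "ba_lower": self.ba_lower,
            "ba_upper": self.ba_upper,
            "outlier_ids": list(self.outlier_ids),
            "difference_convention": "observed - predicted",
        }


def agreement_report(
    observed: Sequence[float],
    predicted: Sequence[float],
    ids: Sequence[str] | None = None,
    *,
    sd_multiplier: float = 2.0,
) -> ValidationReport:
    """Compute the agreement report for paired observed/predicted values.

    Bland–Altman limits are placed at mean ± ``sd_multiplier`` x SD of the
    differences; the conventional multiplier here is a literal 2 (pass 1.96
    for the normal-quantile variant).  Outliers are the points strictly
    outside the limits.  SDs use the sample (n-1) convention; the median
    uses the mid-point convention for even n.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise GlycoError("observed and predicted must be 1-d vectors of equal length")
    n = obs.size
    if n < 3:
        raise GlycoError("need at least 3 paired observations")
    if not (np.isfinite(obs).all() and np.isfinite(pred).all()):
        raise GlycoError("non-finite values in input")
    if ids is None:
        ids = [str(i) for i in range(n)]
    elif len(ids) != n:
        raise GlycoError("ids length mismatch")

    if np.std(obs) == 0 or np.std(pred) == 0:
        raise GlycoError("correlation undefined: zero variance in a column")
    r = float(stats.pearsonr(obs, pred).statistic)

    diff = obs - pred
    ba_mean = float(diff.mean())
    ba_sd = float(diff.std(ddof=1))
    lower = ba_mean - sd_multiplier * ba_sd
    upper = ba_mean + sd_multiplier * ba_sd
    outliers = tuple(str(i) for i, d in zip(ids, diff) if d < lower or d > upper)

    return ValidationReport(
        n=n,
        pearson_r=r,
        mean_observed=float(obs.mean()),
        sd_observed=float(obs.std(ddof=1)),
        mean_predicted=float(pred.mean()),
        sd_predicted=float(pred.std(ddof=1)),
        median_abs_residual=float(np.median(np.abs(diff))),
        ba_mean_diff=ba_mean,
        ba_lower=lower,
        ba_upper=upper,
        outlier_ids=outliers,
    )
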
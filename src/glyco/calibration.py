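"""Estimation of the empirical GI-lowering coefficients and starch availability.

The dilution model GI = N / (S + sum_j x_j b_j), with N the availability-
corrected numerator and S the summed glycemic carbohydrate amounts, is
linear in the unknown b_j after an exact algebraic rearrangement: for each
product p with observed GI_p,

    N_p / GI_p - S_p = sum_j x_pj b_j .

The left-hand side is computable from the composition and the known glycemic
coefficients, so the b_j are estimated by ordinary least squares with no
intercept (the model has none).  A nonlinear mode that minimises residuals
directly in GI space is provided for comparison, since the two residual
definitions weight products differently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import least_squares

from .model_core import (
    CoefficientTable,
    Composition,
    GlycoError,
    default_coefficients,
    normalize_nutrient,
    predict_gi,
)

__all__ = ["CalibrationResult", "calibrate_b", "solve_starch_availability"]

_RANK_RTOL = 1e-10


class CollinearityError(GlycoError):
    """Raised when the calibration design matrix is rank deficient."""


@dataclass(frozen=True)
class CalibrationResult:
    """Estimated GI-lowering coefficients with their uncertainty."""

    b_estimates: Mapping[str, float]
    standard_errors: Mapping[str, float]
    residual_sd: float
    n_products: int
    warnings: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "b_estimates": dict(self.b_estimates),
            "standard_errors": dict(self.standard_errors),
            "residual_sd": self.residual_sd,
            "n_products": self.n_products,
            "warnings": list(self.warnings),
        }


def _numerator_and_sums(
    comp: Composition, coeffs: CoefficientTable
) -> tuple[float, float]:
    """Availability-corrected numerator N and glycemic amount sum S."""
    if "starch" in comp.amounts and comp.amounts["starch"] > 0:
        if comp.starch_availability is None:
            raise GlycoError(
                "starch availability must be resolved before calibration"
            )
    res = predict_gi(comp, coeffs)
    return res.numerator, sum(
        a
        for n, a in comp.amounts.items()
        if n in coeffs and coeffs[n].role == "glycemic"
    )


def _aliased_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns expressible (numerically) as combinations of the others."""
    aliased = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if others.shape[1] == 0:
            continue
        proj, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ proj
        if np.linalg.norm(resid) <= _RANK_RTOL * max(np.linalg.norm(X[:, j]), 1.0):
            aliased.append(names[j])
    return aliased


def calibrate_b(
    data: Sequence[tuple[Composition, float]],
    coeffs_glycemic: CoefficientTable | None = None,
    nutrients_to_fit: Sequence[str] | None = None,
    *,
    method: str = "linearized",
) -> CalibrationResult:
    """Estimate GI-lowering coefficients from (composition, observed GI) pairs.

    Parameters
    ----------
    data
        Products with resolved starch availabilities and observed GI > 0.
    coeffs_glycemic
        Table providing the glycemic coefficients (GIs, availabilities) and
        the fixed b values of any lowering nutrient not being fitted; fixed
        contributions are subtracted from the response.
    nutrients_to_fit
        Lowering nutrients whose b is estimated; defaults to every lowering
        nutrient present in the data.
    method
        ``"linearized"`` (exact OLS on the rearranged model, the default) or
        ``"nonlinear"`` (least squares on GI residuals, initialised at the
        linearized solution).

    Negative estimates are reported as-is with a warning, never clipped:
    a negative b is a diagnostic, not a parameter.
    """
    coeffs = coeffs_glycemic or default_coefficients()
    if len(data) == 0:
        raise GlycoError("empty calibration dataset")

    present: set[str] = set()
    for comp, gi in data:
        if gi <= 0:
            raise GlycoError("observed GI must be positive for calibration")
        for n, a in comp.amounts.items():
            if n in coeffs and coeffs[n].role != "glycemic" and a > 0:
                present.add(n)
    if nutrients_to_fit is None:
        fit_names = sorted(present)
    else:
        fit_names = [normalize_nutrient(n) for n in nutrients_to_fit]
        for n in fit_names:
            if n in coeffs and coeffs[n].role == "glycemic":
                raise GlycoError(f"{n!r} is glycemic; only lowering nutrients have b")
    if not fit_names:
        raise GlycoError("no lowering nutrients to fit")
    if len(data) < len(fit_names) + 1:
        raise GlycoError(
            f"need at least {len(fit_names) + 1} products to fit {len(fit_names)} coefficients"
        )

    X = np.zeros((len(data), len(fit_names)))
    y = np.zeros(len(data))
    N = np.zeros(len(data))  # availability-corrected numerators
    base = np.zeros(len(data))  # glycemic sum + fixed-b contributions
    gi_obs = np.array([gi for _, gi in data], dtype=float)
    for p, (comp, gi) in enumerate(data):
        numerator, s_glycemic = _numerator_and_sums(comp, coeffs)
        fixed = 0.0
        for n, a in comp.amounts.items():
            if n in coeffs and coeffs[n].role == "glycemic":
                continue
            if n in fit_names:
                X[p, fit_names.index(n)] = a
            else:
                # fixed-b nutrient: move its known contribution to the left
                fixed += a * coeffs[n].effective_b
        N[p] = numerator
        base[p] = s_glycemic + fixed
        y[p] = numerator / gi - s_glycemic - fixed

    sv = np.linalg.svd(X, compute_uv=False)
    if sv[0] == 0 or sv[-1] / sv[0] < _RANK_RTOL:
        raise CollinearityError(
            "rank-deficient design; aliased nutrients: "
            + ", ".join(_aliased_columns(X, fit_names) or fit_names)
        )

    fit = sm.OLS(y, X).fit()
    b = dict(zip(fit_names, fit.params))
    se = dict(zip(fit_names, fit.bse))

    warnings: list[str] = []
    for n, v in b.items():
        if v < 0:
            warnings.append(f"negative estimate for {n!r}: b = {v:.4f}")

    dof = max(len(data) - len(fit_names), 1)

    def gi_resid(theta: np.ndarray) -> np.ndarray:
        return N / (base + X @ theta) - gi_obs

    if method == "nonlinear":
        sol = least_squares(gi_resid, np.array([b[n] for n in fit_names]))
        b = dict(zip(fit_names, sol.x))
        resid = gi_resid(sol.x)
        residual_sd = float(np.sqrt(resid @ resid / dof))
        # Gauss-Newton covariance for SEs
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * (resid @ resid / dof)
            se = dict(zip(fit_names, np.sqrt(np.diag(cov))))
        except np.linalg.LinAlgError:
            se = {n: float("nan") for n in fit_names}
        warnings = [f"negative estimate for {n!r}: b = {v:.4f}" for n, v in b.items() if v < 0]
    elif method == "linearized":
        # residual SD reported in GI units via the forward model
        resid = gi_resid(np.array([b[n] for n in fit_names]))
        residual_sd = float(np.sqrt(resid @ resid / dof))
    else:
        raise GlycoError(f"unknown calibration method {method!r}")

    return CalibrationResult(
        b_estimates=b,
        standard_errors=se,
        residual_sd=residual_sd,
        n_products=len(data),
        warnings=tuple(warnings),
    )


def solve_starch_availability(
    composition: Composition,
    gi_target: float,
    coeffs: CoefficientTable | None = None,
) -> tuple[float, list[str]]:
    """Back-solve the starch availability that reproduces a target GI.

    Inverts the dilution model for the single unknown a:

        a = (GI_target * D - sum_{non-starch} x_i GI_i) / (x_starch * GI_starch)

    with D the full model denominator.  The raw solution is returned even
    when outside [0, 1], with a warning, so diagnostics stay honest.
    """
    coeffs = coeffs or default_coefficients()
    x_starch = composition.amounts.get("starch", 0.0)
    if x_starch <= 0:
        raise GlycoError("composition has no starch to solve availability for")
    if gi_target < 0:
        raise GlycoError("target GI must be >= 0")

    denominator = 0.0
    non_starch_num = 0.0
    for n, a in composition.amounts.items():
        spec = coeffs[n]
        if spec.role == "glycemic":
            if a > 0:
                denominator += a
                if n != "starch":
                    non_starch_num += a * spec.availability_default * spec.gi
        else:
            denominator += a * spec.effective_b

    gi_starch = coeffs["starch"].gi
    availability = (gi_target * denominator - non_starch_num) / (x_starch * gi_starch)
    warnings = []
    if not 0 <= availability <= 1:
        warnings.append(
            f"back-solved availability {availability:.4f} outside [0, 1]; "
            "target GI inconsistent with composition"
        )
    return availability, warnings
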
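"""Ridge calibration of REE on VCO2 and the simplified bedside formula.

A single-predictor penalized linear regression of reference REE (kcal/day)
on VCO2 (mL/min): the predictor is standardized, the intercept left
unpenalized, the coefficient solved in closed form per penalty, and the
penalty chosen by k-fold cross-validated squared error.  The fitted line is
then rounded to an integer-coefficient bedside formula (reference result:
REE = 135 + 8*VCO2) and that formula is scored with the full agreement
battery.

With one predictor the penalty matters little — it is retained because the
procedure being validated used it, and because it makes the estimator
well-defined under degenerate resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .agreement import DEFAULT_BANDS, AgreementSummary, PctMode, summarize_agreement
from .weir import SimplifiedFormula, simplified_ree

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "RidgeREECalibrator",
    "CalibrationResult",
    "fit_ridge",
    "round_to_simplified",
    "evaluate_formula",
]

DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(np.logspace(-4, 2, 25))


def _ridge_closed_form(xs: np.ndarray, yc: np.ndarray, lam: float) -> float:
    """Penalized slope for a standardized predictor and centered response:
    beta = sum(xs*yc) / (sum(xs^2) + lam)  (the ||y - X b||^2 + lam*b^2
    minimizer, matching the common machine-learning convention)."""
    return float(xs @ yc / (xs @ xs + lam))


class RidgeREECalibrator(RegressorMixin, BaseEstimator):
    """Cross-validated single-predictor ridge regressor of REE on VCO2.

    Parameters
    ----------
    alphas : array-like of float
        Penalty grid (on the standardized predictor); selected by k-fold
        cross-validated mean squared error, smallest penalty winning ties.
    cv : int
        Number of folds (shuffled).
    random_state : int or None
        Seed for the fold shuffle.

    Attributes
    ----------
    intercept_ : float
        Intercept on the original mL/min scale (kcal/day).
    coef_ : ndarray of shape (1,)
        Slope on the original scale (kcal/day per mL/min).
    alpha_ : float
        Selected penalty.
    r2_ : float
        In-sample coefficient of determination of the selected fit.
    cv_mse_ : ndarray of shape (len(alphas),)
        Mean cross-validated squared error per grid penalty.
    n_ : int
        Number of observations fitted.
    """

    def __init__(self, alphas=DEFAULT_LAMBDA_GRID, cv: int = 10, random_state=None):
        self.alphas = alphas
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=3)
        if X.shape[1] != 1:
            raise ValueError(f"expected a single VCO2 predictor, got {X.shape[1]} columns")
        alphas = np.asarray(self.alphas, dtype=float)
        if alphas.size == 0:
            raise ValueError("alphas grid is empty")
        if np.any(alphas < 0):
            raise ValueError("penalties must be non-negative")
        x = X[:, 0]
        n = x.size
        if n < max(self.cv, 3):
            raise ValueError(f"need at least max(cv, 3) = {max(self.cv, 3)} samples, got {n}")
        mx, sx = x.mean(), x.std()
        if sx == 0:
            raise ValueError("VCO2 predictor has zero variance")

        # grid search: closed-form fit per fold and penalty
        order = np.argsort(alphas, kind="mergesort")
        cv_mse = np.zeros(alphas.size)
        kf = KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        for train, test in kf.split(x):
            xt, yt = x[train], y[train]
            mt, st = xt.mean(), xt.std()
            if st == 0:
                raise ValueError("a CV fold has zero predictor variance; reduce cv")
            xs = (xt - mt) / st
            yc = yt - yt.mean()
            for i, lam in enumerate(alphas):
                beta = _ridge_closed_form(xs, yc, lam)
                pred = yt.mean() + beta * (x[test] - mt) / st
                cv_mse[i] += ((y[test] - pred) ** 2).sum()
        cv_mse /= n
        # smallest penalty wins ties
        best = order[np.argmin(cv_mse[order])]
        self.alpha_ = float(alphas[best])
        self.cv_mse_ = cv_mse

        xs = (x - mx) / sx
        yc = y - y.mean()
        beta = _ridge_closed_form(xs, yc, self.alpha_)
        self.coef_ = np.array([beta / sx])
        self.intercept_ = float(y.mean() - beta * mx / sx)
        resid = y - (self.intercept_ + self.coef_[0] * x)
        sst = float(((y - y.mean()) ** 2).sum())
        self.r2_ = 1.0 - float((resid**2).sum()) / sst
        self.n_ = int(n)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return self.intercept_ + X[:, 0] * self.coef_[0]


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted calibration line plus its rounded bedside form.

    ``evaluation`` is populated once the simplified formula has been scored
    against a paired dataset (see :func:`evaluate_formula`).
    """

    intercept: float  # kcal/day
    slope: float  # kcal/day per mL/min
    penalty: float
    r2: float
    n: int
    simplified: SimplifiedFormula
    evaluation: AgreementSummary | None = None


def fit_ridge(
    vco2,
    ree,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    cv_folds: int = 10,
    seed: int | None = 0,
    slope_decimals: int = 0,
    intercept_decimals: int = 0,
) -> CalibrationResult:
    """Fit the cross-validated ridge calibration and round it to a bedside
    formula.  Thin wrapper over :class:`RidgeREECalibrator`."""
    vco2 = np.asarray(vco2, dtype=float).ravel()
    ree = np.asarray(ree, dtype=float).ravel()
    est = RidgeREECalibrator(alphas=lambda_grid, cv=cv_folds, random_state=seed)
    est.fit(vco2[:, None], ree)
    result = CalibrationResult(
        intercept=est.intercept_,
        slope=float(est.coef_[0]),
        penalty=est.alpha_,
        r2=est.r2_,
        n=est.n_,
        simplified=SimplifiedFormula(intercept=0.0, slope=1.0),  # placeholder
    )
    simplified = round_to_simplified(result, slope_decimals, intercept_decimals)
    return CalibrationResult(
        intercept=result.intercept,
        slope=result.slope,
        penalty=result.penalty,
        r2=result.r2,
        n=result.n,
        simplified=simplified,
    )


def _round_half_away(x: float, decimals: int) -> float:
    scale = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * scale + 0.5) / scale)


def round_to_simplified(
    result: CalibrationResult, slope_decimals: int = 0, intercept_decimals: int = 0
) -> SimplifiedFormula:
    """Round the fitted line to a bedside formula, half away from zero
    (so 7.5 -> 8 and -0.5 -> -1, independent of banker's rounding)."""
    return SimplifiedFormula(
        intercept=_round_half_away(result.intercept, intercept_decimals),
        slope=_round_half_away(result.slope, slope_decimals),
    )


def evaluate_formula(
    formula: SimplifiedFormula,
    ds,
    bands=DEFAULT_BANDS,
    error_mode: PctMode | str = PctMode.REL_REF,
    difference_mode: PctMode | str = PctMode.REL_PAIR_MEAN,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
) -> AgreementSummary:
    """Score a simplified formula on a paired dataset's ventilator block
    VCO2 against the IC reference, with the full agreement battery."""
    if len(ds.frame) == 0:
        raise ValueError("paired dataset is empty")
    est = simplified_ree(ds.frame["block_vco2"].to_numpy(), formula)
    ref = ds.frame["ree_ic"].to_numpy()
    return summarize_agreement(
        est,
        ref,
        rq=None,
        bands=bands,
        error_mode=error_mode,
        difference_mode=difference_mode,
        ci_method=ci_method,
        n_boot=n_boot,
        seed=seed,
    )
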
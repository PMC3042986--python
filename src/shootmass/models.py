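"""Shoot dry weight regression models.

The quantity of interest is shoot dry weight (SDW, grams) of an individual
cereal plant, inferred non-destructively from its projected shoot area
A (mm², from :mod:`shootmass.imaging`) and, for the age-aware model, its age
HD (days).  Five model forms are supported:

========== =============================================== =================
form       model                                           response scale
========== =============================================== =================
linear     SDW = a0 + a1·A                                 natural
quadratic  SDW = a0 + a1·A + a2·A²                         natural
cubic      SDW = a0 + a1·A + a2·A² + a3·A³                 natural
power      SDW = a0·A^a1   (fitted as log SDW ~ log A)     log
psw        SDW = c0 + c1·A + c2·A·HD                       natural
========== =============================================== =================

The ``psw`` form derives from the *plant specific weight* PSW = SDW / A
(g/mm²), which is empirically linear in plant age: PSW = b0 + b1·HD.
Substituting into SDW = A·PSW and allowing a free intercept gives the
area-by-age interaction model above.  Because salt-stressed plants of a
given area are older (hence denser) than unstressed plants of the same
area, a model in area alone is systematically biased across salt
treatments while the interaction model is not; that bias structure is
quantified in :mod:`shootmass.validation`.

All forms are fitted by ordinary least squares with an intercept; the power
form uses natural logs on both sides.  Inference (standard errors, t, two-
sided p from the t distribution on the residual degrees of freedom, R²)
follows the usual OLS estimators.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import DomainError, InputError, SingularDesignError

__all__ = [
    "MODEL_FORMS",
    "FitResult",
    "PSWLine",
    "BiomassRegressor",
    "design_matrix",
    "fit_ols",
    "fit_model",
    "predict",
    "plant_specific_weight",
    "fit_psw_line",
]

MODEL_FORMS = ("linear", "quadratic", "cubic", "power", "psw")

_POLY_DEGREE = {"linear": 1, "quadratic": 2, "cubic": 3}

#: Coefficient unit strings per form, matching the reporting convention
#: (grams, mm², days).
_UNITS = {
    "linear": ("g", "g/mm^2"),
    "quadratic": ("g", "g/mm^2", "g/mm^4"),
    "cubic": ("g", "g/mm^2", "g/mm^4", "g/mm^6"),
    "power": ("log(g)", "log(g)/log(mm^2)"),
    "psw": ("g", "g/mm^2", "g/(day.mm^2)"),
}


@dataclasses.dataclass(frozen=True)
class FitResult:
    """An OLS fit: coefficients with full inference plus per-observation residuals.

    ``scale_const`` is only set for the power form: the back-transformed
    multiplicative constant exp(intercept), reported alongside the log-scale
    intercept because the model is fitted on the log scale.
    """

    form: str
    terms: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    rsquared: float
    resid: np.ndarray
    nobs: int
    units: tuple[str, ...] | None = None
    scale_const: float | None = None

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table: term, unit, value, std_error, t, p."""
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "unit": list(self.units) if self.units else [""] * len(self.terms),
                "value": self.params,
                "std_error": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )


@dataclasses.dataclass(frozen=True)
class PSWLine:
    """Plant specific weight as a linear function of age: PSW = b0 + b1·age."""

    b0: float  # g/mm^2
    b1: float  # g/(mm^2.day)
    fit: FitResult

    def __call__(self, age_days) -> np.ndarray:
        return self.b0 + self.b1 * np.asarray(age_days, dtype=float)


def _check_form(form: str) -> str:
    if form not in MODEL_FORMS:
        raise InputError(f"unknown model form {form!r}; expected one of {MODEL_FORMS}")
    return form


def _regressors(form: str, area: np.ndarray, age: np.ndarray | None) -> pd.DataFrame:
    """Regressor table (including intercept column) for one model form."""
    area = np.asarray(area, dtype=float)
    n = area.shape[0]
    const = np.ones(n)
    if form in _POLY_DEGREE:
        cols = {"intercept": const}
        for d in range(1, _POLY_DEGREE[form] + 1):
            cols["area" if d == 1 else f"area^{d}"] = area**d
        return pd.DataFrame(cols)
    if form == "power":
        if np.any(area <= 0):
            raise DomainError("power form requires strictly positive areas (log transform)")
        return pd.DataFrame({"intercept": const, "log_area": np.log(area)})
    if form == "psw":
        if age is None:
            raise InputError("psw form requires plant age")
        age = np.asarray(age, dtype=float)
        if age.shape != area.shape:
            raise InputError("area and age must have equal length")
        return pd.DataFrame({"intercept": const, "area": area, "area_age": area * age})
    raise InputError(f"unknown model form {form!r}")  # pragma: no cover


def design_matrix(form: str, obs: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Build the regressor table and response vector for a model form.

    ``obs`` is a phenotype table with columns ``area_mm2``, ``sdw_g`` and,
    for the psw form, ``age_days``.  The power form returns the response on
    the natural-log scale.
    """
    _check_form(form)
    if len(obs) == 0:
        raise InputError("observations must not be empty")
    for col in ("area_mm2", "sdw_g") + (("age_days",) if form == "psw" else ()):
        if col not in obs.columns:
            raise InputError(f"phenotype table is missing column {col!r}")
    area = obs["area_mm2"].to_numpy(dtype=float)
    age = obs["age_days"].to_numpy(dtype=float) if "age_days" in obs.columns else None
    X = _regressors(form, area, age)
    X.index = obs.index
    y = obs["sdw_g"].astype(float)
    if form == "power":
        if (y <= 0).any():
            raise DomainError("power form requires strictly positive SDW (log transform)")
        y = np.log(y)
    return X, pd.Series(np.asarray(y), index=obs.index, name="sdw_g")


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    # Pivoted QR: columns permuted after the numerical rank are the dependent ones.
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        raise SingularDesignError([names[j] for j in piv[rank:]])


def fit_ols(X, y, form: str = "custom", units: tuple[str, ...] | None = None) -> FitResult:
    """Ordinary least squares with classical inference.

    ``X`` is the full regressor table (intercept column included) as a
    DataFrame or 2-D array; ``y`` the response vector.  Raises
    :class:`SingularDesignError` naming the dependent columns when the
    design is rank deficient, and :class:`InputError` when there are not
    more observations than regressors.
    """
    if isinstance(X, pd.DataFrame):
        names = tuple(map(str, X.columns))
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim != 2:
            raise InputError("X must be two-dimensional")
        names = tuple(f"x{j}" for j in range(Xa.shape[1]))
    ya = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if ya.shape[0] != n:
        raise InputError("X and y must have equal length")
    if n <= p:
        raise InputError(f"need more observations ({n}) than regressors ({p})")
    _check_rank(Xa, names)
    res = sm.OLS(ya, Xa).fit(method="qr")
    scale_const = float(np.exp(res.params[0])) if form == "power" else None
    return FitResult(
        form=form,
        terms=names,
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        tvalues=np.asarray(res.tvalues),
        pvalues=np.asarray(res.pvalues),
        df_resid=int(res.df_resid),
        rsquared=float(res.rsquared),
        resid=np.asarray(res.resid),
        nobs=n,
        units=units,
        scale_const=scale_const,
    )


def fit_model(form: str, obs: pd.DataFrame) -> FitResult:
    """Fit one of the five model forms to a phenotype table."""
    _check_form(form)
    X, y = design_matrix(form, obs)
    return fit_ols(X, y, form=form, units=_UNITS[form])


def predict(fit: FitResult, area, age=None) -> np.ndarray:
    """Evaluate a fitted model at new areas (and ages, for the psw form).

    The power form back-transforms from the log scale.
    """
    form = fit.form
    if form not in MODEL_FORMS:
        raise InputError(f"cannot predict for form {fit.form!r}")
    area = np.atleast_1d(np.asarray(area, dtype=float))
    if form == "psw":
        if age is None:
            raise InputError("psw form requires plant age for prediction")
        age = np.broadcast_to(np.asarray(age, dtype=float), area.shape)
    X = _regressors(form, area, age if form == "psw" else None).to_numpy()
    yhat = X @ fit.params
    if form == "power":
        yhat = np.exp(yhat)
    return yhat


def plant_specific_weight(sdw, area):
    """PSW = SDW / projected shoot area, in g/mm².  Area must be positive."""
    sdw = np.asarray(sdw, dtype=float)
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise DomainError("plant specific weight requires area > 0")
    return sdw / area


def fit_psw_line(obs: pd.DataFrame) -> PSWLine:
    """Regress per-plant PSW on age: PSW = b0 + b1·age.

    Raises :class:`SingularDesignError` when the table contains a single
    harvest day (no age variation to identify the slope).
    """
    for col in ("area_mm2", "sdw_g", "age_days"):
        if col not in obs.columns:
            raise InputError(f"phenotype table is missing column {col!r}")
    psw = plant_specific_weight(obs["sdw_g"].to_numpy(), obs["area_mm2"].to_numpy())
    age = obs["age_days"].to_numpy(dtype=float)
    X = pd.DataFrame({"intercept": np.ones_like(age), "age_days": age}, index=obs.index)
    fit = fit_ols(X, psw, form="psw_line", units=("g/mm^2", "g/(mm^2.day)"))
    return PSWLine(b0=float(fit.params[0]), b1=float(fit.params[1]), fit=fit)


class BiomassRegressor(RegressorMixin, BaseEstimator):
    """Sklearn-style estimator for shoot dry weight as a function of area (and age).

    Parameters
    ----------
    form : {"linear", "quadratic", "cubic", "power", "psw"}, default "psw"
        Model form (see module docstring).

    ``X`` has the area (mm²) in column 0 and, required for ``form="psw"``,
    the plant age (days) in column 1; ``y`` is SDW in grams.  After fitting:

    Attributes
    ----------
    result_ : FitResult
        Coefficients with standard errors, t, p, R² and residuals.
    intercept_ : float
        Intercept on the fitted scale (log scale for the power form).
    coef_ : ndarray
        Non-intercept coefficients on the fitted scale.
    """

    def __init__(self, form: str = "psw"):
        self.form = form

    def _split_columns(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        area = X[:, 0]
        if self.form == "psw":
            if X.shape[1] < 2:
                raise InputError("psw form requires two columns: area_mm2, age_days")
            return area, X[:, 1]
        return area, None

    def fit(self, X, y) -> "BiomassRegressor":
        _check_form(self.form)
        X, y = check_X_y(X, y, ensure_min_features=1)
        self.n_features_in_ = X.shape[1]
        area, age = self._split_columns(X)
        D = _regressors(self.form, area, age)
        yt = np.asarray(y, dtype=float)
        if self.form == "power":
            if np.any(yt <= 0):
                raise DomainError("power form requires strictly positive SDW")
            yt = np.log(yt)
        self.result_ = fit_ols(D, yt, form=self.form, units=_UNITS[self.form])
        self.intercept_ = float(self.result_.params[0])
        self.coef_ = np.asarray(self.result_.params[1:])
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "result_")
        X = check_array(X, ensure_min_features=1)
        if X.shape[1] != self.n_features_in_:
            raise InputError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        area, age = self._split_columns(X)
        return predict(self.result_, area, age)
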
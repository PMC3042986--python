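"""Cross-validated error and bias diagnostics for biomass models.

Two error measures are reported, both in grams and both defined on
prediction errors e_i = SDW_predicted,i − SDW_actual,i:

* RMSE = sqrt(mean(e_i²)) — overall estimation error;
* MTE  = mean(e_i) — *mean total error*, the estimation bias; positive
  means systematic over-estimation.  They satisfy
  RMSE² = MTE² + Var_pop(e), so the bias is never larger in magnitude
  than the RMSE.

Generalisation error is estimated by K-fold cross-validation (K = 5 by
default): observations are randomly assigned to K near-equal folds, the
model is fitted on K−1 folds and evaluated on the held-out fold, and the
fold RMSEs are averaged over the K rounds (the pooled RMSE over all
held-out residuals is also reported, since the two differ slightly when
fold sizes are unequal).  Stratifying held-out errors by salt treatment
exposes the bias of the area-only model — over-estimation of unstressed
plants, under-estimation of salt-stressed ones — that the area-by-age
model removes.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .errors import InputError
from .models import FitResult, design_matrix, fit_model, predict

__all__ = [
    "DEFAULT_SEED",
    "CVResult",
    "ComparisonResult",
    "rmse",
    "mte",
    "kfold_split",
    "cross_validate",
    "compare_models",
    "stratified_report",
]

logger = logging.getLogger(__name__)

#: Default seed for fold assignment, fixed so runs are reproducible by default.
DEFAULT_SEED = 20110201


def _paired(predicted, actual) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float).ravel()
    a = np.asarray(actual, dtype=float).ravel()
    if p.shape != a.shape:
        raise InputError(f"length mismatch: {p.shape[0]} predicted vs {a.shape[0]} actual")
    if p.size == 0:
        raise InputError("need at least one observation")
    return p, a


def rmse(predicted, actual) -> float:
    """Root mean square of (predicted − actual), in grams."""
    p, a = _paired(predicted, actual)
    return float(np.sqrt(np.mean((p - a) ** 2)))


def mte(predicted, actual) -> float:
    """Mean total error (bias): mean of (predicted − actual); positive = over-estimation."""
    p, a = _paired(predicted, actual)
    return float(np.mean(p - a))


def kfold_split(n: int, k: int, seed: int = DEFAULT_SEED) -> np.ndarray:
    """Random K-fold assignment: array of fold indices in [0, k) of length n.

    Fold sizes differ by at most one; deterministic given the seed.
    """
    if not 2 <= k <= n:
        raise InputError(f"need 2 <= k <= n, got k={k}, n={n}")
    folds = np.empty(n, dtype=int)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for i, (_, test_idx) in enumerate(kf.split(np.arange(n))):
        folds[test_idx] = i
    return folds


@dataclasses.dataclass(frozen=True)
class CVResult:
    """Cross-validation output for one model form."""

    form: str
    fold_rmse: np.ndarray
    mean_rmse: float  # arithmetic mean of the K fold RMSEs
    pooled_rmse: float  # RMSE over all held-out residuals pooled
    predictions: pd.Series  # held-out prediction per observation
    folds: np.ndarray
    fits: tuple[FitResult, ...]


def cross_validate(
    form: str,
    obs: pd.DataFrame,
    k: int = 5,
    seed: int = DEFAULT_SEED,
    folds: np.ndarray | None = None,
) -> CVResult:
    """K-fold cross-validation of one model form on a phenotype table.

    Each observation is predicted exactly once, by a model never trained on
    it.  Returns per-fold RMSEs, their unweighted mean, the pooled RMSE and
    the held-out predictions aligned to ``obs``.  A precomputed fold
    assignment may be passed via ``folds`` (e.g. to evaluate two models on
    identical partitions); otherwise folds are drawn from ``seed``.
    """
    n = len(obs)
    if folds is None:
        folds = kfold_split(n, k, seed)
    else:
        folds = np.asarray(folds, dtype=int)
        if folds.shape != (n,):
            raise InputError("folds must assign one fold index per observation")
        k = int(folds.max()) + 1
    preds = np.full(n, np.nan)
    fold_rmse = np.empty(k)
    fits = []
    pos = np.arange(n)
    actual = obs["sdw_g"].to_numpy(dtype=float)
    for i in range(k):
        test = folds == i
        train = ~test
        train_obs = obs.iloc[pos[train]]
        X_tr, _ = design_matrix(form, train_obs)
        if len(train_obs) <= X_tr.shape[1]:
            raise InputError(f"fold {i}: training part too small to fit {form!r}")
        fit = fit_model(form, train_obs)
        fits.append(fit)
        test_obs = obs.iloc[pos[test]]
        age = test_obs["age_days"].to_numpy() if "age_days" in test_obs.columns else None
        yhat = predict(fit, test_obs["area_mm2"].to_numpy(), age)
        preds[test] = yhat
        fold_rmse[i] = rmse(yhat, actual[test])
    return CVResult(
        form=form,
        fold_rmse=fold_rmse,
        mean_rmse=float(fold_rmse.mean()),
        pooled_rmse=rmse(preds, actual),
        predictions=pd.Series(preds, index=obs.index, name=f"sdw_pred_{form}"),
        folds=folds,
        fits=tuple(fits),
    )


@dataclasses.dataclass(frozen=True)
class ComparisonResult:
    """Paired comparison of two models' held-out squared errors (A minus B)."""

    mean_sq_error_diff: float  # mean(e_A² − e_B²); positive favours model B
    p_value: float
    n: int


def compare_models(pred_a, pred_b, actual) -> ComparisonResult:
    """Paired two-sided t-test on per-observation squared errors of two models.

    Both prediction vectors must cover the same observations (same fold
    assignment).  Identical predictions give difference 0 and p = 1.
    """
    pa, act = _paired(pred_a, actual)
    pb, act2 = _paired(pred_b, actual)
    if pa.shape != pb.shape:
        raise InputError("prediction vectors must have equal length")
    if pa.size < 2:
        raise InputError("paired comparison needs at least two observations")
    sq_a = (pa - act) ** 2
    sq_b = (pb - act2) ** 2
    diff = sq_a - sq_b
    if np.allclose(diff, 0.0):
        return ComparisonResult(mean_sq_error_diff=0.0, p_value=1.0, n=pa.size)
    t = stats.ttest_rel(sq_a, sq_b)
    return ComparisonResult(
        mean_sq_error_diff=float(diff.mean()),
        p_value=float(t.pvalue),
        n=pa.size,
    )


_STRATA_COLUMNS = {"treatment": "treatment", "variety": "variety", "age": "age_days"}


def stratified_report(
    predictions,
    obs: pd.DataFrame,
    by: str = "treatment",
) -> pd.DataFrame:
    """RMSE and MTE per stratum plus an overall row.

    ``by`` is one of ``treatment``, ``variety``, ``age`` or ``overall``.
    Returns a table with columns ``stratum, n, rmse_g, mte_g``; the overall
    row is always last.  Empty strata (unused categorical levels) are
    omitted with a logged warning.
    """
    p, a = _paired(predictions, obs["sdw_g"].to_numpy())
    rows = []
    if by != "overall":
        if by not in _STRATA_COLUMNS:
            raise InputError(
                f"unknown stratification {by!r}; expected treatment/variety/age/overall"
            )
        col = _STRATA_COLUMNS[by]
        if col not in obs.columns:
            raise InputError(f"phenotype table is missing column {col!r}")
        labels = obs[col]
        observed = pd.unique(labels)
        if isinstance(labels.dtype, pd.CategoricalDtype):
            for unused in set(labels.cat.categories) - set(observed):
                logger.warning("stratum %r is empty; omitted from report", unused)
        for level in observed:
            sel = (labels == level).to_numpy()
            rows.append(
                {
                    "stratum": level,
                    "n": int(sel.sum()),
                    "rmse_g": rmse(p[sel], a[sel]),
                    "mte_g": mte(p[sel], a[sel]),
                }
            )
    rows.append({"stratum": "overall", "n": p.size, "rmse_g": rmse(p, a), "mte_g": mte(p, a)})
    return pd.DataFrame(rows, columns=["stratum", "n", "rmse_g", "mte_g"])
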
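"""Multiple-regression model development, filtering and external validation.

The model space is every subset of 1–6 of the 16 activity-pattern predictors
(14,892 models for the full space).  Each candidate is fit by ordinary least
squares on the training cohort and passes *internal* validation iff all of

* VIF < 5 for every predictor (collinearity),
* R² > 0.5 (precision),
* RMSE < 3 MADRS units (accuracy)

hold strictly.  Surviving models are then *externally* validated on an
independent cohort with frozen coefficients: Pearson r between predicted and
observed scores must exceed the α = 0.05 critical value (0.576 at n = 12)
and test RMSE must stay below 3.  Greedy forward-stepwise selection (partial
F-test or AIC entry) provides the semi-supervised alternative to the brute
force, and two null references calibrate achieved accuracy: a dummy model
(constant test-mean prediction) and an empirical RMSE distribution from
random integer predictions in the observed score range.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import MODEL_FEATURES

#: internal / external validation thresholds (strict inequalities)
VIF_MAX = 5.0
R2_MIN = 0.5
RMSE_MAX = 3.0


class SingularDesignError(ValueError):
    """The design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FittedModel:
    predictors: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    standardized_coefficients: np.ndarray
    r_squared: float
    rmse: float
    vif: np.ndarray

    @property
    def size(self) -> int:
        return len(self.predictors)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[list(self.predictors)].to_numpy(dtype=float)
        return self.intercept + X @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "intercept": self.intercept,
            "coefficients": dict(zip(self.predictors, self.coefficients.tolist())),
            "standardized_coefficients": dict(
                zip(self.predictors, self.standardized_coefficients.tolist())),
            "r2": self.r_squared,
            "rmse": self.rmse,
            "vif": dict(zip(self.predictors, [float(v) for v in self.vif])),
        }


@dataclass
class ValidationResult:
    pearson_r: float
    rmse: float
    passed_internal: bool
    passed_external: bool
    undefined_r: bool = False


@dataclass
class NullDistribution:
    rmse_samples: np.ndarray
    n_sim: int
    value_range: tuple[int, int]
    seed: int

    def prob_at_most(self, x: float) -> float:
        """Empirical P(RMSE <= x)."""
        return float(np.searchsorted(self.rmse_samples, x, side="right")
                     / self.n_sim)


def _design(table: pd.DataFrame, predictors: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    X = table[list(predictors)].to_numpy(dtype=float)
    y = table["MADRS"].to_numpy(dtype=float)
    return X, y


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares with explicit intercept; returns (beta, residuals)."""
    A = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta, y - A @ beta


def vif(table: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    """Variance inflation factor per predictor: 1/(1 − R²_j) from regressing
    predictor j on the remaining ones.  Single-predictor models return 1;
    perfect collinearity yields +inf."""
    preds = list(predictors)
    if len(preds) == 1:
        return np.array([1.0])
    out = np.empty(len(preds))
    X = table[preds].to_numpy(dtype=float)
    for j in range(len(preds)):
        xj = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(xj)), others])
        beta, *_ = np.linalg.lstsq(A, xj, rcond=None)
        ssr = float(((xj - A @ beta) ** 2).sum())
        sst = float(((xj - xj.mean()) ** 2).sum())
        if sst == 0 or ssr / sst < 1e-12:
            out[j] = np.inf
        else:
            out[j] = 1.0 / (ssr / sst)
    return out


def fit_ols(table: pd.DataFrame, predictors: Sequence[str]) -> FittedModel:
    """Ordinary least squares of MADRS on the given predictor subset.

    RMSE uses the plain mean-squared-residual denominator so that train and
    test accuracies are directly comparable; standardized coefficient j is
    b_j · sd(x_j)/sd(y).
    """
    preds = tuple(predictors)
    if len(preds) == 0:
        raise ValueError("at least one predictor required")
    X, y = _design(table, preds)
    if len(y) < len(preds) + 2:
        raise ValueError("need at least p + 2 observations")
    beta, resid = _ols(X, y)
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = float((resid ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    sx = X.std(axis=0)
    sy = y.std()
    std_coef = beta[1:] * sx / sy if sy > 0 else np.full(len(preds), np.nan)
    return FittedModel(predictors=preds, intercept=float(beta[0]),
                       coefficients=beta[1:],
                       standardized_coefficients=std_coef,
                       r_squared=r2, rmse=rmse, vif=vif(table, preds))


# ---------------------------------------------------------------------------
# brute-force enumeration and internal filtering


def enumerate_models(feature_names: Sequence[str] = MODEL_FEATURES,
                     max_size: int = 6) -> Iterator[tuple[str, ...]]:
    """Yield every predictor subset of size 1..max_size exactly once, ordered
    by size then lexicographically in the given feature order."""
    names = list(feature_names)
    if len(set(names)) != len(names):
        raise ValueError("feature names must be distinct")
    if max_size > len(names):
        raise ValueError("max_size exceeds the number of features")
    for k in range(1, max_size + 1):
        yield from combinations(names, k)


def internal_filter(model: FittedModel, vif_max: float = VIF_MAX,
                    r2_min: float = R2_MIN, rmse_max: float = RMSE_MAX) -> bool:
    """True iff all three internal-validation inequalities hold strictly."""
    return (bool(np.all(model.vif < vif_max))
            and model.r_squared > r2_min
            and model.rmse < rmse_max)


def brute_force(table: pd.DataFrame,
                feature_names: Sequence[str] = MODEL_FEATURES,
                max_size: int = 6, vif_max: float = VIF_MAX,
                r2_min: float = R2_MIN,
                rmse_max: float = RMSE_MAX) -> tuple[list[FittedModel], int]:
    """Fit every candidate subset and keep internal-filter survivors.

    Returns (survivors, total number of candidates fitted).
    """
    survivors: list[FittedModel] = []
    total = 0
    for spec in enumerate_models(feature_names, max_size):
        total += 1
        try:
            model = fit_ols(table, spec)
        except SingularDesignError:
            continue
        if internal_filter(model, vif_max, r2_min, rmse_max):
            survivors.append(model)
    return survivors, total


# ---------------------------------------------------------------------------
# forward stepwise selection


def _aic(n: int, ssr: float, k: int) -> float:
    # Gaussian log-likelihood AIC; k regression coefficients + intercept
    return n * np.log(ssr / n) + 2 * (k + 1)


def stepwise_select(table: pd.DataFrame, criterion: str = "F",
                    excluded: Iterable[str] = (), max_size: int = 6,
                    feature_names: Sequence[str] = MODEL_FEATURES,
                    alpha_enter: float = 0.05) -> list[FittedModel]:
    """Greedy forward selection from the intercept-only model.

    criterion="F": at each step add the candidate with the smallest partial-F
    p-value, if below ``alpha_enter``.  criterion="AIC": add the candidate
    giving the largest AIC decrease, if any.  Ties break on feature order.
    Returns the sequence of fitted models of increasing size (possibly empty).
    """
    if criterion not in ("F", "AIC"):
        raise ValueError("criterion must be 'F' or 'AIC'")
    candidates = [f for f in feature_names if f not in set(excluded)]
    y = table["MADRS"].to_numpy(dtype=float)
    n = len(y)
    selected: list[str] = []
    path: list[FittedModel] = []
    ssr_current = float(((y - y.mean()) ** 2).sum())
    aic_current = _aic(n, ssr_current, 0) if ssr_current > 0 else -np.inf

    while len(selected) < max_size:
        best: tuple[float, str] | None = None
        for f in candidates:
            if f in selected:
                continue
            trial = selected + [f]
            try:
                X, _ = _design(table, trial)
                _, resid = _ols(X, y)
            except SingularDesignError:
                continue
            ssr = float((resid ** 2).sum())
            df_resid = n - len(trial) - 1
            if df_resid <= 0:
                continue
            if criterion == "F":
                if ssr <= 0:
                    pval = 0.0
                else:
                    fstat = (ssr_current - ssr) / (ssr / df_resid)
                    pval = float(stats.f.sf(max(fstat, 0.0), 1, df_resid))
                score = pval
            else:
                score = _aic(n, max(ssr, 1e-300), len(trial))
            if best is None or score < best[0]:
                best = (score, f)
        if best is None:
            break
        score, f = best
        if criterion == "F" and score >= alpha_enter:
            break
        if criterion == "AIC" and score >= aic_current:
            break
        selected.append(f)
        model = fit_ols(table, selected)
        path.append(model)
        X, _ = _design(table, selected)
        _, resid = _ols(X, y)
        ssr_current = float((resid ** 2).sum())
        aic_current = _aic(n, max(ssr_current, 1e-300), len(selected))
    return path


# ---------------------------------------------------------------------------
# external validation and null references


def critical_pearson_r(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical Pearson correlation at significance ``alpha``:
    r_crit = t/√(t² + n − 2) with t the α/2 upper t-quantile at n − 2 df."""
    if n < 3:
        raise ValueError("need n >= 3")
    t_crit = stats.t.ppf(1 - alpha / 2, n - 2)
    return float(t_crit / np.sqrt(t_crit ** 2 + n - 2))


def external_validate(model: FittedModel, test_table: pd.DataFrame,
                      r_min: float | None = None,
                      rmse_max: float = RMSE_MAX) -> ValidationResult:
    """Evaluate a frozen model on an independent cohort.

    ``r_min`` defaults to the α = 0.05 critical r for the test-set size.
    Zero-variance predictions leave r undefined and fail automatically.
    """
    y = test_table["MADRS"].to_numpy(dtype=float)
    if r_min is None:
        r_min = critical_pearson_r(len(y))
    pred = model.predict(test_table)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    internal = internal_filter(model)
    if np.std(pred) == 0 or np.std(y) == 0:
        return ValidationResult(pearson_r=np.nan, rmse=rmse,
                                passed_internal=internal,
                                passed_external=False, undefined_r=True)
    r = float(stats.pearsonr(pred, y).statistic)
    return ValidationResult(pearson_r=r, rmse=rmse, passed_internal=internal,
                            passed_external=(r > r_min and rmse < rmse_max))


def dummy_rmse(test_madrs: Sequence[float]) -> float:
    """RMSE of the constant test-mean prediction (= population SD)."""
    y = np.asarray(test_madrs, dtype=float)
    if y.size == 0:
        raise ValueError("empty score series")
    return float(np.std(y))


def random_null(test_madrs: Sequence[float], n_sim: int = 1_000_000,
                value_range: tuple[int, int] | None = None,
                seed: int = 0) -> NullDistribution:
    """Empirical RMSE distribution of uniform random integer predictions.

    Each simulated set draws one integer per test subject uniformly in
    ``value_range`` (default: the observed min–max, inclusive) and records
    the RMSE against the observed scores.  Samples are returned sorted.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    y = np.asarray(test_madrs, dtype=float)
    if value_range is None:
        value_range = (int(y.min()), int(y.max()))
    lo, hi = value_range
    if lo > hi:
        raise ValueError("range min must not exceed max")
    rng = np.random.default_rng(seed)
    out = np.empty(n_sim)
    chunk = 200_000
    for s in range(0, n_sim, chunk):
        m = min(chunk, n_sim - s)
        draws = rng.integers(lo, hi + 1, size=(m, len(y)))
        out[s:s + m] = np.sqrt(np.mean((draws - y) ** 2, axis=1))
    out.sort()
    return NullDistribution(rmse_samples=out, n_sim=n_sim,
                            value_range=(lo, hi), seed=seed)


# ---------------------------------------------------------------------------
# reporting analytics


def predictor_occurrence(models: Sequence[FittedModel],
                         feature_names: Sequence[str] = MODEL_FEATURES) -> pd.DataFrame:
    """Occurrence frequency of each predictor per model size, plus the
    across-size average; all values in [0, 1]."""
    if not models:
        raise ValueError("model list is empty")
    sizes = sorted({m.size for m in models})
    table = pd.DataFrame(0.0, index=list(feature_names),
                         columns=[*sizes, "average"])
    for k in sizes:
        of_size = [m for m in models if m.size == k]
        for f in feature_names:
            table.loc[f, k] = sum(f in m.predictors for m in of_size) / len(of_size)
    table["average"] = table[sizes].mean(axis=1)
    return table


def residual_profile(models: Sequence[FittedModel], table: pd.DataFrame,
                     thresholds: Sequence[float] = (1, 2, 3, 4, 5)) -> pd.DataFrame:
    """Proportion of absolute residuals below each threshold, per model and
    averaged across models (row 'average'); nondecreasing in the threshold."""
    y = table["MADRS"].to_numpy(dtype=float)
    rows = {}
    for i, m in enumerate(models):
        resid = np.abs(y - m.predict(table))
        rows[i] = [float(np.mean(resid < c)) for c in thresholds]
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"<{c}" for c in thresholds])
    df.loc["average"] = df.mean(axis=0)
    return df


def bland_altman(observed: Sequence[float],
                 predicted: Sequence[float]) -> dict[str, float]:
    """Mean difference (observed − predicted) and 95% limits of agreement."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("series must have equal length >= 2")
    diff = obs - pred
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return {"mean_diff": mean_diff,
            "loa_low": mean_diff - 1.96 * sd,
            "loa_high": mean_diff + 1.96 * sd}


def cohort_compare(train: pd.DataFrame, test: pd.DataFrame) -> pd.DataFrame:
    """Descriptive between-cohort comparison: mean/SD/min/max per continuous
    variable with a two-sided Student's t-test, and the sex ratio compared by
    a Pearson chi-square test (no continuity correction)."""
    rows = []
    numeric = [c for c in train.columns
               if c in test.columns and c not in ("id", "sex")
               and pd.api.types.is_numeric_dtype(train[c])]
    for c in numeric:
        a = train[c].to_numpy(dtype=float)
        b = test[c].to_numpy(dtype=float)
        if np.std(a) == 0 and np.std(b) == 0 and a.mean() == b.mean():
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        rows.append({"variable": c, "train_mean": a.mean(), "train_sd": a.std(ddof=1),
                     "train_min": a.min(), "train_max": a.max(),
                     "test_mean": b.mean(), "test_sd": b.std(ddof=1),
                     "test_min": b.min(), "test_max": b.max(), "p": p})
    if "sex" in train.columns and "sex" in test.columns:
        tab = np.array([
            [int((train["sex"] == 1).sum()), int((train["sex"] == 0).sum())],
            [int((test["sex"] == 1).sum()), int((test["sex"] == 0).sum())],
        ])
        if tab.sum(axis=0).min() > 0:
            p = float(stats.chi2_contingency(tab, correction=False).pvalue)
        else:
            p = 1.0
        rows.append({"variable": "sex", "train_mean": tab[0, 0], "train_sd": tab[0, 1],
                     "test_mean": tab[1, 0], "test_sd": tab[1, 1], "p": p})
    return pd.DataFrame(rows).set_index("variable")
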
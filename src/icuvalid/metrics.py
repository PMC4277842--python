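"""Performance statistics for probabilistic mortality predictions.

All statistics are implemented from first principles on (outcome, risk)
vectors:

* discrimination — the c index (probability a random death was given a
  higher risk than a random survivor, ties counted half; equals the area
  under the ROC curve), with standard error and paired model comparison via
  DeLong's structural components;
* calibration — the Hosmer-Lemeshow chi-squared over ten equal-sized groups
  by predicted probability, and Cox's calibration regression (logistic fit
  of observed survival on predicted survival log-odds; ideal intercept 0,
  slope 1, joint likelihood-ratio test on 2 df);
* accuracy / overall fit — Brier's score (mean squared error), Shapiro's R
  (geometric mean probability assigned to the realised outcome) and their
  scaled R-squared forms against the constant null model predicting the
  cohort event rate;
* Wilson score intervals for observed mortality proportions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .riskmodel import PredictionSet, LOG_ODDS_CLAMP

__all__ = [
    "ValidationReport",
    "c_index",
    "delong_test",
    "hosmer_lemeshow",
    "cox_calibration",
    "CoxCalibration",
    "brier_score",
    "ss_r2",
    "shapiro_r",
    "entropy_r2",
    "wilson_ci",
    "roc_points",
    "calibration_groups",
    "oe_ratio",
    "validate",
    "PROB_CLAMP",
]

#: probabilities are clamped to [eps, 1-eps] before any logarithm
PROB_CLAMP = 1e-10


def _as_arrays(preds) -> Tuple[np.ndarray, np.ndarray]:
    """Accept a PredictionSet or an (outcome, risk) pair."""
    if isinstance(preds, PredictionSet):
        return preds.outcome.astype(int), preds.predicted_risk.astype(float)
    y, p = preds
    return np.asarray(y, dtype=int), np.asarray(p, dtype=float)


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)


# ---------------------------------------------------------------------------
# Discrimination: c index and DeLong machinery
# ---------------------------------------------------------------------------

def _delong_components(y: np.ndarray, p: np.ndarray):
    """AUC plus DeLong structural components, via midranks in O(n log n).

    Returns (auc, v10, v01) where v10[i] is the empirical placement of death
    i among survivors and v01[j] the complement placement of survivor j.
    """
    deaths = p[y == 1]
    survivors = p[y == 0]
    m, n = len(deaths), len(survivors)
    if m == 0 or n == 0:
        raise ValueError("c index requires at least one death and one survivor")
    tz = stats.rankdata(np.concatenate([deaths, survivors]))
    tx = stats.rankdata(deaths)
    ty = stats.rankdata(survivors)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    return auc, v10, v01


def c_index(preds, level: float = 0.95):
    """c index with DeLong standard error and normal confidence interval.

    Equivalent to counting, over all death-survivor pairs, those where the
    death got the higher risk (ties counted half), divided by the number of
    pairs — computed via midranks rather than explicit pair enumeration.
    """
    y, p = _as_arrays(preds)
    auc, v10, v01 = _delong_components(y, p)
    m, n = len(v10), len(v01)
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) + (v01.var(ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(auc), se, (float(auc - z * se), float(auc + z * se))


def delong_test(preds_a, preds_b):
    """Paired comparison of two models' c indices on the same admissions.

    Returns (c_a, c_b, difference, variance, z, p_two_sided).  The variance
    of the difference comes from the paired covariance of the structural
    components; comparing a model with itself (or any strictly monotone
    transform of itself) yields difference 0 and p = 1.
    """
    if not isinstance(preds_a, PredictionSet) or not isinstance(preds_b, PredictionSet):
        raise TypeError("delong_test expects two PredictionSets")
    if len(preds_a) != len(preds_b) or not np.array_equal(
        np.sort(preds_a.admission_ids), np.sort(preds_b.admission_ids)
    ):
        raise ValueError("delong_test requires identical admission lists; "
                         "restrict both models to their intersection first")
    order_a = np.argsort(preds_a.admission_ids)
    order_b = np.argsort(preds_b.admission_ids)
    ya = preds_a.outcome[order_a]
    yb = preds_b.outcome[order_b]
    if not np.array_equal(ya, yb):
        raise ValueError("outcomes disagree between the two prediction sets")
    pa = preds_a.predicted_risk[order_a]
    pb = preds_b.predicted_risk[order_b]

    auc_a, v10a, v01a = _delong_components(ya, pa)
    auc_b, v10b, v01b = _delong_components(ya, pb)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(v10a, v10b, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01a, v01b, ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if diff == 0:
        z, p = 0.0, 1.0
    return float(auc_a), float(auc_b), float(diff), float(max(var, 0.0)), float(z), p


# ---------------------------------------------------------------------------
# Calibration: grouping, Hosmer-Lemeshow, Cox calibration regression
# ---------------------------------------------------------------------------

def calibration_groups(preds, n_groups: int = 10) -> pd.DataFrame:
    """Ten (by default) equal-sized groups ordered by predicted risk.

    Records with identical predicted risk stay in the same group, so with
    heavy ties the groups may be unequal (and fewer than requested).
    Columns: group, n, mean_risk, observed, expected.
    """
    y, p = _as_arrays(preds)
    n = len(y)
    if n == 0:
        raise ValueError("empty prediction set")
    order = np.argsort(p, kind="mergesort")
    ps, ys = p[order], y[order]
    grp = (np.arange(n) * n_groups) // n
    # pull each run of tied risks into the group of its first element
    change = np.flatnonzero(np.diff(ps) != 0) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [n]]))
    grp = np.repeat(grp[starts], lengths)
    rows = []
    for k, g in enumerate(np.unique(grp)):
        mask = grp == g
        rows.append(
            {
                "group": k + 1,
                "n": int(mask.sum()),
                "mean_risk": float(ps[mask].mean()),
                "observed": int(ys[mask].sum()),
                "expected": float(ps[mask].sum()),
            }
        )
    return pd.DataFrame(rows)


def hosmer_lemeshow(preds, n_groups: int = 10):
    """Hosmer-Lemeshow chi-squared over equal-sized risk groups.

    chi2 = sum over groups of (o - e)^2 / (n_g * pi_g * (1 - pi_g)) with
    pi_g the group's mean predicted risk; degrees of freedom equal the
    number of groups, the convention for externally developed models whose
    coefficients were not estimated on the validation data.

    Returns (chi2, df, p, calibration table).
    """
    table = calibration_groups(preds, n_groups=n_groups)
    pi = table["mean_risk"].to_numpy()
    if np.any((pi <= 0) | (pi >= 1)):
        raise ValueError("a group has degenerate mean predicted risk (0 or 1); "
                         "try fewer groups")
    ng = table["n"].to_numpy(float)
    o = table["observed"].to_numpy(float)
    e = table["expected"].to_numpy(float)
    chi2 = float(np.sum((o - e) ** 2 / (ng * pi * (1 - pi))))
    df = len(table)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p, table


@dataclass
class CoxCalibrationResult:
    intercept: float
    intercept_ci: Tuple[float, float]
    slope: float
    slope_ci: Tuple[float, float]
    chi2: float
    df: int
    p: float


class CoxCalibration:
    """Cox's calibration regression as a fit-style estimator.

    Fits a logistic regression of observed *survival* on the model's
    predicted log-odds of survival.  A perfectly calibrated model yields
    intercept 0 and slope 1; intercept < 0 means the model under-predicts
    risk overall, slope < 1 that it under-predicts the variability of risk.
    The joint test of (intercept, slope) = (0, 1) is a likelihood ratio
    against the offset model, chi-squared on 2 degrees of freedom (so
    p = exp(-chi2 / 2)).

    Attributes (after ``fit``): ``intercept_``, ``slope_``,
    ``intercept_ci_``, ``slope_ci_``, ``chi2_``, ``df_``, ``p_``.
    """

    def __init__(self, level: float = 0.95, maxiter: int = 200):
        self.level = level
        self.maxiter = maxiter

    def get_params(self, deep=True):
        return {"level": self.level, "maxiter": self.maxiter}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, preds, y=None) -> "CoxCalibration":
        if y is not None:
            p = np.asarray(preds, dtype=float)
            yv = np.asarray(y, dtype=int)
        else:
            yv, p = _as_arrays(preds)
        if yv.min() == yv.max():
            raise ValueError("Cox calibration requires both outcome classes")
        p = _clamp(p)
        # survival indicator on predicted survival log-odds
        s = 1 - yv
        x = np.clip(np.log((1 - p) / p), -LOG_ODDS_CLAMP, LOG_ODDS_CLAMP)
        exog = sm.add_constant(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(s, exog).fit(disp=0, maxiter=self.maxiter)
        if not res.mle_retvals.get("converged", False):
            raise RuntimeError(
                "Cox calibration logistic fit did not converge: "
                f"{res.mle_retvals}"
            )
        if np.max(np.abs(res.params)) > 50:
            raise RuntimeError("Cox calibration fit is degenerate (likely complete separation)")
        # offset model: linear predictor is the predicted survival log-odds itself
        q = expit(x)
        q = _clamp(q)
        ll_offset = float(np.sum(s * np.log(q) + (1 - s) * np.log(1 - q)))
        chi2 = max(2.0 * (float(res.llf) - ll_offset), 0.0)
        ci = res.conf_int(alpha=1 - self.level)
        ci = np.asarray(ci)
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.intercept_ci_ = (float(ci[0, 0]), float(ci[0, 1]))
        self.slope_ci_ = (float(ci[1, 0]), float(ci[1, 1]))
        self.chi2_ = chi2
        self.df_ = 2
        self.p_ = float(stats.chi2.sf(chi2, 2))
        return self

    def result(self) -> CoxCalibrationResult:
        return CoxCalibrationResult(self.intercept_, self.intercept_ci_, self.slope_,
                                    self.slope_ci_, self.chi2_, self.df_, self.p_)


def cox_calibration(preds, level: float = 0.95) -> CoxCalibrationResult:
    """Functional wrapper over :class:`CoxCalibration`."""
    return CoxCalibration(level=level).fit(preds).result()


# ---------------------------------------------------------------------------
# Accuracy / overall fit
# ---------------------------------------------------------------------------

def brier_score(preds) -> float:
    """Mean squared error between outcome and predicted risk."""
    y, p = _as_arrays(preds)
    return float(np.mean((y - p) ** 2))


def ss_r2(preds) -> float:
    """Sum-of-squares R²: Brier's score scaled against the constant null model."""
    y, p = _as_arrays(preds)
    pbar = y.mean()
    null = float(np.mean((y - pbar) ** 2))
    if null == 0:
        return 0.0
    return 1.0 - brier_score((y, p)) / null


def shapiro_r(preds) -> float:
    """Geometric mean of the probability assigned to the realised outcome."""
    y, p = _as_arrays(preds)
    p = _clamp(p)
    assigned = np.where(y == 1, p, 1 - p)
    return float(np.exp(np.mean(np.log(assigned))))


def entropy_r2(preds) -> float:
    """Entropy-based R²: Shapiro's R scaled against the constant null model."""
    y, p = _as_arrays(preds)
    r = shapiro_r((y, p))
    pbar = float(np.clip(y.mean(), PROB_CLAMP, 1 - PROB_CLAMP))
    r_null = shapiro_r((y, np.full(len(y), pbar)))
    if r_null >= 1.0:
        return 0.0
    return 1.0 - np.log(r) / np.log(r_null)


def oe_ratio(preds) -> float:
    """Observed deaths over expected deaths (sum of predicted risks)."""
    y, p = _as_arrays(preds)
    return float(y.sum() / p.sum())


# ---------------------------------------------------------------------------
# Wilson score interval
# ---------------------------------------------------------------------------

def wilson_ci(k: int, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Wilson score interval for a binomial proportion, as proportions in [0, 1]."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    z = stats.norm.ppf(0.5 + level / 2.0)
    phat = k / n
    denom = 1.0 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    lower = 0.0 if k == 0 else max(0.0, float(centre - half))
    upper = 1.0 if k == n else min(1.0, float(centre + half))
    return (lower, upper)


# ---------------------------------------------------------------------------
# ROC curve
# ---------------------------------------------------------------------------

def roc_points(preds) -> pd.DataFrame:
    """ROC coordinates (1 - specificity, sensitivity) at every distinct threshold.

    Includes the trivial endpoints (0,0) and (1,1); both coordinates are
    monotone non-decreasing and the trapezoidal area equals the c index
    under the ties-count-half convention.
    """
    y, p = _as_arrays(preds)
    m = int(y.sum())
    n = len(y) - m
    if m == 0 or n == 0:
        raise ValueError("ROC requires both outcome classes")
    order = np.argsort(-p, kind="mergesort")
    ps, ys = p[order], y[order]
    # cumulative counts at the end of each tie block (threshold = block value)
    block_end = np.flatnonzero(np.diff(ps) != 0)
    idx = np.concatenate([block_end, [len(ps) - 1]])
    tp = np.cumsum(ys)[idx]
    fp = np.cumsum(1 - ys)[idx]
    fpr = np.concatenate([[0.0], fp / n])
    tpr = np.concatenate([[0.0], tp / m])
    thr = np.concatenate([[np.inf], ps[idx]])
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


# ---------------------------------------------------------------------------
# The full report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Every performance statistic for one model on one cohort stratum."""

    model_name: str
    stratum: str
    n: int
    observed_deaths: int
    observed_mortality_pct: float
    wilson_ci_95: Tuple[float, float]  # percent bounds
    expected_mortality_pct: float
    c_index: float
    c_index_se: float
    c_index_ci_95: Tuple[float, float]
    hl_chi2: float
    hl_df: int
    hl_p: float
    cox_intercept: float
    cox_intercept_ci_95: Tuple[float, float]
    cox_slope: float
    cox_slope_ci_95: Tuple[float, float]
    cox_chi2: float
    cox_df: int
    cox_p: float
    brier: float
    ss_r2: float
    shapiro_r: float
    entropy_r2: float

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("wilson_ci_95", "c_index_ci_95", "cox_intercept_ci_95", "cox_slope_ci_95"):
            d[key] = list(d[key])
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationReport":
        d = dict(d)
        for key in ("wilson_ci_95", "c_index_ci_95", "cox_intercept_ci_95", "cox_slope_ci_95"):
            d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, text_or_path) -> "ValidationReport":
        try:
            doc = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path, encoding="utf-8") as fh:
                doc = json.load(fh)
        return cls.from_dict(doc)


def validate(preds: PredictionSet, n_groups: int = 10, stratum: str = "overall") -> ValidationReport:
    """Assemble the complete battery of statistics for one prediction set."""
    y, p = _as_arrays(preds)
    n = len(y)
    deaths = int(y.sum())
    lo_w, hi_w = wilson_ci(deaths, n)
    c, se, ci = c_index(preds)
    chi2, df, hp, _ = hosmer_lemeshow(preds, n_groups=n_groups)
    cox = cox_calibration(preds)
    return ValidationReport(
        model_name=preds.model_name if isinstance(preds, PredictionSet) else "model",
        stratum=stratum,
        n=n,
        observed_deaths=deaths,
        observed_mortality_pct=100.0 * deaths / n,
        wilson_ci_95=(100.0 * lo_w, 100.0 * hi_w),
        expected_mortality_pct=100.0 * float(p.mean()),
        c_index=c,
        c_index_se=se,
        c_index_ci_95=ci,
        hl_chi2=chi2,
        hl_df=df,
        hl_p=hp,
        cox_intercept=cox.intercept,
        cox_intercept_ci_95=cox.intercept_ci,
        cox_slope=cox.slope,
        cox_slope_ci_95=cox.slope_ci,
        cox_chi2=cox.chi2,
        cox_df=cox.df,
        cox_p=cox.p,
        brier=brier_score(preds),
        ss_r2=ss_r2(preds),
        shapiro_r=shapiro_r(preds),
        entropy_r2=entropy_r2(preds),
    )
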
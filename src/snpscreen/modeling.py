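"""Logistic-regression model comparison by AIC, with ROC/AUC summaries.

Genotypes enter the binary-outcome logistic regression additively, coded
0/1/2 minor-allele copies (a per-copy odds multiplier); clinical
covariates enter as given.  Models are ranked by AIC = -2 logLik +
2 n_par, and discrimination is summarized by the rank-based (Mann-
Whitney) AUC with a Youden-J operating point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

logger = logging.getLogger("snpscreen")

_SEPARATION_COEF = 15.0  # |logit coefficient| beyond which we flag quasi-separation


@dataclass
class LogisticFit:
    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    n_par: int
    converged: bool
    separation_flag: bool
    fitted: np.ndarray

    def predict(self) -> np.ndarray:
        return self.fitted


@dataclass
class RocSummary:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    operating_point: tuple[float, float, float]  # (threshold, sens, spec)


def fit_logistic(design: pd.DataFrame | np.ndarray, outcome: np.ndarray) -> LogisticFit:
    """Maximum-likelihood logistic fit (IRLS/Newton via statsmodels).

    An intercept is always prepended.  Quasi-separation (any coefficient
    beyond +-15 on the logit scale) sets ``separation_flag`` while the
    achieved log-likelihood is retained.
    """
    y = np.asarray(outcome, dtype=float)
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    n, k = X.shape
    if n != len(y):
        raise ValueError("design / outcome length mismatch")
    if n < k + 1:
        raise ValueError("more parameters than observations")
    for j in range(k):
        if np.all(X[:, j] == X[0, j]):
            raise ValueError(f"constant non-intercept column {names[j]!r}")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        # name the columns that are linear combinations of earlier ones
        aliased = []
        for j in range(1, Xc.shape[1]):
            if np.linalg.matrix_rank(Xc[:, : j + 1]) < j + 1:
                aliased.append(names[j - 1])
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    model = sm.Logit(y, Xc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=False, maxiter=100, tol=1e-10, method="newton")
        except Exception:
            # Newton's Hessian goes singular under (quasi-)separation;
            # a gradient method still drives the deviance toward its limit
            res = model.fit(disp=False, maxiter=1000, method="lbfgs")
    coefs = np.asarray(res.params)
    separated = bool(np.any(np.abs(coefs) > _SEPARATION_COEF))
    if separated:
        logger.warning("quasi-separation detected (|coef| > %g)", _SEPARATION_COEF)
    return LogisticFit(
        terms=["intercept"] + names,
        coefficients=coefs,
        standard_errors=np.asarray(res.bse),
        log_likelihood=float(res.llf),
        n_par=len(coefs),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation_flag=separated,
        fitted=np.asarray(res.predict()),
    )


def fit_intercept_only(outcome: np.ndarray) -> LogisticFit:
    """Null model: intercept = logit of the event rate, in closed form."""
    y = np.asarray(outcome, dtype=float)
    n1 = float(y.sum())
    n0 = float(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("outcome has a single class")
    rate = n1 / (n0 + n1)
    ll = n1 * np.log(rate) + n0 * np.log(1 - rate)
    return LogisticFit(["intercept"], np.array([np.log(n1 / n0)]),
                       np.array([np.sqrt(1 / n1 + 1 / n0)]), float(ll),
                       1, True, False, np.full(len(y), rate))


def aic(fit: LogisticFit) -> float:
    """AIC = -2 log-likelihood + 2 n_par (smaller is better)."""
    return -2.0 * fit.log_likelihood + 2.0 * fit.n_par


def roc_auc(scores: np.ndarray, outcome: np.ndarray) -> RocSummary:
    """ROC curve, rank-based AUC (ties counted 1/2), Youden operating point.

    The operating point maximizes sensitivity + specificity - 1; ties are
    broken toward higher sensitivity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = rankdata(s)  # midranks handle ties as 1/2 concordance
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    thresholds = np.unique(s)[::-1]
    sens = np.array([(s[y == 1] >= t).mean() for t in thresholds])
    spec = np.array([(s[y == 0] < t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())
    # among J-maximizers prefer the highest sensitivity
    pick = best[np.argmax(sens[best])]
    return RocSummary(thresholds, sens, spec, float(auc),
                      (float(thresholds[pick]), float(sens[pick]), float(spec[pick])))


def compare_models(model_specs: list[list[str]], data: pd.DataFrame,
                   outcome: np.ndarray) -> pd.DataFrame:
    """Fit every spec (a list of column names in ``data``; [] is the null
    model, which is always included) and rank by ascending AIC.

    Rows with a missing value in any used column are dropped per model
    (logged).  Returns (terms, n, AIC, AUC, sensitivity, specificity).
    """
    specs = [spec for spec in model_specs]
    if [] not in specs:
        specs = [[]] + specs
    y_all = np.asarray(outcome, dtype=float)
    rows = []
    for spec in specs:
        if spec:
            sub = data[spec].apply(pd.to_numeric, errors="coerce")
            keep = ~(sub.isna().any(axis=1).to_numpy() | np.isnan(y_all))
            dropped = int((~keep).sum())
            if dropped:
                logger.info("model %s: dropping %d row(s) with missing values",
                            "+".join(spec), dropped)
            y = y_all[keep]
            fit = fit_logistic(sub.loc[keep], y)
        else:
            keep = ~np.isnan(y_all)
            y = y_all[keep]
            fit = fit_intercept_only(y)
        roc = roc_auc(fit.fitted, y.astype(int))
        rows.append({
            "terms": "+".join(spec) if spec else "NULL",
            "n": int(len(y)),
            "AIC": aic(fit),
            "AUC": roc.auc,
            "sensitivity": roc.operating_point[1],
            "specificity": roc.operating_point[2],
            "separation_flag": fit.separation_flag,
        })
    return pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
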
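"""Logistic-regression estimators with odds-ratio inference.

Two fitting methods behind one scikit-learn style estimator:

* ``method="mle"`` — ordinary maximum likelihood through IRLS
  (delegated to statsmodels GLM with a Binomial family / logit link);
  Wald covariance from the inverse observed information.
* ``method="firth"`` — Jeffreys-prior penalized likelihood
  (Firth bias reduction), which yields finite estimates even under
  complete separation.  The penalized log-likelihood is

      l*(b) = l(b) + 0.5 * log det I(b)

  and the modified score adds ``h_i * (0.5 - p_i)`` to each residual,
  where ``h_i`` are the leverages of the weighted hat matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit
from sklearn.base import BaseEstimator

__all__ = ["LogitRegression", "SeparationWarning", "SingleClassError"]

INTERCEPT = "intercept"


class SeparationWarning(UserWarning):
    """Raised when an MLE fit shows signs of (quasi-)separation."""


class SingleClassError(ValueError):
    """Outcome has a single observed class; the model is not identified."""


def _as_matrix(X, feature_names):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{j}" for j in range(mat.shape[1])]
        )
    if len(names) != mat.shape[1]:
        raise ValueError("feature_names length does not match X columns")
    return mat, names


def _loglik(y, eta):
    # numerically stable Bernoulli log-likelihood: -sum log(1 + exp(-(2y-1) eta))
    s = (2.0 * y - 1.0) * eta
    return -np.sum(np.logaddexp(0.0, -s))


def _firth_fit(X, y, max_iter, tol, coef_tol):
    """Newton iterations with step-halving on the penalized likelihood."""
    n, p = X.shape
    beta = np.zeros(p)

    def penalized(beta):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = (X * w[:, None]).T @ X
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return -np.inf, mu, w, info
        return _loglik(y, eta) + 0.5 * logdet, mu, w, info

    pll, mu, w, info = penalized(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            chol = cho_factor(info)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate design
            break
        # leverages of W^1/2 X (X' W X)^-1 X' W^1/2
        XiXt = cho_solve(chol, X.T)
        h = w * np.einsum("ij,ji->i", X, XiXt)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = cho_solve(chol, score)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        # step-halving: accept only increases of the penalized likelihood
        scale = 1.0
        for _ in range(25):
            cand = beta + scale * step
            pll_new, mu_new, w_new, info_new = penalized(cand)
            if pll_new > pll - 1e-12:
                break
            scale *= 0.5
        delta = np.max(np.abs(scale * step))
        beta, pll, mu, w, info = cand, pll_new, mu_new, w_new, info_new
        if delta < coef_tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
        converged = False
    return beta, cov, pll, converged, it


def _mle_fit(X, y, max_iter, tol):
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=max_iter, tol=tol, scale=1.0)
    beta = np.asarray(res.params, dtype=float)
    cov = np.asarray(res.cov_params(), dtype=float)
    converged = bool(getattr(res, "converged", True))
    iterations = len(res.fit_history.get("deviance", [])) - 1
    return beta, cov, float(res.llf), converged, max(iterations, 0)


@dataclass
class _FitState:
    params: pd.Series = field(default_factory=pd.Series)
    cov: pd.DataFrame = field(default_factory=pd.DataFrame)


class LogitRegression(BaseEstimator):
    """Binary logistic regression reporting odds ratios.

    Parameters
    ----------
    method : {"mle", "firth"}
        Plain maximum likelihood or Firth's penalized likelihood.
    fit_intercept : bool
        Prepend a constant column (named ``"intercept"``).
    max_iter, tol, coef_tol :
        IRLS/Newton controls; convergence is declared when the largest
        absolute score falls below `tol` or the largest coefficient
        update falls below `coef_tol`.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Slopes (intercept excluded).
    intercept_ : float
    params_ : pandas.Series
        Full coefficient vector on the log-odds scale, intercept first.
    covariance_ : pandas.DataFrame
        Wald covariance of ``params_`` (inverse observed information;
        for Firth, evaluated at the penalized estimate).
    converged_, n_iter_, loglik_, n_obs_ : fit diagnostics.
    """

    def __init__(self, method="mle", fit_intercept=True, max_iter=100,
                 tol=1e-8, coef_tol=1e-10):
        self.method = method
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.tol = tol
        self.coef_tol = coef_tol

    def fit(self, X, y, feature_names=None):
        if self.method not in ("mle", "firth"):
            raise ValueError(f"unknown method {self.method!r}")
        mat, names = _as_matrix(X, feature_names)
        y = np.asarray(y, dtype=float).ravel()
        if mat.shape[0] != y.shape[0]:
            raise ValueError("X and y have different lengths")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("outcome must be binary 0/1")
        classes = np.unique(y)
        if classes.size < 2 and self.method == "mle":
            raise SingleClassError(
                "outcome has a single observed class; MLE is not identified"
            )
        if self.fit_intercept:
            mat = np.column_stack([np.ones(len(y)), mat])
            names = [INTERCEPT] + names

        if self.method == "mle":
            beta, cov, llf, converged, it = _mle_fit(mat, y, self.max_iter, self.tol)
            if converged and np.max(np.abs(beta)) > 15.0:
                converged = False
            if not converged:
                warnings.warn(
                    "MLE did not converge cleanly (possible separation); "
                    "consider method='firth'",
                    SeparationWarning,
                    stacklevel=2,
                )
        else:
            beta, cov, llf, converged, it = _firth_fit(
                mat, y, self.max_iter, self.tol, self.coef_tol
            )

        self.feature_names_in_ = np.asarray(
            names[1:] if self.fit_intercept else names, dtype=object
        )
        self.params_ = pd.Series(beta, index=names, name="log_odds")
        self.covariance_ = pd.DataFrame(cov, index=names, columns=names)
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self.classes_ = np.array([0.0, 1.0])
        self.converged_ = bool(converged)
        self.n_iter_ = int(it)
        self.loglik_ = float(llf)
        self.n_obs_ = int(len(y))
        return self

    def decision_function(self, X):
        mat, _ = _as_matrix(X, None)
        return self.intercept_ + mat @ self.coef_

    def predict_proba(self, X):
        p = expit(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(float)

    def odds_ratios(self, alpha=0.05):
        """Wald odds-ratio table (term, estimate, se, or, ci, p, stars)."""
        from scipy.stats import norm

        se = np.sqrt(np.clip(np.diag(self.covariance_.to_numpy()), 0.0, None))
        est = self.params_.to_numpy()
        z = norm.ppf(1.0 - alpha / 2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            zstat = np.where(se > 0, est / se, np.inf * np.sign(est))
        pvals = np.where(se > 0, 2.0 * norm.sf(np.abs(np.where(se > 0, zstat, 0.0))),
                         np.where(est == 0.0, 1.0, 0.0))
        stars = np.select(
            [pvals <= 0.001, pvals <= 0.01, pvals <= 0.05],
            ["***", "**", "*"],
            default="",
        )
        return pd.DataFrame(
            {
                "term": self.params_.index,
                "estimate": est,
                "se": se,
                "or": np.exp(est),
                "ci_low": np.exp(est - z * se),
                "ci_high": np.exp(est + z * se),
                "p": pvals,
                "stars": stars,
            }
        ).reset_index(drop=True)
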
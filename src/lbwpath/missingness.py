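"""Missingness diagnostics, chained-equation imputation, Rubin pooling.

The diagnostic regresses a missingness indicator (1 = missing) on
covariates expected to drive missingness; any covariate significant at
p <= 0.05 labels the variable MAR-consistent, otherwise MCAR-consistent.

Imputation runs chained equations over the two incompletely observed
variables: birth weight by predictive-mean matching (k = 5 donors,
Bayesian parameter draws), the binary wealth band by logistic draws.
The LBW flag is re-derived from each imputed weight.  Outcome variables
(stillbirth, death day) are never imputed; they enter the imputation
models as predictors only.  Completed datasets are pooled with Rubin's
rules: pooled estimate = mean, total variance T = W + (1 + 1/m) B, and
the small-sample degrees of freedom (m - 1)(1 + W / ((1 + 1/m) B))^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .cohort import Cohort
from .estimation import LogitFit, ModelSpec, design_matrix, model_frame
from .estimators import LogitRegression

__all__ = [
    "DiagnosticResult",
    "ImputationSet",
    "PooledFit",
    "MICEImputer",
    "missingness_diagnostic",
    "mice_impute",
    "pool_rubin",
]

#: predictor terms for the imputation models (everything observed, with
#: the outcome indicators as auxiliaries)
_PREDICTOR_TERMS = [
    "quarter[2]", "quarter[3]", "quarter[4]", "education_none",
    "age_band[<20]", "age_band[30+]", "birth_order_band[1]",
    "birth_order_band[5+]", "residence[rural]", "has_partner", "prior_loss",
    "multiple_birth", "child_sex[female]", "facility_delivery",
    "stillbirth", "early_neonatal_death", "late_neonatal_death",
]


@dataclass
class DiagnosticResult:
    """Missingness-indicator fit plus an MAR/MCAR-consistency verdict."""

    fit: LogitFit
    verdict: str
    p_values: pd.Series

    @property
    def mar_consistent(self):
        return self.verdict == "MAR-consistent"


def missingness_diagnostic(df, target, covariates, alpha=0.05):
    """Logistic model of the `target` missing-dummy on `covariates`."""
    df = df.df if isinstance(df, Cohort) else df
    indicator = df[target].isna().astype(float)
    n_miss = int(indicator.sum())
    if n_miss == 0 or n_miss == len(df):
        raise ValueError(
            f"nothing to diagnose: {target!r} has {n_miss} missing values"
        )
    X = design_matrix(df, list(covariates))
    keep = X.notna().all(axis=1)
    est = LogitRegression(method="mle").fit(X.loc[keep], indicator.loc[keep])
    spec = ModelSpec(
        outcome=f"missing[{target}]",
        terms=list(covariates),
        allow_lonely_interactions=True,
    )
    fit = LogitFit(
        spec=spec,
        params=est.params_,
        cov=est.covariance_,
        n_used=int(keep.sum()),
        method="mle",
        converged=est.converged_,
        iterations=est.n_iter_,
        loglik=est.loglik_,
    )
    table = fit.or_table().set_index("term")
    pvals = table["p"].drop(index="intercept")
    verdict = "MAR-consistent" if (pvals <= alpha).any() else "MCAR-consistent"
    return DiagnosticResult(fit=fit, verdict=verdict, p_values=pvals)


@dataclass
class ImputationSet:
    """m completed datasets sharing all observed cells."""

    m: int
    cohorts: list
    method_map: dict
    iterations: int
    seed: int


def _bayes_ols_draw(X, y, rng):
    """Posterior draw of (beta, sigma) under the standard OLS reference prior."""
    n, p = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta_hat = XtX_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2 = resid @ resid / rng.chisquare(dof)
    cov_chol = np.linalg.cholesky(XtX_inv + 1e-12 * np.eye(p))
    beta = beta_hat + np.sqrt(sigma2) * (cov_chol @ rng.standard_normal(p))
    return beta_hat, beta


def _pmm_impute(X_obs, y_obs, X_mis, rng, k=5):
    """Predictive-mean matching: donor values from the k nearest predictions."""
    beta_hat, beta_draw = _bayes_ols_draw(X_obs, y_obs, rng)
    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_draw
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    sorted_y = y_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    n_obs = len(sorted_pred)
    out = np.empty(len(pred_mis))
    for i, (p, j) in enumerate(zip(pred_mis, pos)):
        lo = max(j - k, 0)
        hi = min(j + k, n_obs)
        window = np.arange(lo, hi)
        dist = np.abs(sorted_pred[window] - p)
        donors = window[np.argsort(dist, kind="stable")[:k]]
        out[i] = sorted_y[donors[rng.integers(0, len(donors))]]
    return out


def _logistic_draw_impute(X_obs, y_obs, X_mis, rng):
    """Draw imputations for a binary variable from a posterior-perturbed fit."""
    est = LogitRegression(method="firth", fit_intercept=False)
    est.fit(X_obs, y_obs)
    cov = est.covariance_.to_numpy()
    cov = (cov + cov.T) / 2.0
    try:
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(cov)))
    except np.linalg.LinAlgError:
        chol = np.diag(np.sqrt(np.clip(np.diag(cov), 0, None)))
    beta = est.params_.to_numpy() + chol @ rng.standard_normal(len(cov))
    p = expit(X_mis @ beta)
    return (rng.random(len(p)) < p).astype(float)


class MICEImputer(BaseEstimator):
    """Multiple imputation by chained equations for cohort tables.

    Parameters
    ----------
    m : int
        Number of completed datasets (the study default is 100; tests
        run far fewer).
    iterations : int
        Chained-equation sweeps per dataset (>= 5 recommended).
    k_pmm : int
        Donor-pool size for predictive-mean matching of birth weight.
    random_state : int
        Seed; chains are seeded independently via SeedSequence spawning.
    """

    _methods = {"birth_weight_kg": "pmm", "wealth_band": "logistic"}

    def __init__(self, m=10, iterations=10, k_pmm=5, random_state=0):
        self.m = m
        self.iterations = iterations
        self.k_pmm = k_pmm
        self.random_state = random_state

    def fit(self, df):
        src = df.df if isinstance(df, Cohort) else df
        targets = [v for v in self._methods if src[v].isna().any()]
        for v in self._methods:
            if src[v].notna().sum() == 0:
                raise ValueError(f"variable {v!r} has no observed values")
        ss = np.random.SeedSequence(self.random_state)
        chains = []
        for child in ss.spawn(self.m):
            rng = np.random.default_rng(child)
            chains.append(self._one_chain(src, targets, rng))
        self.imputations_ = chains
        self.variables_ = targets
        return self

    def _predictors(self, work, exclude):
        frame = model_frame(work)
        cols = [t for t in _PREDICTOR_TERMS if t in frame.columns]
        X = frame[cols].to_numpy(dtype=float)
        aux = []
        if exclude != "wealth_band" and "wealth_band[less_poor]" in frame:
            aux.append(frame["wealth_band[less_poor]"].to_numpy(dtype=float))
        if exclude != "birth_weight_kg" and "lbw" in frame:
            aux.append(frame["lbw"].to_numpy(dtype=float))
        if aux:
            X = np.column_stack([X] + aux)
        return np.column_stack([np.ones(len(X)), X])

    def _one_chain(self, src, targets, rng):
        work = src.copy()
        miss = {v: src[v].isna().to_numpy() for v in targets}
        if not targets:
            return work
        # initialize by resampling observed values
        for v in targets:
            obs = src.loc[~miss[v], v].to_numpy()
            work.loc[miss[v], v] = rng.choice(obs, size=int(miss[v].sum()))
        for _ in range(max(self.iterations, 1)):
            if "birth_weight_kg" in targets:
                v = "birth_weight_kg"
                X = self._predictors(work, exclude=v)
                y = src[v].to_numpy(dtype=float)
                imputed = _pmm_impute(
                    X[~miss[v]], y[~miss[v]], X[miss[v]], rng, k=self.k_pmm
                )
                work.loc[miss[v], v] = imputed
            if "wealth_band" in targets:
                v = "wealth_band"
                X = self._predictors(work, exclude=v)
                y_obs = (src.loc[~miss[v], v] == "less_poor").to_numpy(float)
                draws = _logistic_draw_impute(
                    X[~miss[v]], y_obs, X[miss[v]], rng
                )
                work.loc[miss[v], v] = np.where(draws == 1.0, "less_poor",
                                                "poorer")
        return work

    def transform(self, df=None):
        return list(self.imputations_)


def mice_impute(df, m=10, iterations=10, seed=0, k_pmm=5) -> ImputationSet:
    """Chained-equation multiple imputation (see :class:`MICEImputer`)."""
    imp = MICEImputer(m=m, iterations=iterations, k_pmm=k_pmm,
                      random_state=seed).fit(df)
    return ImputationSet(
        m=m,
        cohorts=imp.imputations_,
        method_map=dict(MICEImputer._methods),
        iterations=iterations,
        seed=seed,
    )


@dataclass
class PooledFit:
    """Rubin-combined estimates over m imputed fits."""

    estimates: pd.Series
    within_var: pd.Series
    between_var: pd.Series
    total_var: pd.Series
    df: pd.Series
    m: int
    spec: ModelSpec | None = None

    def se(self):
        return np.sqrt(self.total_var)

    def or_table(self, alpha=0.05):
        from scipy import stats

        se = self.se()
        tq = np.where(
            np.isfinite(self.df), stats.t.ppf(1 - alpha / 2, self.df),
            stats.norm.ppf(1 - alpha / 2),
        )
        z = np.where(se > 0, self.estimates / se, np.inf)
        p = 2 * stats.t.sf(np.abs(z), np.where(np.isfinite(self.df),
                                               self.df, 1e9))
        return pd.DataFrame(
            {
                "term": self.estimates.index,
                "estimate": self.estimates.to_numpy(),
                "se": se.to_numpy(),
                "or": np.exp(self.estimates.to_numpy()),
                "ci_low": np.exp(self.estimates.to_numpy() - tq * se.to_numpy()),
                "ci_high": np.exp(self.estimates.to_numpy() + tq * se.to_numpy()),
                "p": p,
                "w_var": self.within_var.to_numpy(),
                "b_var": self.between_var.to_numpy(),
                "df": self.df.to_numpy(),
                "m": self.m,
            }
        ).reset_index(drop=True)


def pool_rubin(fits) -> PooledFit:
    """Combine m >= 2 fits of one model spec with Rubin's rules."""
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("Rubin pooling needs m >= 2 fits")
    index = fits[0].params.index
    for f in fits[1:]:
        if list(f.params.index) != list(index):
            raise ValueError("fits have mismatched model specifications")
    m = len(fits)
    est = np.vstack([f.params.to_numpy() for f in fits])
    var = np.vstack([np.diag(f.cov.to_numpy()) for f in fits])
    qbar = est.mean(axis=0)
    w = var.mean(axis=0)
    b = est.var(axis=0, ddof=1)
    t = w + (1.0 + 1.0 / m) * b
    with np.errstate(divide="ignore"):
        df = np.where(
            b > 0,
            (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2,
            np.inf,
        )
    mk = lambda a: pd.Series(a, index=index)
    return PooledFit(
        estimates=mk(qbar), within_var=mk(w), between_var=mk(b),
        total_var=mk(t), df=mk(df), m=m, spec=fits[0].spec,
    )
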
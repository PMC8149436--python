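"""Model specification, design encoding, and odds-ratio estimation.

Cohort tables carry the raw epidemiological codings (categorical bands,
0/1 flags, birth weight in kg, death day).  ``model_frame`` expands them
into a numeric frame of dummy columns with the study's reference
categories (weight >= 2.5 kg, community delivery, quarter 1, primary+
education, age 20-29, birth order 2-4, urban, no partner, no prior loss,
poorer, male, singleton) plus the derived outcome indicators:

``lbw``                   birth weight < 2.5 kg (missing when weight is)
``perinatal_death``       stillbirth or live-born death on days 0-6
``early_neonatal_death``  live-born death on days 0-6
``neonatal_death``        live-born death on days 0-27
``late_neonatal_death``   live-born death on days 7-27

Interaction terms are written ``"a:b"`` and resolved as column products.
Fits are complete-case: rows missing any model variable are dropped and
``n_used`` reports what remained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import LogitRegression

__all__ = [
    "ModelSpec",
    "LogitFit",
    "model_frame",
    "design_matrix",
    "fit_logistic",
    "fit_firth",
    "odds_ratio_table",
    "compute_vif",
    "wealth_index",
    "parse_formula",
]

#: default reference level per raw categorical column
REFERENCE_LEVELS = {
    "age_band": "20-29",
    "birth_order_band": "2-4",
    "residence": "urban",
    "wealth_band": "poorer",
    "child_sex": "male",
    "quarter": 1,
    "year": 2011,
    "facility_sector": "public",
}

_BINARY_COLS = [
    "education_none",
    "has_partner",
    "multiple_birth",
    "prior_loss",
    "facility_delivery",
    "stillbirth",
]


@dataclass
class ModelSpec:
    """Outcome plus ordered model terms (interactions as ``"a:b"``)."""

    outcome: str
    terms: list[str]
    reference_levels: dict = field(default_factory=dict)
    allow_lonely_interactions: bool = False
    name: str = ""

    def __post_init__(self):
        if self.outcome in self.terms:
            raise ValueError("outcome cannot appear among the model terms")
        if not self.allow_lonely_interactions:
            for t in self.terms:
                if ":" in t:
                    for part in t.split(":"):
                        if part not in self.terms:
                            raise ValueError(
                                f"interaction {t!r} lacks main effect {part!r}"
                            )


def parse_formula(formula, **kwargs):
    """Build a ModelSpec from ``"outcome ~ a + b + a:b"``."""
    lhs, _, rhs = formula.partition("~")
    terms = [t.strip() for t in rhs.split("+") if t.strip()]
    return ModelSpec(outcome=lhs.strip(), terms=terms, **kwargs)


def model_frame(df, reference_levels=None):
    """Expand a cohort table into a numeric model frame (see module doc)."""
    refs = dict(REFERENCE_LEVELS)
    if reference_levels:
        refs.update(reference_levels)
    out = pd.DataFrame(index=df.index)
    for col in _BINARY_COLS:
        if col in df:
            out[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    if "maternal_age" in df:
        out["maternal_age"] = df["maternal_age"].astype(float)
    for col, ref in refs.items():
        if col not in df:
            continue
        series = df[col]
        levels = [lv for lv in pd.unique(series.dropna()) if lv != ref]
        # stable ordering for deterministic column layout
        levels = sorted(levels, key=str)
        for lv in levels:
            dummy = (series == lv).astype(float)
            dummy[series.isna()] = np.nan
            out[f"{col}[{lv}]"] = dummy
    if "birth_weight_kg" in df:
        w = df["birth_weight_kg"].astype(float)
        lbw = (w < 2.5).astype(float)
        lbw[w.isna()] = np.nan
        out["lbw"] = lbw
    if "facility_delivery" in out:
        out["community_delivery"] = 1.0 - out["facility_delivery"]
    if "death_day" in df and "stillbirth" in df:
        dd = pd.to_numeric(df["death_day"], errors="coerce")
        live = df["stillbirth"].astype(float) == 0.0
        early = (live & (dd <= 6)).astype(float)
        out["early_neonatal_death"] = early
        out["perinatal_death"] = ((df["stillbirth"].astype(float) == 1.0) | (early == 1.0)).astype(float)
        out["neonatal_death"] = (live & (dd <= 27)).astype(float)
        out["late_neonatal_death"] = (live & (dd >= 7) & (dd <= 27)).astype(float)
    # any other numeric column passes through untouched (ad-hoc designs)
    handled = set(_BINARY_COLS) | set(refs) | {
        "maternal_age", "birth_weight_kg", "death_day",
    }
    for col in df.columns:
        if col in handled or col in out.columns:
            continue
        if pd.api.types.is_numeric_dtype(df[col]):
            out[col] = df[col].astype(float)
    return out


def _resolve_term(frame, term):
    if term in frame.columns:
        return frame[term]
    if ":" in term:
        parts = term.split(":")
        col = None
        for p in parts:
            piece = _resolve_term(frame, p)
            col = piece if col is None else col * piece
        return col
    raise KeyError(f"model term {term!r} not found in the model frame")


def design_matrix(df, terms, reference_levels=None, frame=None):
    """Numeric design (no constant) for `terms` over a cohort table."""
    if frame is None:
        frame = model_frame(df, reference_levels)
    data = {t: _resolve_term(frame, t) for t in terms}
    return pd.DataFrame(data, index=frame.index)


@dataclass
class LogitFit:
    """A fitted logistic model with Wald inference on the OR scale."""

    spec: ModelSpec
    params: pd.Series          # log-odds, "intercept" first
    cov: pd.DataFrame
    n_used: int
    method: str
    converged: bool
    iterations: int
    loglik: float
    message: str = ""

    @property
    def coefficients(self):
        return self.params.to_dict()

    def se(self):
        return pd.Series(
            np.sqrt(np.clip(np.diag(self.cov.to_numpy()), 0.0, None)),
            index=self.params.index,
        )

    def or_table(self, alpha=0.05):
        est = LogitRegression()
        est.params_ = self.params
        est.covariance_ = self.cov
        return est.odds_ratios(alpha=alpha)


def _fit(df, spec, method, **est_kwargs):
    frame = model_frame(df, spec.reference_levels)
    if spec.outcome not in frame.columns:
        raise KeyError(f"outcome {spec.outcome!r} not found in the model frame")
    X = design_matrix(df, spec.terms, frame=frame)
    y = frame[spec.outcome]
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X.loc[keep], y.loc[keep].astype(float)
    n_used = int(keep.sum())
    if n_used == 0:
        raise ValueError("no complete cases for this model specification")
    est = LogitRegression(method=method, **est_kwargs)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        est.fit(X, y)
    message = "; ".join(str(w.message) for w in caught) if caught else ""
    return LogitFit(
        spec=spec,
        params=est.params_,
        cov=est.covariance_,
        n_used=n_used,
        method=method,
        converged=est.converged_,
        iterations=est.n_iter_,
        loglik=est.loglik_,
        message=message,
    )


def fit_logistic(df, spec, **est_kwargs):
    """Maximum-likelihood logistic fit; flags separation and points to Firth."""
    return _fit(df, spec, "mle", **est_kwargs)


def fit_firth(df, spec, **est_kwargs):
    """Firth penalized logistic fit; finite even under complete separation."""
    return _fit(df, spec, "firth", **est_kwargs)


def odds_ratio_table(fit, alpha=0.05):
    """OR / 95% CI / Wald p table with significance stars."""
    return fit.or_table(alpha=alpha)


def compute_vif(df, covariates, reference_levels=None):
    """Variance inflation factors over the dummy-encoded covariate design.

    Returns a Series indexed by encoded column, ``inf`` for perfectly
    collinear columns; values >= 10 indicate problematic collinearity
    (see :func:`vif_flags`).
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    X = design_matrix(df, list(covariates), reference_levels).dropna()
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two covariate columns")
    exog = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, name in enumerate(X.columns, start=1):
            try:
                v = variance_inflation_factor(exog, j)
            except Exception:
                v = np.inf
            out[name] = np.inf if not np.isfinite(v) else float(v)
    return pd.Series(out, name="vif")


def vif_flags(vifs, cutoff=10.0):
    """Boolean flags for covariates at/above the collinearity cut-off."""
    return vifs >= cutoff


def wealth_index(asset_table, n_bands=5):
    """Asset-based wealth index from the first principal component.

    Standardizes the asset indicator columns, extracts the first PC with
    the sign oriented so ownership loads positively, ranks households
    into quintiles 1-5 and derives the binary band used in the models
    (quintiles 3-5 "less_poor" vs 1-2 "poorer").  Zero-variance columns
    are dropped with a warning.

    Returns
    -------
    scores : pandas.Series
    quintiles : pandas.Series of int (1..n_bands)
    band : pandas.Series in {"poorer", "less_poor"}
    """
    from sklearn.decomposition import PCA

    X = pd.DataFrame(asset_table).astype(float)
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("asset table needs >=2 rows and >=1 column")
    sd = X.std(ddof=0)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance asset columns: {dead}")
        X = X.drop(columns=dead)
        sd = sd.drop(dead)
    if X.shape[1] == 0:
        raise ValueError("no informative asset columns remain")
    Z = (X - X.mean()) / sd
    pca = PCA(n_components=1)
    scores = pca.fit_transform(Z.to_numpy())[:, 0]
    if pca.components_[0].sum() < 0:  # orient: owning assets -> richer
        scores = -scores
        pca.components_ = -pca.components_
    scores = pd.Series(scores, index=X.index, name="wealth_score")
    ranks = scores.rank(method="first")
    quintiles = pd.cut(ranks, bins=n_bands, labels=False).astype(int) + 1
    quintiles.name = "wealth_quintile"
    band = pd.Series(
        np.where(quintiles >= 3, "less_poor", "poorer"),
        index=X.index,
        name="wealth_band",
    )
    wealth_index.last_explained_variance_ratio_ = float(
        pca.explained_variance_ratio_[0]
    )
    return scores, quintiles, band
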
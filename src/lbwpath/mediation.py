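"""Product-of-coefficients mediation through low birth weight, and the
institutional-delivery moderation of the LBW effect.

For an exposure ``i`` with coefficient ``beta_xm`` in the LBW model,
LBW coefficient ``beta_my`` in the perinatal model and direct
coefficient ``beta_direct`` in the perinatal model (zero when the
exposure is excluded from that model), all on the log-odds scale:

    indirect   = beta_xm * beta_my
    total      = indirect + beta_direct
    proportion = 100 * |indirect / total|, carrying the sign of the
                 indirect effect

A structurally absent direct path (``beta_direct = 0``) gives exactly
+-100%.  Uncertainty comes from nonparametric case resampling with
percentile intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import Cohort
from .estimation import LogitFit, fit_firth, fit_logistic, model_frame
from .specs import DEFAULT_EXPOSURES, lbw_spec, perinatal_spec

__all__ = [
    "MediationResult",
    "MediationAnalysis",
    "indirect_effect",
    "proportion_mediated",
    "mediation_table",
    "fit_moderation",
    "moderation_label",
    "bootstrap_mediation",
]

LBW_TERM = "lbw"


def indirect_effect(beta_xm, beta_my):
    """Indirect (mediated) effect: the product of the two path coefficients."""
    if not (math.isfinite(beta_xm) and math.isfinite(beta_my)):
        raise ValueError("path coefficients must be finite")
    return beta_xm * beta_my


def proportion_mediated(beta_xm, beta_my, beta_direct):
    """Signed percentage of the total effect carried by the mediator.

    Magnitude is |indirect / (indirect + direct)| x 100; the sign is the
    sign of the indirect effect.  A zero total effect is undefined: a
    warning is issued and NaN returned.
    """
    ind = indirect_effect(beta_xm, beta_my)
    total = ind + beta_direct
    if total == 0.0:
        warnings.warn("total effect is zero; proportion mediated undefined")
        return float("nan")
    return 100.0 * abs(ind / total) * (1.0 if ind > 0 else -1.0 if ind < 0 else 0.0)


@dataclass
class MediationResult:
    """Mediation decomposition for one exposure."""

    exposure: str
    beta_xm: float          # exposure -> LBW
    beta_my: float          # LBW -> perinatal death
    beta_direct: float      # exposure -> perinatal death (0 if excluded)
    indirect: float
    total: float
    proportion_mediated_pct: float
    ci: tuple | None = None             # percentile CI for the indirect effect
    proportion_ci: tuple | None = None  # percentile CI for the proportion

    @classmethod
    def from_paths(cls, exposure, beta_xm, beta_my, beta_direct):
        ind = indirect_effect(beta_xm, beta_my)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prop = proportion_mediated(beta_xm, beta_my, beta_direct)
        return cls(
            exposure=exposure,
            beta_xm=beta_xm,
            beta_my=beta_my,
            beta_direct=beta_direct,
            indirect=ind,
            total=ind + beta_direct,
            proportion_mediated_pct=prop,
        )


def mediation_table(lbw_fit: LogitFit, pm_fit: LogitFit, exposures=None,
                    lbw_term=LBW_TERM):
    """One MediationResult per exposure, sorted by |proportion mediated|."""
    exposures = list(exposures) if exposures is not None else list(DEFAULT_EXPOSURES)
    if lbw_fit.spec.outcome != "lbw":
        raise ValueError("lbw_fit must model the lbw outcome")
    if lbw_term not in pm_fit.params.index:
        raise ValueError(f"{lbw_term!r} term absent from the perinatal model")
    beta_my = float(pm_fit.params[lbw_term])
    results = []
    for exp in exposures:
        if exp not in lbw_fit.params.index:
            raise ValueError(f"exposure {exp!r} absent from the LBW model")
        beta_xm = float(lbw_fit.params[exp])
        beta_direct = float(pm_fit.params.get(exp, 0.0))
        results.append(
            MediationResult.from_paths(exp, beta_xm, beta_my, beta_direct)
        )
    results.sort(
        key=lambda r: (
            -abs(r.proportion_mediated_pct)
            if math.isfinite(r.proportion_mediated_pct)
            else math.inf
        )
    )
    return results


def results_frame(results):
    """Mediation results as the exportable CSV table."""
    rows = []
    for r in results:
        rows.append(
            {
                "exposure": r.exposure,
                "beta_xm": r.beta_xm,
                "beta_my": r.beta_my,
                "beta_direct": r.beta_direct,
                "indirect": r.indirect,
                "total": r.total,
                "proportion_pct": r.proportion_mediated_pct,
                "ci_low": r.ci[0] if r.ci else np.nan,
                "ci_high": r.ci[1] if r.ci else np.nan,
                "prop_ci_low": r.proportion_ci[0] if r.proportion_ci else np.nan,
                "prop_ci_high": r.proportion_ci[1] if r.proportion_ci else np.nan,
            }
        )
    return pd.DataFrame(rows)


def fit_moderation(df, level="full", **fit_kwargs) -> LogitFit:
    """Perinatal model with the LBW x facility-delivery interaction.

    Falls back to the Firth fit (flagged in ``message``) when an empty
    LBW-by-facility event cell or non-convergence signals separation.
    """
    src = df.df if isinstance(df, Cohort) else df
    spec = perinatal_spec("full" if level == "full" else "adjusted2")
    frame = model_frame(src)
    events = frame[frame["perinatal_death"] == 1.0]
    cells = (
        events.groupby(
            [events["lbw"].fillna(-1), events["facility_delivery"]]
        ).size()
        if len(events)
        else pd.Series(dtype=int)
    )
    complete_cells = sum(
        1 for (l, f) in [(0, 0), (0, 1), (1, 0), (1, 1)]
        if cells.get((float(l), float(f)), 0) > 0
    )
    if complete_cells < 4:
        fit = fit_firth(src, spec, **fit_kwargs)
        fit.message = (
            "empty LBW x facility event cell; Firth fallback used"
            + (f"; {fit.message}" if fit.message else "")
        )
        return fit
    fit = fit_logistic(src, spec, **fit_kwargs)
    if not fit.converged:
        fb = fit_firth(src, spec, **fit_kwargs)
        fb.message = "MLE non-convergence; Firth fallback used"
        return fb
    return fit


def moderation_label(fit, interaction_term="lbw:facility_delivery"):
    """Qualitative read of the interaction: modest / substantial / none."""
    table = fit.or_table().set_index("term")
    row = table.loc[interaction_term]
    est = float(np.log(row["or"]))
    excludes_null = row["ci_low"] > 1.0 or row["ci_high"] < 1.0
    if excludes_null:
        return "substantial"
    if abs(est) < 0.2:
        return "modest"
    return "inconclusive"


def bootstrap_mediation(df, lbw_model=None, pm_model=None, exposures=None,
                        B=500, seed=0, lbw_term=LBW_TERM, alpha=0.05):
    """Percentile bootstrap CIs for the indirect effects and proportions.

    Nonparametric case resampling of birth records; replicates whose
    resample leaves an outcome single-classed (or a fit non-converged)
    are dropped and counted, with a warning above 10% dropped.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for stable percentile intervals")
    src = df.df if isinstance(df, Cohort) else df
    lbw_model = lbw_model or lbw_spec()
    pm_model = pm_model or perinatal_spec("full")
    exposures = list(exposures) if exposures is not None else list(DEFAULT_EXPOSURES)

    point = mediation_table(
        fit_logistic(src, lbw_model), fit_logistic(src, pm_model),
        exposures, lbw_term,
    )
    rng = np.random.default_rng(seed)
    n = len(src)
    draws = {r.exposure: [] for r in point}
    props = {r.exposure: [] for r in point}
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = src.iloc[idx]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lf = fit_logistic(boot, lbw_model)
                pf = fit_logistic(boot, pm_model)
            if not (lf.converged and pf.converged):
                dropped += 1
                continue
            rows = mediation_table(lf, pf, exposures, lbw_term)
        except Exception:
            dropped += 1
            continue
        for r in rows:
            draws[r.exposure].append(r.indirect)
            props[r.exposure].append(r.proportion_mediated_pct)
    if dropped > 0.10 * B:
        warnings.warn(
            f"{dropped}/{B} bootstrap replicates dropped "
            "(single-class or non-converged resamples)"
        )
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    for r in point:
        d = np.asarray(draws[r.exposure])
        p = np.asarray(props[r.exposure])
        p = p[np.isfinite(p)]
        if len(d):
            r.ci = (float(np.percentile(d, lo)), float(np.percentile(d, hi)))
        if len(p):
            r.proportion_ci = (
                float(np.percentile(p, lo)),
                float(np.percentile(p, hi)),
            )
    bootstrap_mediation.last_dropped_ = dropped
    return point


class MediationAnalysis(BaseEstimator):
    """End-to-end mediation analysis on a cohort table.

    Fits the adjusted LBW model and the fully adjusted perinatal model
    (complete cases), decomposes each exposure's effect into indirect
    and direct paths, and optionally bootstraps percentile intervals.

    Attributes (after ``fit``): ``lbw_fit_``, ``pm_fit_``,
    ``moderation_fit_``, ``results_`` (list of MediationResult) and
    ``table_`` (tidy DataFrame).
    """

    def __init__(self, exposures=None, pm_level="full", bootstrap=0,
                 random_state=0, lbw_term=LBW_TERM):
        self.exposures = exposures
        self.pm_level = pm_level
        self.bootstrap = bootstrap
        self.random_state = random_state
        self.lbw_term = lbw_term

    def fit(self, df):
        src = df.df if isinstance(df, Cohort) else df
        exposures = (
            list(self.exposures) if self.exposures is not None
            else list(DEFAULT_EXPOSURES)
        )
        self.lbw_fit_ = fit_logistic(src, lbw_spec())
        self.pm_fit_ = fit_moderation(src, level=self.pm_level)
        if self.bootstrap:
            self.results_ = bootstrap_mediation(
                src,
                lbw_model=lbw_spec(),
                pm_model=perinatal_spec(self.pm_level),
                exposures=exposures,
                B=self.bootstrap,
                seed=self.random_state,
                lbw_term=self.lbw_term,
            )
        else:
            self.results_ = mediation_table(
                self.lbw_fit_, self.pm_fit_, exposures, self.lbw_term
            )
        self.moderation_label_ = moderation_label(self.pm_fit_)
        self.table_ = results_frame(self.results_)
        return self
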
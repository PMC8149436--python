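"""Synthetic HDSS-style birth cohorts: generation, missingness, I/O.

One row per registered birth.  Covariates are drawn from configured
marginals, low birth weight from a logistic structural model over the
covariates, stillbirth and early neonatal death (days 0-6) from logistic
models sharing the perinatal slopes (intercepts calibrated separately to
the stillbirth and perinatal marginal rates), and late neonatal death
(days 7-27) from its own logistic model among first-week survivors.
Death days are allocated within the early window by the configured
day-bin split.  A MAR step can then mask birth weight (driven by
community delivery and perinatal death) and wealth (driven by maternal
age < 20).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm
from sklearn.base import BaseEstimator

from .config import GeneratorConfig, build_default_config
from .estimation import model_frame

__all__ = [
    "Cohort",
    "CohortGenerator",
    "generate_cohort",
    "apply_missingness",
    "calibrate_intercepts",
    "CalibrationError",
    "CohortSchemaError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "day7_survivors",
]

CSV_COLUMNS = [
    "year", "quarter", "maternal_age", "age_band", "residence",
    "education_none", "has_partner", "wealth_band", "birth_order_band",
    "multiple_birth", "prior_loss", "child_sex", "facility_delivery",
    "facility_sector", "birth_weight_kg", "stillbirth", "death_day",
]

_INT_COLS = ["year", "quarter", "education_none", "has_partner",
             "multiple_birth", "prior_loss", "facility_delivery", "stillbirth"]


class CalibrationError(RuntimeError):
    """A target rate is unreachable for any intercept value."""


class CohortSchemaError(ValueError):
    """A cohort file violates the schema or a record invariant."""


@dataclass
class Cohort:
    """An ordered collection of birth records with provenance."""

    df: pd.DataFrame
    seed: int | None = None
    config_digest: str = ""
    created: str = ""

    def __len__(self):
        return len(self.df)


def _frame_of(obj):
    return obj.df if isinstance(obj, Cohort) else obj


def _age_bands(age):
    return np.select([age < 20, age < 30], ["<20", "20-29"], default="30+")


def _linear_predictor(frame, coefs, extra=None):
    """Sum of coefficient * resolved column; names must resolve."""
    eta = np.full(len(frame), float(coefs.get("intercept", 0.0)))
    for name, value in coefs.items():
        if name == "intercept":
            continue
        if extra is not None and name in extra:
            col = extra[name]
        elif name in frame.columns:
            col = frame[name].to_numpy(dtype=float)
        elif ":" in name:
            col = np.ones(len(frame))
            for part in name.split(":"):
                sub = (
                    extra[part] if extra is not None and part in extra
                    else frame[part].to_numpy(dtype=float)
                )
                col = col * sub
        else:
            raise KeyError(f"coefficient {name!r} does not resolve to a column")
        eta = eta + float(value) * col
    return eta


def generate_cohort(config: GeneratorConfig | None = None, seed=None) -> Cohort:
    """Draw a fully observed cohort of ``config.n_births`` records."""
    config = config if config is not None else build_default_config()
    config.validate()
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    n = config.n_births
    m = config.covariate_marginals

    age_cfg = m["maternal_age"]
    a = (age_cfg["low"] - age_cfg["mean"]) / age_cfg["sd"]
    b = (age_cfg["high"] - age_cfg["mean"]) / age_cfg["sd"]
    age = truncnorm.rvs(a, b, loc=age_cfg["mean"], scale=age_cfg["sd"],
                        size=n, random_state=rng)

    order_probs = [
        m["birth_order_first"],
        1.0 - m["birth_order_first"] - m["birth_order_fifth_plus"],
        m["birth_order_fifth_plus"],
    ]
    facility = rng.random(n) < m["facility_delivery"]
    private = rng.random(n) < m["private_given_facility"]
    df = pd.DataFrame(
        {
            "year": rng.choice(np.asarray(m["years"], dtype=int), size=n),
            "quarter": rng.integers(1, 5, size=n),
            "maternal_age": age,
            "age_band": _age_bands(age),
            "residence": np.where(rng.random(n) < m["rural"], "rural", "urban"),
            "education_none": (rng.random(n) < m["education_none"]).astype(int),
            "has_partner": (rng.random(n) < m["has_partner"]).astype(int),
            "wealth_band": np.where(
                rng.random(n) < m["wealth_less_poor"], "less_poor", "poorer"
            ),
            "birth_order_band": rng.choice(
                np.array(["1", "2-4", "5+"]), size=n, p=order_probs
            ),
            "multiple_birth": (rng.random(n) < m["multiple_birth"]).astype(int),
            "prior_loss": (rng.random(n) < m["prior_loss"]).astype(int),
            "child_sex": np.where(rng.random(n) < m["female"], "female", "male"),
            "facility_delivery": facility.astype(int),
            "facility_sector": np.where(
                facility, np.where(private, "private", "public"), "none"
            ),
        }
    )

    frame = model_frame(df)

    # mediator: low birth weight, then a weight consistent with the flag
    p_lbw = expit(_linear_predictor(frame, config.lbw_coefficients))
    lbw = rng.random(n) < p_lbw
    weight = np.empty(n)
    n_lbw = int(lbw.sum())
    weight[lbw] = truncnorm.rvs(
        (0.8 - 2.15) / 0.30, (2.499 - 2.15) / 0.30, loc=2.15, scale=0.30,
        size=n_lbw, random_state=rng,
    )
    weight[~lbw] = truncnorm.rvs(
        (2.5 - 3.25) / 0.45, (5.5 - 3.25) / 0.45, loc=3.25, scale=0.45,
        size=n - n_lbw, random_state=rng,
    )
    df["birth_weight_kg"] = np.round(weight, 3)
    extra = {"lbw": lbw.astype(float)}

    # stillbirth: logistic sharing the perinatal slopes, own intercept
    p_sb = expit(_linear_predictor(frame, config.stillbirth_coefficients, extra))
    stillbirth = rng.random(n) < p_sb
    df["stillbirth"] = stillbirth.astype(int)

    # early neonatal death (days 0-6) among live births
    p_early = expit(_linear_predictor(frame, config.perinatal_coefficients, extra))
    early = (~stillbirth) & (rng.random(n) < p_early)

    # late neonatal death (days 7-27) among first-week survivors
    p_late = expit(
        _linear_predictor(frame, config.late_neonatal_coefficients, extra)
    )
    late = (~stillbirth) & (~early) & (rng.random(n) < p_late)

    s0, s1, _ = config.death_day_split
    death_day = np.full(n, np.nan)
    n_early = int(early.sum())
    if n_early:
        first_bin = rng.random(n_early) < (s0 / (s0 + s1) if s0 + s1 > 0 else 0.0)
        days = np.where(
            first_bin,
            rng.choice([0, 1], size=n_early, p=[0.75, 0.25]),
            rng.integers(2, 7, size=n_early),
        )
        death_day[early] = days
    n_late = int(late.sum())
    if n_late:
        death_day[late] = rng.integers(7, 28, size=n_late)
    df["death_day"] = death_day

    df = df[CSV_COLUMNS]
    return Cohort(
        df=df,
        seed=seed,
        config_digest=config.digest(),
        created=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
    )


def apply_missingness(cohort, config: GeneratorConfig | None = None, seed=0):
    """Mask birth weight and wealth under the configured MAR mechanisms."""
    config = config if config is not None else build_default_config()
    df = _frame_of(cohort).copy()
    rng = np.random.default_rng(seed)
    frame = model_frame(df)
    extra = {
        "community_delivery": 1.0 - frame["facility_delivery"].to_numpy(),
        "perinatal_death": frame["perinatal_death"].to_numpy(),
    }
    for var, mech in config.missingness.items():
        with np.errstate(invalid="ignore"):
            p = expit(_linear_predictor(frame, mech, extra))
        mask = rng.random(len(df)) < p
        df.loc[mask, var] = np.nan
    if isinstance(cohort, Cohort):
        return replace(cohort, df=df)
    return Cohort(df=df, seed=seed, config_digest=config.digest())


# ---------------------------------------------------------------------------
# calibration

_TARGET_ATTRS = {
    "lbw_prevalence": ("lbw_coefficients", "lbw_prevalence_target"),
    "stillbirth_rate": ("stillbirth_coefficients", "stillbirth_rate_target"),
    "perinatal_rate": ("perinatal_coefficients", "perinatal_rate_target"),
    "neonatal_rate": ("late_neonatal_coefficients", "neonatal_rate_target"),
    "weight_missingness": ("birth_weight_kg", None),
    "wealth_missingness": ("wealth_band", None),
}

#: calibration order honouring structural dependencies
_TARGET_ORDER = [
    "lbw_prevalence", "stillbirth_rate", "perinatal_rate", "neonatal_rate",
    "weight_missingness", "wealth_missingness",
]

_DEFAULT_TOL = {
    "lbw_prevalence": 0.005,          # +-0.5 pp
    "stillbirth_rate": 1.0,           # +-1 per 1000
    "perinatal_rate": 1.0,
    "neonatal_rate": 1.0,
    "weight_missingness": 0.005,
    "wealth_missingness": 0.005,
}


def _measure(config, name, seeds, mask_seeds):
    """Mean simulated value of a calibration target (common random numbers)."""
    vals = []
    for s, ms in zip(seeds, mask_seeds):
        coh = generate_cohort(config, seed=s)
        df = coh.df
        total = len(df)
        sb = int(df["stillbirth"].sum())
        live = total - sb
        dd = df["death_day"]
        if name == "lbw_prevalence":
            vals.append(float((df["birth_weight_kg"] < 2.5).mean()))
        elif name == "stillbirth_rate":
            vals.append(1000.0 * sb / total)
        elif name == "perinatal_rate":
            early = int((dd <= 6).sum())
            vals.append(1000.0 * (sb + early) / total)
        elif name == "neonatal_rate":
            vals.append(1000.0 * int((dd <= 27).sum()) / live)
        else:
            var = _TARGET_ATTRS[name][0]
            masked = apply_missingness(coh, config, seed=ms)
            vals.append(float(masked.df[var].isna().mean()))
    return float(np.mean(vals))


def _with_intercept(config, name, value):
    attr = _TARGET_ATTRS[name][0]
    if name in ("weight_missingness", "wealth_missingness"):
        mech = {k: dict(v) for k, v in config.missingness.items()}
        mech[attr]["intercept"] = value
        return replace(config, missingness=mech)
    coefs = dict(getattr(config, attr))
    coefs["intercept"] = value
    return replace(config, **{attr: coefs})


def calibrate_intercepts(config, targets, reps=30, seed=0, tol=None,
                         bracket=(-20.0, 3.0), max_bisect=40):
    """Tune intercepts by monotone bisection on Monte-Carlo rate estimates.

    `targets` maps target names (keys of the supported set: lbw_prevalence,
    stillbirth_rate, perinatal_rate, neonatal_rate, weight_missingness,
    wealth_missingness) to desired values — rates per 1000, prevalences
    and missing fractions as fractions.  Calibration proceeds in
    structural order (mediator before outcomes) with common random
    numbers, so the simulated rate is monotone in the intercept and the
    bisection is deterministic given `seed`.
    """
    unknown = set(targets) - set(_TARGET_ATTRS)
    if unknown:
        raise ValueError(f"unsupported calibration targets: {sorted(unknown)}")
    tol = {**_DEFAULT_TOL, **(tol or {})}
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(reps)]
    mask_seeds = [s + 1 for s in seeds]

    out = config
    for name in _TARGET_ORDER:
        if name not in targets:
            continue
        target = float(targets[name])
        lo, hi = bracket
        f_lo = _measure(_with_intercept(out, name, lo), name, seeds, mask_seeds)
        f_hi = _measure(_with_intercept(out, name, hi), name, seeds, mask_seeds)
        if target <= f_lo:
            # degenerate target at/below the floor: drive the rate to ~0
            out = _with_intercept(out, name, lo)
            continue
        if target > f_hi:
            raise CalibrationError(
                f"target {name}={target} unreachable (max simulated {f_hi:.4g})"
            )
        for _ in range(max_bisect):
            mid = 0.5 * (lo + hi)
            f_mid = _measure(_with_intercept(out, name, mid), name, seeds,
                             mask_seeds)
            if abs(f_mid - target) <= 0.25 * tol[name] or (hi - lo) < 1e-4:
                lo = hi = mid
                break
            if f_mid < target:
                lo = mid
            else:
                hi = mid
        out = _with_intercept(out, name, 0.5 * (lo + hi))
    return out


# ---------------------------------------------------------------------------
# validation and I/O

def validate_cohort(df):
    """Raise CohortSchemaError on the first violated record invariant."""
    df = _frame_of(df)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required columns: {missing}")
    dd = pd.to_numeric(df["death_day"], errors="coerce")
    sb = df["stillbirth"].astype(float)
    bad = dd.notna() & ((dd < 0) | (dd > 27) | (dd != dd.round()))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise CohortSchemaError(
            f"row {row}, column 'death_day': value {dd.iloc[row]!r} outside 0-27"
        )
    clash = (sb == 1) & dd.notna()
    if clash.any():
        row = int(np.flatnonzero(clash)[0])
        raise CohortSchemaError(
            f"row {row}, column 'death_day': stillbirth with a death day"
        )
    sector_none = df["facility_sector"].astype(str) == "none"
    fac = df["facility_delivery"].astype(float) == 1
    bad = sector_none == fac
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise CohortSchemaError(
            f"row {row}, column 'facility_sector': inconsistent with "
            "facility_delivery"
        )
    bands = pd.Series(_age_bands(df["maternal_age"].to_numpy(dtype=float)),
                      index=df.index)
    bad = bands != df["age_band"].astype(str)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise CohortSchemaError(
            f"row {row}, column 'age_band': inconsistent with maternal_age"
        )
    w = df["birth_weight_kg"].astype(float)
    bad = w.notna() & ((w <= 0) | (w > 8))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise CohortSchemaError(
            f"row {row}, column 'birth_weight_kg': implausible value"
        )
    return df


def write_cohort(cohort, path):
    """Write the standard cohort CSV (missing values as empty cells)."""
    df = _frame_of(cohort)[CSV_COLUMNS].copy()
    df["death_day"] = df["death_day"].astype("Int64")
    df.to_csv(path, index=False)
    return path


def read_cohort(path) -> Cohort:
    """Read and validate a cohort CSV."""
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise CohortSchemaError(f"cannot parse cohort file {path}: {exc}") from exc
    validate_cohort(df)
    df = df[CSV_COLUMNS].copy()
    for col in _INT_COLS:
        df[col] = df[col].astype(np.int64)
    df["maternal_age"] = df["maternal_age"].astype(float)
    df["birth_weight_kg"] = df["birth_weight_kg"].astype(float)
    df["death_day"] = pd.to_numeric(df["death_day"], errors="coerce").astype(float)
    return Cohort(df=df)


def day7_survivors(df):
    """Live births that survived the first week (late-neonatal risk set)."""
    df = _frame_of(df)
    dd = pd.to_numeric(df["death_day"], errors="coerce")
    keep = (df["stillbirth"].astype(float) == 0) & (dd.isna() | (dd >= 7))
    return df.loc[keep]


class CohortGenerator(BaseEstimator):
    """Estimator-style front end over the cohort generator.

    Parameters mirror :class:`GeneratorConfig`; ``config=None`` uses the
    calibrated default.  ``generate`` draws a fully observed cohort,
    ``generate_masked`` additionally applies the MAR mechanisms.
    """

    def __init__(self, config=None, with_missingness=False):
        self.config = config
        self.with_missingness = with_missingness

    def _config(self):
        cfg = self.config
        if cfg is None:
            return build_default_config()
        if isinstance(cfg, dict):
            return GeneratorConfig.from_dict(cfg)
        return cfg

    def generate(self, seed=None) -> Cohort:
        cfg = self._config()
        cohort = generate_cohort(cfg, seed=seed)
        if self.with_missingness:
            mask_seed = (cohort.seed + 1) % (2**31)
            cohort = apply_missingness(cohort, cfg, seed=mask_seed)
        return cohort

    # sklearn-style alias
    def sample(self, seed=None) -> Cohort:
        return self.generate(seed=seed)
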
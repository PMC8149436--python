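"""Generator configuration: marginals, structural log-odds, missingness.

The default configuration encodes the study world the analysis assumes:
covariate marginals of an Eastern-Ugandan HDSS birth register
(n = 10 758 births, 2011-2015), logistic structural models for low
birth weight, perinatal death and late neonatal death whose slopes are
the natural logs of the fully adjusted odds ratios, and MAR missingness
in birth weight (27%) and wealth (19%).  Intercepts are calibrated by
Monte-Carlo bisection (see :func:`lbwpath.cohort.calibrate_intercepts`)
to the marginal rates: stillbirths 12/1000 total births, perinatal
deaths 31/1000 total births, neonatal deaths 22/1000 live births, LBW
prevalence 10%.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

__all__ = ["GeneratorConfig", "build_default_config"]

_LN = math.log

# fully adjusted perinatal-mortality odds ratios (multiple birth excluded
# from this model because of its collinearity with LBW)
PERINATAL_OR = {
    "lbw": 2.55,
    "facility_delivery": 1.16,
    "lbw:facility_delivery": 0.91,
    "quarter[2]": 1.07,
    "quarter[3]": 1.23,
    "quarter[4]": 1.20,
    "education_none": 1.63,
    "age_band[<20]": 1.08,
    "age_band[30+]": 1.68,
    "birth_order_band[1]": 1.05,
    "birth_order_band[5+]": 0.38,
    "residence[rural]": 1.38,
    "has_partner": 0.75,
    "prior_loss": 3.95,
    "wealth_band[less_poor]": 0.85,
    "child_sex[female]": 1.05,
}

# adjusted low-birth-weight odds ratios
LBW_OR = {
    "quarter[2]": 1.12,
    "quarter[3]": 1.06,
    "quarter[4]": 1.03,
    "education_none": 1.14,
    "age_band[<20]": 1.40,
    "age_band[30+]": 0.98,
    "birth_order_band[1]": 0.88,
    "birth_order_band[5+]": 0.97,
    "residence[rural]": 1.40,
    "has_partner": 0.76,
    "prior_loss": 1.33,
    "multiple_birth": 3.12,
    "wealth_band[less_poor]": 0.92,
    "child_sex[female]": 1.12,
}

# adjusted late-neonatal odds ratios (LBW excluded for collinearity with
# multiple birth; no facility term in the adjusted model)
LATE_NEONATAL_OR = {
    "quarter[2]": 1.65,
    "quarter[3]": 1.64,
    "quarter[4]": 1.41,
    "education_none": 1.24,
    "age_band[<20]": 1.21,
    "age_band[30+]": 1.73,
    "birth_order_band[1]": 0.88,
    "birth_order_band[5+]": 1.89,
    "residence[rural]": 0.82,
    "has_partner": 0.54,
    "prior_loss": 3.17,
    "multiple_birth": 6.93,
    "wealth_band[less_poor]": 0.72,
    "child_sex[female]": 0.55,
}

# Monte-Carlo-calibrated intercepts for the default marginals (frozen;
# re-derivable with calibrate_intercepts, and verified by the test suite)
DEFAULT_INTERCEPTS = {
    "lbw": -2.363858,
    "stillbirth": -5.099656,
    "perinatal": -4.599280,
    "late_neonatal": -5.978213,
    "missing_weight": -1.323856,
    "missing_wealth": -1.600314,
}

DEFAULT_MARGINALS = {
    "rural": 0.64,
    "facility_delivery": 0.84,
    "private_given_facility": 0.15,
    "has_partner": 0.86,
    "education_none": 0.14,
    "wealth_less_poor": 0.53,
    "multiple_birth": 0.03,
    "prior_loss": 0.10,
    "birth_order_first": 0.20,
    "birth_order_fifth_plus": 0.25,
    "female": 0.50,
    "maternal_age": {"mean": 27.3, "sd": 6.5, "low": 13.0, "high": 49.0},
    "years": [2011, 2012, 2013, 2014, 2015],
}

#: names a structural coefficient may refer to (resolved in the model frame)
ALLOWED_TERMS = (
    set(PERINATAL_OR) | set(LBW_OR) | set(LATE_NEONATAL_OR)
    | {"community_delivery", "perinatal_death", "stillbirth", "maternal_age"}
)


def _log_or(table, intercept):
    out = {"intercept": float(intercept)}
    out.update({k: _LN(v) for k, v in table.items()})
    return out


@dataclass
class GeneratorConfig:
    """Full stated world for the synthetic birth-cohort generator."""

    n_births: int = 10758
    seed: int = 0
    covariate_marginals: dict = field(
        default_factory=lambda: json.loads(json.dumps(DEFAULT_MARGINALS))
    )
    lbw_coefficients: dict = field(
        default_factory=lambda: _log_or(LBW_OR, DEFAULT_INTERCEPTS["lbw"])
    )
    perinatal_coefficients: dict = field(
        default_factory=lambda: _log_or(PERINATAL_OR, DEFAULT_INTERCEPTS["perinatal"])
    )
    stillbirth_coefficients: dict = field(
        default_factory=lambda: _log_or(PERINATAL_OR, DEFAULT_INTERCEPTS["stillbirth"])
    )
    late_neonatal_coefficients: dict = field(
        default_factory=lambda: _log_or(
            LATE_NEONATAL_OR, DEFAULT_INTERCEPTS["late_neonatal"]
        )
    )
    death_day_split: tuple = (0.62, 0.255, 0.125)
    stillbirth_rate_target: float = 12.0
    perinatal_rate_target: float = 31.0
    neonatal_rate_target: float = 22.0
    lbw_prevalence_target: float = 0.10
    missingness: dict = field(
        default_factory=lambda: {
            "birth_weight_kg": {
                "intercept": DEFAULT_INTERCEPTS["missing_weight"],
                "community_delivery": 1.5,
                "perinatal_death": 1.0,
            },
            "wealth_band": {
                "intercept": DEFAULT_INTERCEPTS["missing_wealth"],
                "age_band[<20]": 1.0,
            },
        }
    )
    missingness_targets: dict = field(
        default_factory=lambda: {"birth_weight_kg": 0.27, "wealth_band": 0.19}
    )

    def __post_init__(self):
        self.death_day_split = tuple(float(p) for p in self.death_day_split)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self):
        if self.n_births < 1:
            raise ValueError("n_births must be >= 1")
        m = self.covariate_marginals
        for key, val in m.items():
            if key in ("maternal_age", "years"):
                continue
            if not 0.0 <= float(val) <= 1.0:
                raise ValueError(f"marginal {key!r}={val} outside [0, 1]")
        if (
            m["birth_order_first"] + m["birth_order_fifth_plus"] > 1.0
        ):
            raise ValueError("birth-order band probabilities exceed 1")
        split = self.death_day_split
        if len(split) != 3 or any(p < 0 for p in split):
            raise ValueError("death_day_split must be three non-negative shares")
        if abs(sum(split) - 1.0) > 1e-9:
            raise ValueError("death_day_split must sum to 1")
        for label, coefs in [
            ("lbw", self.lbw_coefficients),
            ("perinatal", self.perinatal_coefficients),
            ("stillbirth", self.stillbirth_coefficients),
            ("late_neonatal", self.late_neonatal_coefficients),
        ]:
            for name in coefs:
                if name != "intercept" and name not in ALLOWED_TERMS:
                    raise ValueError(
                        f"{label} coefficient {name!r} does not resolve to a "
                        "generated covariate"
                    )
        for var, mech in self.missingness.items():
            for name in mech:
                if name != "intercept" and name not in ALLOWED_TERMS:
                    raise ValueError(
                        f"missingness coefficient {name!r} ({var}) does not "
                        "resolve to a generated covariate"
                    )
        return self

    # -- (de)serialization ------------------------------------------------
    def to_dict(self):
        d = asdict(self)
        d["death_day_split"] = list(self.death_day_split)
        return d

    @classmethod
    def from_dict(cls, d):
        return cls(**d)

    def digest(self):
        """Stable SHA-256 digest of the configuration (provenance key)."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_default_config(**overrides) -> GeneratorConfig:
    """The calibrated default configuration (see module docstring)."""
    return GeneratorConfig(**overrides)
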
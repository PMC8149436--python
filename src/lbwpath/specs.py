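"""Default model specifications for the three study outcomes.

The perinatal ladder mirrors the staged adjustment of the analysis:
unadjusted (LBW only), + place of delivery, + the LBW x facility
interaction, then the fully adjusted model.  Multiple birth is excluded
from the perinatal model and LBW from the late-neonatal model — both
dropped for collinearity with each other (an explicit transformation,
not an automatic detector).  The late-neonatal model is fit on the
day-7+ survivor risk set (see :func:`lbwpath.cohort.day7_survivors`).
"""

from __future__ import annotations

from .estimation import ModelSpec

__all__ = [
    "COVARIATE_TERMS",
    "DEFAULT_EXPOSURES",
    "lbw_spec",
    "perinatal_spec",
    "late_neonatal_spec",
    "PERINATAL_LADDER",
]

#: shared socio-demographic adjustment set (study reference categories)
COVARIATE_TERMS = [
    "quarter[2]", "quarter[3]", "quarter[4]",
    "education_none",
    "age_band[<20]", "age_band[30+]",
    "birth_order_band[1]", "birth_order_band[5+]",
    "residence[rural]",
    "has_partner",
    "prior_loss",
    "wealth_band[less_poor]",
    "child_sex[female]",
]

#: the five mediation exposures, in the order reported
DEFAULT_EXPOSURES = [
    "residence[rural]",     # rural residence
    "age_band[<20]",        # adolescent mother
    "prior_loss",           # previous newborn or pregnancy loss
    "multiple_birth",
    "has_partner",
]

PERINATAL_LADDER = ("unadjusted", "adjusted1", "adjusted2", "full")


def lbw_spec() -> ModelSpec:
    """Adjusted low-birth-weight model (includes multiple birth)."""
    return ModelSpec(
        outcome="lbw",
        terms=COVARIATE_TERMS + ["multiple_birth"],
        name="lbw_adjusted",
    )


def perinatal_spec(level="full") -> ModelSpec:
    """One rung of the perinatal adjustment ladder."""
    if level == "unadjusted":
        terms = ["lbw"]
    elif level == "adjusted1":
        terms = ["lbw", "facility_delivery"]
    elif level == "adjusted2":
        terms = ["lbw", "facility_delivery", "lbw:facility_delivery"]
    elif level == "full":
        terms = (
            ["lbw", "facility_delivery", "lbw:facility_delivery"]
            + COVARIATE_TERMS
        )
    else:
        raise ValueError(f"unknown ladder level {level!r}")
    return ModelSpec(outcome="perinatal_death", terms=terms,
                     name=f"perinatal_{level}")


def late_neonatal_spec() -> ModelSpec:
    """Adjusted late-neonatal model (no LBW, no facility term)."""
    return ModelSpec(
        outcome="late_neonatal_death",
        terms=COVARIATE_TERMS + ["multiple_birth"],
        name="late_neonatal_adjusted",
    )
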
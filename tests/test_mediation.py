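"""Product-of-coefficients mediation and the LBW x facility moderation."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from lbwpath import (
    MediationAnalysis, bootstrap_mediation, build_default_config,
    fit_moderation, generate_cohort, indirect_effect, mediation_table,
    proportion_mediated,
)
from lbwpath.estimation import LogitFit, ModelSpec, fit_logistic
from lbwpath.mediation import moderation_label, results_frame
from lbwpath.specs import DEFAULT_EXPOSURES, lbw_spec, perinatal_spec

LN = math.log


def fit_from_coefficients(outcome, coefficients, se=0.1):
    """Assemble a LogitFit directly from known log-odds (printed ORs)."""
    params = pd.Series(coefficients)
    cov = pd.DataFrame(
        np.diag([se**2] * len(params)), index=params.index, columns=params.index
    )
    spec = ModelSpec(
        outcome=outcome,
        terms=[t for t in params.index if t != "intercept"],
        allow_lonely_interactions=True,
    )
    return LogitFit(spec=spec, params=params, cov=cov, n_used=0, method="mle",
                    converged=True, iterations=0, loglik=0.0)


# adjusted odds ratios from the published tables, as inputs
LBW_FIT = fit_from_coefficients(
    "lbw",
    {
        "intercept": -2.4,
        "residence[rural]": LN(1.40),
        "age_band[<20]": LN(1.40),
        "prior_loss": LN(1.33),
        "multiple_birth": LN(3.12),
        "has_partner": LN(0.76),
    },
)
PM_FIT = fit_from_coefficients(
    "perinatal_death",
    {
        "intercept": -4.5,
        "lbw": LN(2.55),
        "residence[rural]": LN(1.38),
        "age_band[<20]": LN(1.08),
        "prior_loss": LN(3.95),
        "has_partner": LN(0.75),
        # multiple_birth structurally excluded (collinearity with LBW)
    },
)


class TestIndirectEffect:
    @pytest.mark.parametrize(
        "bxm, bmy, expected",
        [
            (LN(3.12), LN(2.55), 1.0651),   # multiple births
            (0.0, LN(2.55), 0.0),
            (LN(0.76), LN(2.55), -0.2569),  # partner, protective
        ],
    )
    def test_products_from_printed_ors(self, bxm, bmy, expected):
        assert indirect_effect(bxm, bmy) == pytest.approx(expected, abs=5e-4)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            indirect_effect(float("nan"), 1.0)


class TestProportionMediated:
    def test_structurally_zero_direct_path_is_exactly_100(self):
        assert proportion_mediated(LN(3.12), LN(2.55), 0.0) == 100.0
        assert proportion_mediated(LN(0.5), LN(2.55), 0.0) == -100.0

    @pytest.mark.parametrize(
        "bxm, direct, expected",
        [
            (LN(1.33), LN(3.95), 16.27),   # prior loss
            (LN(1.40), LN(1.38), 49.44),   # rural residence
            (LN(0.76), LN(0.75), -47.17),  # partner: both paths protective
        ],
    )
    def test_signed_percentages_from_printed_ors(self, bxm, direct, expected):
        assert proportion_mediated(bxm, LN(2.55), direct) == pytest.approx(
            expected, abs=0.05
        )

    def test_null_mediator_path_gives_zero(self):
        assert proportion_mediated(0.0, LN(2.55), 0.5) == 0.0

    def test_zero_total_effect_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = proportion_mediated(LN(2.0), LN(2.0), -(LN(2.0) ** 2))
        assert math.isnan(out)


class TestMediationTable:
    def test_sign_pattern_and_ordering_from_printed_tables(self):
        rows = mediation_table(LBW_FIT, PM_FIT, DEFAULT_EXPOSURES)
        by_exposure = {r.exposure: r for r in rows}
        signs = {
            "residence[rural]": 1, "age_band[<20]": 1, "prior_loss": 1,
            "multiple_birth": 1, "has_partner": -1,
        }
        for exp, sign in signs.items():
            assert math.copysign(1, by_exposure[exp].proportion_mediated_pct) == sign
        assert by_exposure["multiple_birth"].proportion_mediated_pct == 100.0
        assert by_exposure["multiple_birth"].beta_direct == 0.0
        # sorted by |proportion mediated|, largest first
        props = [abs(r.proportion_mediated_pct) for r in rows]
        assert props == sorted(props, reverse=True)

    def test_conservation_indirect_plus_direct_is_total(self):
        for r in mediation_table(LBW_FIT, PM_FIT, DEFAULT_EXPOSURES):
            assert r.indirect + r.beta_direct == pytest.approx(r.total, abs=1e-12)

    def test_null_mediator_coefficient_zeroes_the_table(self):
        pm = fit_from_coefficients(
            "perinatal_death",
            {**PM_FIT.params.to_dict(), "lbw": 0.0},
        )
        rows = mediation_table(LBW_FIT, pm,
                               ["residence[rural]", "prior_loss", "has_partner"])
        assert all(r.proportion_mediated_pct == 0.0 for r in rows)

    def test_missing_lbw_term_rejected(self):
        pm = fit_from_coefficients("perinatal_death", {"intercept": -4.0,
                                                       "prior_loss": 1.0})
        with pytest.raises(ValueError, match="lbw"):
            mediation_table(LBW_FIT, pm, ["prior_loss"])

    def test_unknown_exposure_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            mediation_table(LBW_FIT, PM_FIT, ["education_none"])

    def test_reference_relabeling_flips_signs_keeps_magnitude(self, small_cohort):
        plain = mediation_table(
            fit_logistic(small_cohort.df, lbw_spec()),
            fit_logistic(small_cohort.df, perinatal_spec("full")),
            ["residence[rural]"],
        )[0]
        relab = {"residence": "rural"}
        swap = lambda terms: [t.replace("residence[rural]", "residence[urban]")
                              for t in terms]
        lbw_m = ModelSpec("lbw", swap(lbw_spec().terms), reference_levels=relab)
        pm_m = ModelSpec("perinatal_death", swap(perinatal_spec("full").terms),
                         reference_levels=relab)
        flipped = mediation_table(
            fit_logistic(small_cohort.df, lbw_m),
            fit_logistic(small_cohort.df, pm_m),
            ["residence[urban]"],
        )[0]
        assert flipped.beta_xm == pytest.approx(-plain.beta_xm, abs=1e-5)
        assert flipped.beta_direct == pytest.approx(-plain.beta_direct, abs=1e-5)
        assert abs(flipped.proportion_mediated_pct) == pytest.approx(
            abs(plain.proportion_mediated_pct), abs=1e-3
        )

    def test_sign_pattern_reproduced_across_replicates(self, default_config):
        # the five-exposure pattern (+, +, +, +, -) at the study size
        expected = {"residence[rural]": 1, "age_band[<20]": 1, "prior_loss": 1,
                    "multiple_birth": 1, "has_partner": -1}
        hits = 0
        reps = 40
        for r in range(reps):
            df = generate_cohort(default_config, seed=8000 + r).df
            rows = mediation_table(
                fit_logistic(df, lbw_spec()),
                fit_logistic(df, perinatal_spec("full")),
                DEFAULT_EXPOSURES,
            )
            ok = all(
                math.copysign(1, row.proportion_mediated_pct) == expected[row.exposure]
                for row in rows
            )
            hits += ok
        assert hits >= 36  # >= 90% of replicates (binomial slack on >= 95%)


class TestModeration:
    def test_null_interaction_recovered(self):
        cfg = build_default_config()
        coefs = dict(cfg.perinatal_coefficients)
        coefs["lbw:facility_delivery"] = 0.0
        cfg.perinatal_coefficients = coefs
        cfg.stillbirth_coefficients = {
            **cfg.stillbirth_coefficients, "lbw:facility_delivery": 0.0
        }
        ests = []
        for r in range(25):
            df = generate_cohort(cfg, seed=8500 + r).df
            fit = fit_moderation(df)
            ests.append(fit.params["lbw:facility_delivery"])
        sem = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests)) < 3 * sem + 0.02

    def test_empty_event_cell_falls_back_to_firth(self):
        from conftest import make_births

        df = make_births(400, day01=10)
        df.loc[:40, "birth_weight_kg"] = 2.0          # LBW facility births
        df.loc[200:280, "facility_delivery"] = 0      # community births
        df.loc[200:280, "facility_sector"] = "none"
        df.loc[300:320, "birth_weight_kg"] = 2.0      # LBW community births
        df.loc[300:320, "facility_delivery"] = 0
        df.loc[300:320, "facility_sector"] = "none"
        fit = fit_moderation(df, level="minimal")
        assert fit.method == "firth"
        assert "Firth fallback" in fit.message
        assert np.isfinite(fit.params).all()

    def test_moderation_label_modest_for_printed_interaction(self):
        # OR 0.91 (0.40 to 2.07): small log-odds, CI spanning the null
        se = LN(2.07 / 0.40) / (2 * 1.96)
        fit = fit_from_coefficients(
            "perinatal_death",
            {"intercept": -4.0, "lbw": LN(2.73), "facility_delivery": LN(1.06),
             "lbw:facility_delivery": LN(0.91)},
            se=se,
        )
        assert moderation_label(fit) == "modest"


class TestBootstrap:
    # the interaction-only perinatal rung keeps resamples well-behaved
    # (and fast) at the reduced test-cohort size
    PM_LIGHT = perinatal_spec("adjusted2")

    def test_minimum_replicates_enforced(self, small_cohort):
        with pytest.raises(ValueError, match="B"):
            bootstrap_mediation(small_cohort.df, B=50)

    def test_null_pathway_interval_covers_zero(self):
        cfg = build_default_config(n_births=3000)
        coefs = {k: (v if k == "intercept" else 0.0)
                 for k, v in cfg.lbw_coefficients.items()}
        cfg.lbw_coefficients = coefs
        df = generate_cohort(cfg, seed=21).df
        rows = bootstrap_mediation(df, pm_model=self.PM_LIGHT, B=120, seed=2,
                                   exposures=["residence[rural]"])
        lo, hi = rows[0].ci
        assert lo < 0 < hi

    def test_strong_pathway_interval_excludes_zero(self, cohort_10k):
        rows = bootstrap_mediation(cohort_10k.df, pm_model=self.PM_LIGHT,
                                   B=120, seed=3,
                                   exposures=["multiple_birth"])
        lo, hi = rows[0].ci
        assert lo > 0
        assert rows[0].proportion_ci == (100.0, 100.0)

    def test_endpoints_stable_when_doubling_B(self, cohort_10k):
        a = bootstrap_mediation(cohort_10k.df, pm_model=self.PM_LIGHT,
                                B=400, seed=4, exposures=["multiple_birth"])[0]
        b = bootstrap_mediation(cohort_10k.df, pm_model=self.PM_LIGHT,
                                B=800, seed=5, exposures=["multiple_birth"])[0]
        for x, y in zip(a.ci, b.ci):
            assert abs(x - y) <= 0.10 * max(abs(x), abs(y), 0.1)

    def test_reproducible_given_seed(self, small_cohort):
        a = bootstrap_mediation(small_cohort.df, pm_model=self.PM_LIGHT,
                                B=120, seed=6, exposures=["prior_loss"])[0]
        b = bootstrap_mediation(small_cohort.df, pm_model=self.PM_LIGHT,
                                B=120, seed=6, exposures=["prior_loss"])[0]
        assert a.ci == b.ci


class TestMediationAnalysis:
    def test_estimator_interface(self, cohort_10k):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            analysis = MediationAnalysis().fit(cohort_10k.df)
        assert len(analysis.results_) == 5
        table = results_frame(analysis.results_)
        assert set(table["exposure"]) == set(DEFAULT_EXPOSURES)
        assert analysis.moderation_label_ in {"modest", "substantial",
                                              "inconclusive"}
        assert analysis.get_params()["pm_level"] == "full"
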
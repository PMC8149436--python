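"""End-to-end orchestration: cohort -> screens -> models -> report bundle.

Stage order mirrors the analysis sequence: VIF screen, missingness
diagnostics, multiple imputation, bivariate fits, the adjusted perinatal
ladder (with moderation), a Firth sensitivity comparison, the mediation
table with bootstrap intervals, and rate/trend summaries.  Every
artifact is a CSV named in the returned manifest; the run log records
seeds, the config digest and per-stage wall time.  The main fits use
maximum likelihood (Firth runs as a sensitivity stage only, being far
slower over imputed datasets).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    Cohort, apply_missingness, day7_survivors, generate_cohort, read_cohort,
    write_cohort,
)
from .config import GeneratorConfig, build_default_config
from .estimation import compute_vif, fit_firth, fit_logistic, model_frame
from .mediation import (
    MediationAnalysis, fit_moderation, moderation_label, results_frame,
)
from .missingness import mice_impute, missingness_diagnostic, pool_rubin
from .rates import annual_trends, rate_summary
from .specs import (
    COVARIATE_TERMS, DEFAULT_EXPOSURES, PERINATAL_LADDER, late_neonatal_spec,
    lbw_spec, perinatal_spec,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

_DIAG_COVARIATES = {
    "birth_weight_kg": ["facility_delivery", "perinatal_death",
                        "residence[rural]"],
    "wealth_band": ["age_band[<20]", "residence[rural]", "education_none"],
}


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs."""

    cohort_path: str | None = None          # read this cohort ...
    generator: dict | None = None           # ... or generate one
    with_missingness: bool = True
    seed: int = 0
    mi_m: int = 10
    mi_iterations: int = 5
    bootstrap_B: int = 500
    out_dir: str = "report"

    @classmethod
    def from_dict(cls, d):
        return cls(**d)

    def generator_config(self) -> GeneratorConfig:
        if self.generator is None:
            return build_default_config()
        return GeneratorConfig.from_dict(self.generator)


def _bivariate_tables(df):
    rows = []
    singles = COVARIATE_TERMS + ["multiple_birth", "lbw", "facility_delivery"]
    for outcome, fitter_df, drop in [
        ("perinatal_death", df, None),
        ("late_neonatal_death", day7_survivors(df), None),
        ("lbw", df, "lbw"),
    ]:
        for term in singles:
            if term == drop:
                continue
            from .estimation import ModelSpec

            spec = ModelSpec(outcome=outcome, terms=[term],
                             name=f"bivariate_{outcome}")
            try:
                fit = fit_logistic(fitter_df, spec)
            except Exception:
                continue
            tab = fit.or_table().set_index("term")
            if term not in tab.index:
                continue
            r = tab.loc[term]
            rows.append(
                {
                    "outcome": outcome,
                    "term": term,
                    "or": r["or"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "p": r["p"],
                    "n_used": fit.n_used,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig):
    """Execute the full analysis; returns {artifact name: path}."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gen_cfg = config.generator_config()
    digest = gen_cfg.digest()
    manifest = {}
    log_lines = [
        f"config_digest: {digest}",
        f"seed: {config.seed}",
    ]

    def _stage(name):
        log_lines.append(f"stage: {name}")
        return time.perf_counter()

    def _done(t0):
        log_lines[-1] += f" ({time.perf_counter() - t0:.2f}s)"

    def _save(name, frame):
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        manifest[name] = str(path)

    stage = "load_cohort"
    try:
        t0 = _stage(stage)
        if config.cohort_path:
            cohort = read_cohort(config.cohort_path)
        else:
            cohort = generate_cohort(gen_cfg, seed=config.seed)
            if config.with_missingness:
                cohort = apply_missingness(
                    cohort, gen_cfg, seed=(config.seed + 1) % (2**31)
                )
        df = cohort.df
        write_cohort(cohort, out_dir / "cohort.csv")
        manifest["cohort"] = str(out_dir / "cohort.csv")
        _done(t0)

        stage = "vif_screen"
        t0 = _stage(stage)
        vifs = compute_vif(df, COVARIATE_TERMS + ["multiple_birth",
                                                  "facility_delivery"])
        _save("vif", vifs.rename_axis("term").reset_index())
        _done(t0)

        stage = "missingness_diagnostics"
        t0 = _stage(stage)
        diag_rows = []
        for var, covs in _DIAG_COVARIATES.items():
            if not df[var].isna().any():
                continue
            diag = missingness_diagnostic(df, var, covs)
            tab = diag.fit.or_table()
            tab.insert(0, "variable", var)
            tab["verdict"] = diag.verdict
            diag_rows.append(tab)
        if diag_rows:
            _save("missingness_diagnostics", pd.concat(diag_rows))
        _done(t0)

        stage = "multiple_imputation"
        t0 = _stage(stage)
        pooled_tables = {}
        if df[["birth_weight_kg", "wealth_band"]].isna().any().any():
            imp = mice_impute(df, m=config.mi_m,
                              iterations=config.mi_iterations,
                              seed=(config.seed + 2) % (2**31))
            for label, spec, subset in [
                ("perinatal", perinatal_spec("full"), None),
                ("lbw", lbw_spec(), None),
                ("late_neonatal", late_neonatal_spec(), day7_survivors),
            ]:
                fits = []
                for completed in imp.cohorts:
                    data = subset(completed) if subset else completed
                    fits.append(fit_logistic(data, spec))
                pooled = pool_rubin(fits)
                pooled_tables[label] = pooled
                _save(f"pooled_{label}", pooled.or_table())
        _done(t0)

        stage = "bivariate_fits"
        t0 = _stage(stage)
        _save("bivariate", _bivariate_tables(df))
        _done(t0)

        stage = "adjusted_ladder"
        t0 = _stage(stage)
        ladder_rows = []
        for level in PERINATAL_LADDER:
            fit = fit_logistic(df, perinatal_spec(level))
            tab = fit.or_table()
            tab.insert(0, "level", level)
            tab["n_used"] = fit.n_used
            ladder_rows.append(tab)
        _save("perinatal_ladder", pd.concat(ladder_rows))
        moderation = fit_moderation(df)
        log_lines.append(
            f"moderation: {moderation_label(moderation)} "
            f"(method={moderation.method})"
        )
        lnm_fit = fit_logistic(day7_survivors(df), late_neonatal_spec())
        _save("late_neonatal", lnm_fit.or_table())
        _done(t0)

        stage = "firth_sensitivity"
        t0 = _stage(stage)
        mle = fit_logistic(df, perinatal_spec("full"))
        firth = fit_firth(df, perinatal_spec("full"))
        comparison = pd.DataFrame(
            {
                "term": mle.params.index,
                "mle": mle.params.to_numpy(),
                "firth": firth.params.reindex(mle.params.index).to_numpy(),
            }
        )
        comparison["abs_diff"] = (comparison["mle"] - comparison["firth"]).abs()
        _save("firth_comparison", comparison)
        _done(t0)

        stage = "mediation"
        t0 = _stage(stage)
        analysis = MediationAnalysis(
            bootstrap=config.bootstrap_B, random_state=config.seed
        ).fit(df)
        _save("mediation", results_frame(analysis.results_))
        log_lines.append(
            "mediation exposures: "
            + ", ".join(r.exposure for r in analysis.results_)
        )
        _done(t0)

        stage = "rates"
        t0 = _stage(stage)
        summary = rate_summary(df)
        _save("rates", pd.DataFrame([summary.to_dict()]))
        _save("trends", annual_trends(df))
        _done(t0)
    except Exception as exc:
        log_lines.append(f"FAILED at {stage}: {exc}")
        (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        raise PipelineError(stage, exc) from exc

    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    manifest["run_log"] = str(out_dir / "run_log.txt")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump({"config_digest": digest, "artifacts": manifest}, fh,
                  indent=2)
    return manifest
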
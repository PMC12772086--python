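"""End-to-end orchestration of the behavioural-susceptibility analysis.

Two arms are run independently and joined at the breed level:

* **questionnaire arm** — score Likert answers, apply inclusion filters,
  fit the minimal food-motivation model (sex/neuter/age with two-way
  interactions, reduced by stepwise AIC), compute breed-adjusted food
  motivation and breed averages;
* **clinic (EHR) arm** — one random visit per dog, 5-point BCS collapsed
  to three categories, two Firth binomial fits merged into a multinomial,
  standardized per-breed probabilities with simulation CIs.

The arms are joined by breed (inner join) to estimate the breed-level
association between average food motivation and overweight/obesity
probability; individual-level correlations, model comparisons and the
tertile-stratified interaction analysis complete the report.  Every output
is written under a run directory alongside a manifest (seeds, config hash,
package versions) sufficient to re-run the pipeline bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    apply_questionnaire_filters,
    assign_tertiles,
    breed_average,
    eligible_ehr_breeds,
    recode_bcs_column,
    select_random_visit,
    FilterReport,
)
from .errors import PipelineError
from .firth import (
    breed_probability_table,
    fit_category_models,
    population_age_distribution,
    EhrDesign,
)
from .io import read_table, write_table
from .regression import (
    compare_models,
    extract_tertile_effects,
    fit_ols,
    one_way_anova,
    pairwise_t_holm,
    pearson_cor,
    adjusted_fms,
    stepwise_aic,
    MANAGEMENT_TERMS,
)
from .scoring import default_items, load_items, score_cohort
from .synthetic import SimConfig, generate_ehr_cohort, generate_questionnaire_cohort

log = logging.getLogger("bst.pipeline")

CORR_COLUMNS = ["bcs_owner_9pt", "fms", "ocs", "owner_intervention",
                "restriction_human_food", "exercise_taken"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    # inputs: either file paths, or None to simulate with `sim`
    questionnaire_path: str | None = None
    ehr_path: str | None = None
    items_path: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)

    # cohort rules
    min_age: float = 1.0
    max_age: float = 19.0
    min_bcs: float = 3.0
    breed_min_n: int = 10
    ehr_min_cell_mean: float = 0.0   # 0 disables the sex x age cell-count rule

    # modelling
    categorical_age: bool = False
    include_breed_interactions: bool = True
    n_draws: int = 1000
    ci_level: float = 0.95

    # seeds (visit selection and CI simulation are separate draws)
    visit_seed: int = 2001
    ci_seed: int = 2002

    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        if "ehr_age_range" in asdict(sim):
            sim.ehr_age_range = tuple(sim.ehr_age_range)
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        """The analysis-defining configuration (output location excluded, so
        identical analyses hash identically wherever they are written)."""
        d = asdict(self)
        d["sim"]["ehr_age_range"] = list(d["sim"]["ehr_age_range"])
        d.pop("output_dir")
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class AnalysisReport:
    """All result tables of one pipeline run, plus the manifest."""

    scored_summary: dict
    filter_report: FilterReport
    breed_fms_table: pd.DataFrame
    breed_anova: dict
    breed_probability_table: pd.DataFrame
    breed_association: dict
    correlation_matrix: pd.DataFrame
    bcs_model_comparison: pd.DataFrame
    fm_model_comparison: pd.DataFrame
    tertile_effects: pd.DataFrame
    tertile_model: dict
    tertile_descriptives: pd.DataFrame
    tertile_pairwise: pd.DataFrame
    manifest: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(self.breed_fms_table, outdir / "breed_fms.csv")
        write_table(self.breed_probability_table, outdir / "breed_probabilities.csv")
        write_table(self.correlation_matrix, outdir / "correlation_matrix.csv")
        write_table(self.bcs_model_comparison, outdir / "bcs_model_comparison.csv")
        write_table(self.fm_model_comparison, outdir / "fm_model_comparison.csv")
        write_table(self.tertile_effects, outdir / "tertile_effects.csv")
        write_table(self.tertile_descriptives, outdir / "tertile_descriptives.csv")
        write_table(self.tertile_pairwise, outdir / "tertile_pairwise.csv")
        scalars = {
            "scored_summary": self.scored_summary,
            "filter_report": self.filter_report.to_json_dict(),
            "breed_anova": self.breed_anova,
            "breed_association": self.breed_association,
            "tertile_model": self.tertile_model,
        }
        (outdir / "summary.json").write_text(
            json.dumps(scalars, indent=2, sort_keys=True) + "\n")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s starting", name)
                out = fn(*args, **kwargs)
                log.info("stage %s done", name)
                return out
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - wrapped with stage context
                raise PipelineError(name, str(exc), cause=exc) from exc
        return wrapper
    return deco


def _add_numeric_codes(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    out["sex_male"] = (out["sex"] == "male").astype(float)
    out["neutered"] = (out["neuter"] == "neutered").astype(float)
    return out


@_stage("load_inputs")
def _load_inputs(config: PipelineConfig):
    for path in (config.questionnaire_path, config.ehr_path, config.items_path):
        if path is not None and not os.path.exists(path):
            raise FileNotFoundError(f"input file does not exist: {path}")
    items = load_items(config.items_path) if config.items_path else default_items()
    if config.questionnaire_path is not None:
        raw_q = read_table(config.questionnaire_path)
        truth = None
    else:
        raw_q, truth = generate_questionnaire_cohort(config.sim)
    if config.ehr_path is not None:
        raw_e = read_table(config.ehr_path)
    else:
        raw_e, _ = generate_ehr_cohort(config.sim)
    return raw_q, raw_e, items, truth


def run_full_analysis(config: PipelineConfig) -> AnalysisReport:
    """Run the whole analysis; any stage failure aborts with the stage name.

    Input files are checked before any output is produced, and all
    randomness is controlled by the seeds recorded in the manifest.
    """
    raw_q, raw_e, items, truth = _load_inputs(config)

    # questionnaire arm -----------------------------------------------------
    scored = _stage("score")(score_cohort)(raw_q, items)
    scored = _add_numeric_codes(scored)
    filtered, filter_report = _stage("filter")(apply_questionnaire_filters)(
        scored, min_age=config.min_age, max_age=config.max_age,
        min_bcs=config.min_bcs)
    log.info("filter retained %d / %d rows", filter_report.n_retained,
             filter_report.n_input)

    @_stage("fm_minimal_model")
    def _fm_model(frame):
        return stepwise_aic(
            ["sex_male*neutered", "sex_male*age_years", "neutered*age_years"],
            frame, "fms")

    fm_fit = _fm_model(filtered)
    filtered = filtered.copy()
    filtered["adjusted_fms"] = _stage("adjusted_fms")(adjusted_fms)(filtered, fm_fit)

    breed_fms = _stage("breed_average_fms")(breed_average)(
        filtered, "adjusted_fms", min_n=config.breed_min_n)
    groups = [g["adjusted_fms"].to_numpy()
              for _, g in filtered[filtered["breed"].isin(breed_fms["breed"])]
              .groupby("breed")]
    f_stat, f_p = _stage("breed_anova")(one_way_anova)(groups)

    # clinic arm ------------------------------------------------------------
    one_visit = _stage("select_visit")(select_random_visit)(raw_e, config.visit_seed)
    one_visit = _stage("recode_bcs")(recode_bcs_column)(one_visit)
    if config.ehr_min_cell_mean > 0:
        keep = eligible_ehr_breeds(one_visit, config.ehr_min_cell_mean)
        one_visit = one_visit[one_visit["breed"].isin(keep)]

    @_stage("firth_multinomial")
    def _firth(records):
        design = EhrDesign.from_records(
            records, categorical_age=config.categorical_age,
            include_interactions=config.include_breed_interactions)
        fit_u, fit_o, design = fit_category_models(records, design)
        return fit_u, fit_o, design

    fit_u, fit_o, design = _firth(one_visit)

    @_stage("standardized_probabilities")
    def _probs():
        ages = population_age_distribution(one_visit)
        return breed_probability_table(
            fit_u, fit_o, design, ages, n_draws=config.n_draws,
            level=config.ci_level, seed=config.ci_seed)

    breed_probs = _probs()

    # breed-level join ------------------------------------------------------
    @_stage("breed_association")
    def _associate():
        joined = breed_fms.merge(breed_probs, on="breed", how="inner",
                                 validate="one_to_one")
        r, p = pearson_cor(joined["mean_value"], joined["p_overweight_obese"])
        linfit = fit_ols(["mean_value"], joined, "p_overweight_obese")
        return joined, {
            "n_breeds": int(len(joined)),
            "pearson_r": r,
            "pearson_p": p,
            "r_squared": linfit.r_squared,
            "slope": linfit.coef("mean_value"),
            "regression_p": float(linfit.p_values[
                linfit.term_names.index("mean_value")]),
        }

    joined, association = _associate()

    # individual-level analyses --------------------------------------------
    @_stage("correlation_matrix")
    def _corr():
        rows = []
        for a in CORR_COLUMNS:
            row = {"variable": a}
            for b in CORR_COLUMNS:
                if a == b:
                    row[f"r_{b}"], row[f"p_{b}"] = 1.0, 0.0
                else:
                    row[f"r_{b}"], row[f"p_{b}"] = pearson_cor(
                        filtered[a], filtered[b])
            rows.append(row)
        return pd.DataFrame(rows)

    corr_matrix = _corr()

    @_stage("model_comparisons")
    def _comparisons():
        base = fit_ols(["sex_male*neutered"], filtered, "bcs_owner_9pt")
        with_fms = fit_ols(["sex_male*neutered", "fms"], filtered,
                           "bcs_owner_9pt")
        with_breed = fit_ols(["sex_male*neutered", "breed"], filtered,
                             "bcs_owner_9pt")
        bcs_cmp = compare_models(
            [base, with_fms, with_breed],
            names=["covariates_only", "covariates_plus_fms",
                   "covariates_plus_breed"])
        fm_base = fit_ols(["sex_male*neutered"], filtered, "fms")
        fm_breed = fit_ols(["sex_male*neutered", "breed"], filtered, "fms")
        fm_cmp = compare_models([fm_base, fm_breed],
                                names=["covariates_only", "covariates_plus_breed"])
        return bcs_cmp, fm_cmp

    bcs_cmp, fm_cmp = _comparisons()

    @_stage("tertile_analysis")
    def _tertiles():
        frame = filtered.copy()
        frame["fm_tertile"] = assign_tertiles(frame["fms"].to_numpy())
        effects = extract_tertile_effects(frame)
        model = fit_ols(
            [f"{m}*fm_tertile" for m in MANAGEMENT_TERMS]
            + ["sex_male*fm_tertile", "neutered*fm_tertile",
               "sex_male*neutered", "age_years"],
            frame, "bcs_owner_9pt", relevel={"fm_tertile": "low"})
        desc_vars = ["bcs_owner_9pt", "fms", "age_years", "ocs",
                     "owner_intervention", "restriction_human_food",
                     "exercise_taken"]
        desc_rows, pw_rows = [], []
        for var in desc_vars:
            for lv in ("low", "medium", "high"):
                vals = frame.loc[frame["fm_tertile"] == lv, var].dropna()
                desc_rows.append({"variable": var, "tertile": lv,
                                  "n": int(len(vals)),
                                  "mean": float(vals.mean()),
                                  "sd": float(vals.std())})
            pw = pairwise_t_holm({
                lv: frame.loc[frame["fm_tertile"] == lv, var].dropna().to_numpy()
                for lv in ("low", "medium", "high")})
            pw.insert(0, "variable", var)
            pw_rows.append(pw)
        return (frame, effects,
                {"r_squared": model.r_squared, "aic": model.aic, "n": model.n},
                pd.DataFrame(desc_rows), pd.concat(pw_rows, ignore_index=True))

    _, tertile_effects, tertile_model, tertile_desc, tertile_pw = _tertiles()

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": {"sim": config.sim.seed, "visit": config.visit_seed,
                  "ci": config.ci_seed},
        "row_counts": {
            "questionnaire_raw": int(len(raw_q)),
            "questionnaire_retained": int(filter_report.n_retained),
            "ehr_visits": int(len(raw_e)),
            "ehr_dogs": int(len(one_visit)),
            "breeds_joined": association["n_breeds"],
        },
    }

    report = AnalysisReport(
        scored_summary={
            "n_scored": int(len(scored)),
            "fms_mean": float(filtered["fms"].mean()),
            "fms_sd": float(filtered["fms"].std()),
            "ocs_mean": float(filtered["ocs"].mean()),
            "ocs_sd": float(filtered["ocs"].std()),
        },
        filter_report=filter_report,
        breed_fms_table=breed_fms,
        breed_anova={"f": f_stat, "p": f_p, "n_breeds": int(len(breed_fms))},
        breed_probability_table=breed_probs,
        breed_association=association,
        correlation_matrix=corr_matrix,
        bcs_model_comparison=bcs_cmp,
        fm_model_comparison=fm_cmp,
        tertile_effects=tertile_effects,
        tertile_model=tertile_model,
        tertile_descriptives=tertile_desc,
        tertile_pairwise=tertile_pw,
        manifest=manifest,
    )
    if config.output_dir is not None:
        report.write(config.output_dir)
    return report
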
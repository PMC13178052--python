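"""End-to-end orchestration: simulate → phenotype → estimate → cohorts →
train → evaluate → report.

Each stage consumes only files written by earlier stages (never in-process
state), writes its outputs plus a manifest entry (config hash and output
checksums), and is individually re-runnable. A single global seed
deterministically derives every stage seed, so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cohort as cohort_mod
from . import evaluation as eval_mod
from . import model as model_mod
from . import phenotyping as pheno_mod
from . import records
from . import underreporting as under_mod
from .synthetic import GeneratorConfig, generate_population

logger = logging.getLogger(__name__)

STAGES = ("simulate", "phenotype", "estimate", "cohorts", "train", "evaluate", "report")


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cohort_spec: cohort_mod.CohortSpec = field(default_factory=cohort_mod.CohortSpec)
    model_hyperparameters: dict = field(default_factory=lambda: {
        "depth": 4, "learning_rate": 0.1, "iterations": 200,
        "l2_leaf_reg": 3.0, "border_count": 32,
    })
    search: str = "none"  # none | two-stage
    search_budget_random: int = 5
    search_budget_bayes: int = 5
    cv_folds: int = 5
    threshold: float = 0.5
    ece_bins: int = 10
    trigger_logic: str = "and"
    washout_days: int = 365
    feature_years: tuple[int, int] = (2018, 2021)
    index_year: int = 2022
    #: mirror case index dates onto controls before the washout, so both
    #: groups lose the same amount of observation time (bias exploration)
    control_pseudo_index: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1009 + STAGES.index(stage) + 1) % (2**31)

    def to_json(self) -> str:
        def _enc(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))
        return json.dumps(dataclasses.asdict(self), default=_enc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        gen = GeneratorConfig(**{
            k: tuple(v) if k == "study_years" else v
            for k, v in raw.pop("generator", {}).items()
        })
        spec = cohort_mod.CohortSpec(**{
            k: tuple(v) if k == "validation_sizes" else v
            for k, v in raw.pop("cohort_spec", {}).items()
        })
        if "feature_years" in raw:
            raw["feature_years"] = tuple(raw["feature_years"])
        return cls(generator=gen, cohort_spec=spec, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _update_manifest(out: Path, stage: str, files: list[Path], config: PipelineConfig) -> None:
    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "stages": {},
    }
    manifest["stages"][stage] = {f.name: _sha256(f) for f in files}
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def stage_simulate(config: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    gen = dataclasses.replace(config.generator, seed=config.stage_seed("simulate"))
    events, deaths, demographics, latent = generate_population(gen)
    records.write_events(events, out / "events.csv")
    records.write_deaths(deaths, out / "deaths.csv")
    records.write_demographics(demographics, out / "demographics.csv")
    latent.to_csv(out / "latent.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(
        {"generator": dataclasses.asdict(gen)}, default=str, indent=2, sort_keys=True))
    _update_manifest(out, "simulate", [
        out / n for n in ("events.csv", "deaths.csv", "demographics.csv",
                          "latent.csv", "provenance.json")], config)


def stage_phenotype(config: PipelineConfig, out: Path) -> None:
    codesets = records.load_codesets()
    events = records.read_events(out / "events.csv")
    deaths = records.read_deaths(out / "deaths.csv")
    demographics = records.read_demographics(out / "demographics.csv")

    amb = pheno_mod.classify_ambulatory_table(
        events, codesets["ambulatory_trigger_icds"],
        codesets["ambulatory_trigger_procedures"],
        trigger_logic=config.trigger_logic)
    mort = pheno_mod.classify_death_table(deaths, codesets["mortality_set"])
    amb.to_csv(out / "ambulatory_phenotypes.csv", index=False)
    mort.assign(matched_codes=mort["matched_codes"].map(";".join)).to_csv(
        out / "mortality_phenotypes.csv", index=False)

    amb_summary = pheno_mod.summarize_by_year(amb, demographics)
    death_demo = deaths.rename(columns={
        "person_id": "patient_id", "age_at_death": "age"})[["patient_id", "age", "sex"]]
    mort_summary = pheno_mod.summarize_by_year(
        mort.rename(columns={"person_id": "patient_id"}), death_demo)
    amb_summary.to_csv(out / "ambulatory_summary.csv", index=False)
    mort_summary.to_csv(out / "mortality_summary.csv", index=False)
    _update_manifest(out, "phenotype", [
        out / n for n in ("ambulatory_phenotypes.csv", "mortality_phenotypes.csv",
                          "ambulatory_summary.csv", "mortality_summary.csv")], config)


def stage_estimate(config: PipelineConfig, out: Path, counts_path: Path | None = None) -> None:
    """Scenario grid; with ``counts_path`` the stage runs standalone on an
    external counts table (e.g. the shipped published tables)."""
    out.mkdir(parents=True, exist_ok=True)
    if counts_path is not None:
        table = under_mod.load_paper_tables(counts_path)
        counts = under_mod.counts_from_table(table)
    else:
        counts = []
        for name, stream, label_diag, label_pot in [
            ("ambulatory_summary.csv", "AMBULATORY",
             pheno_mod.DIAGNOSED_HF, pheno_mod.POTENTIAL_HF),
            ("mortality_summary.csv", "MORTALITY",
             pheno_mod.HF_DEATH, pheno_mod.POTENTIAL_HF_DEATH),
        ]:
            summary = pd.read_csv(out / name)
            for year, grp in summary.groupby("year"):
                d = int(grp.loc[grp["label"] == label_diag, "n"].sum())
                p = int(grp.loc[grp["label"] == label_pot, "n"].sum())
                if d == 0:
                    # U(p) is undefined at p=0 with no diagnosed records
                    logger.warning("skipping %s %s: zero diagnosed records", stream, year)
                    continue
                counts.append(under_mod.YearlyCounts(int(year), d, p, stream))
    grid = under_mod.scenario_grid(counts)
    grid.to_csv(out / "scenarios.csv", index=False)
    _update_manifest(out, "estimate", [out / "scenarios.csv"], config)


def stage_cohorts(config: PipelineConfig, out: Path) -> None:
    events = records.read_events(out / "events.csv")
    demographics = records.read_demographics(out / "demographics.csv")
    amb = pd.read_csv(out / "ambulatory_phenotypes.csv",
                      parse_dates=["first_i50_date"])

    retained = cohort_mod.completeness_filter(demographics)
    demographics = demographics[demographics["patient_id"].isin(retained)]

    cases = amb[(amb["label"] == pheno_mod.DIAGNOSED_HF)
                & (amb["first_i50_date"].dt.year == config.index_year)]
    case_ids = set(cases["patient_id"]) & set(retained)
    # controls: never any I50 code in the extraction window
    control_ids = set(amb.loc[amb["label"] != pheno_mod.DIAGNOSED_HF, "patient_id"])
    control_ids &= set(retained)

    first_i50 = dict(zip(cases["patient_id"], cases["first_i50_date"]))
    eligible = case_ids | control_ids
    if config.control_pseudo_index:
        first_i50.update(cohort_mod.assign_pseudo_index(
            sorted(control_ids), list(first_i50.values()),
            seed=config.stage_seed("cohorts")))
    windowed = cohort_mod.apply_washout(
        events[events["patient_id"].isin(eligible)], first_i50,
        washout_days=config.washout_days, feature_years=config.feature_years)
    cohort_mod.assert_no_leakage(windowed, first_i50,
                                 washout_days=config.washout_days,
                                 forbidden_year=config.index_year)
    features = cohort_mod.build_features(
        windowed, demographics[demographics["patient_id"].isin(eligible)], case_ids)
    features = cohort_mod.plausibility_filter(features)
    features.to_csv(out / "features.csv", index=False)

    spec = dataclasses.replace(config.cohort_spec, seed=config.stage_seed("cohorts"))
    cohorts = cohort_mod.assemble_cohorts(features, spec)
    (out / "cohorts.json").write_text(json.dumps(
        {k: sorted(v.tolist()) for k, v in cohorts.items()}, indent=2))
    _update_manifest(out, "cohorts", [out / "features.csv", out / "cohorts.json"], config)


def stage_train(config: PipelineConfig, out: Path) -> dict:
    features = pd.read_csv(out / "features.csv")
    cohorts = json.loads((out / "cohorts.json").read_text())
    train_ids = set(cohorts["development_train"])
    train = features[features["patient_id"].isin(train_ids)].reset_index(drop=True)
    y = (train["label"] == cohort_mod.HF).astype(int).to_numpy()

    seed = config.stage_seed("train")
    if config.search == "two-stage":
        spec, trace = model_mod.two_stage_search(
            train, y, budget_random=config.search_budget_random,
            budget_bayes=config.search_budget_bayes, seed=seed, k=config.cv_folds)
        trace.to_csv(out / "search_trace.csv", index=False)
    else:
        spec = model_mod.ModelSpec(
            model_mod.GRADIENT_BOOSTING, dict(config.model_hyperparameters), seed=seed)
    metrics, fitted = model_mod.crossval_train(
        train, y, spec, k=config.cv_folds, seed=seed)
    metrics.to_csv(out / "cv_metrics.csv", index=False)
    baseline = model_mod.fit_logistic_baseline(train, y, seed=seed)
    (out / "model_spec.json").write_text(json.dumps(
        {"family": spec.family, "hyperparameters": dict(spec.hyperparameters),
         "seed": spec.seed}, indent=2, sort_keys=True))
    _update_manifest(out, "train", [out / "cv_metrics.csv", out / "model_spec.json"], config)
    return {"boosting": fitted, "logistic": baseline}


def stage_evaluate(config: PipelineConfig, out: Path, models: dict) -> None:
    features = pd.read_csv(out / "features.csv")
    cohorts = json.loads((out / "cohorts.json").read_text())
    report: dict = {"threshold": config.threshold, "ece_bins": config.ece_bins,
                    "binning_scheme": "equal_width", "cohorts": {}}
    for cohort_name in ("development_test", "validation_1", "validation_2", "low_prevalence"):
        if cohort_name not in cohorts:
            continue
        ids = set(cohorts[cohort_name])
        sub = features[features["patient_id"].isin(ids)].reset_index(drop=True)
        y = (sub["label"] == cohort_mod.HF).astype(int).to_numpy()
        entry = {}
        for model_name, fitted in models.items():
            scores = model_mod.predict_proba(fitted, sub)
            disc = eval_mod.confusion_and_rates(scores, y, threshold=config.threshold)
            cal = eval_mod.calibration_report(scores, y, n_bins=config.ece_bins)
            entry[model_name] = {
                "discrimination": dataclasses.asdict(disc),
                "calibration": dataclasses.asdict(cal),
            }
        report["cohorts"][cohort_name] = entry

    # concordance of the proxy's potential-HF patients with the model
    amb = pd.read_csv(out / "ambulatory_phenotypes.csv")
    potential_ids = set(amb.loc[amb["label"] == pheno_mod.POTENTIAL_HF, "patient_id"])
    scored = features[features["patient_id"].isin(potential_ids)].reset_index(drop=True)
    if len(scored):
        scores = model_mod.predict_proba(models["boosting"], scored)
        model_pos = set(scored.loc[scores >= config.threshold, "patient_id"])
        overlap, pct = pheno_mod.proxy_model_concordance(
            set(scored["patient_id"]), model_pos)
        report["proxy_model_concordance"] = {
            "proxy_n": len(scored), "overlap": overlap, "percent": pct}
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _update_manifest(out, "evaluate", [out / "report.json"], config)


def make_report(out: Path) -> str:
    """Human-readable markdown summary of whatever stage outputs exist;
    missing stages leave explicit gaps."""
    out = Path(out)
    produced = [p for p in (out / "ambulatory_summary.csv", out / "scenarios.csv",
                            out / "report.json") if p.exists()]
    if not produced:
        raise FileNotFoundError(f"no stage outputs found under {out}")
    lines = ["# hfgap pipeline report", ""]
    for name, title in [("ambulatory_summary.csv", "Ambulatory phenotypes by year"),
                        ("mortality_summary.csv", "Mortality phenotypes by year")]:
        path = out / name
        lines.append(f"## {title}")
        if path.exists():
            lines.append(pd.read_csv(path).to_markdown(index=False))
        else:
            lines.append("_stage output missing_")
        lines.append("")
    lines.append("## Underestimation scenario grid")
    if (out / "scenarios.csv").exists():
        grid = pd.read_csv(out / "scenarios.csv")
        lines.append(grid[grid["p"].isin([0.2, 0.4, 0.6, 0.8, 1.0])]
                     .to_markdown(index=False))
    else:
        lines.append("_stage output missing_")
    lines.append("")
    lines.append("## Model evaluation")
    if (out / "report.json").exists():
        report = json.loads((out / "report.json").read_text())
        for cohort_name, entry in report.get("cohorts", {}).items():
            for model_name, metrics in entry.items():
                d = metrics["discrimination"]
                c = metrics["calibration"]
                lines.append(
                    f"- {cohort_name} / {model_name}: AUC {d['auc']:.3f}, "
                    f"accuracy {d['accuracy']:.3f}, recall {d['recall']:.3f}, "
                    f"Brier {c['brier']:.3f}, ECE {c['ece']:.3f}, "
                    f"slope {c['slope']:.2f}, intercept {c['intercept']:.2f}")
        if "proxy_model_concordance" in report:
            pc = report["proxy_model_concordance"]
            lines.append(f"- proxy/model concordance: {pc['overlap']} of "
                         f"{pc['proxy_n']} ({pc['percent']}%)")
    else:
        lines.append("_stage output missing_")
    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    return text


def run_pipeline(config: PipelineConfig, out: str | Path) -> Path:
    """Run every stage into ``out``; halts on the first failing stage with
    its name in the error context."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    models = None
    for stage in STAGES:
        logger.info("stage %s", stage)
        try:
            if stage == "simulate":
                stage_simulate(config, out)
            elif stage == "phenotype":
                stage_phenotype(config, out)
            elif stage == "estimate":
                stage_estimate(config, out)
            elif stage == "cohorts":
                stage_cohorts(config, out)
            elif stage == "train":
                models = stage_train(config, out)
            elif stage == "evaluate":
                stage_evaluate(config, out, models)
            elif stage == "report":
                make_report(out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
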
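"""End-to-end orchestration: preprocess -> sweep -> gate -> ensemble -> stats.

:class:`RunConfig` is the single configuration object: it points either at
expression/phenotype files on disk or at a synthetic cohort configuration,
restricts the method registry, and carries the gate threshold, BMA weight
offset and seeds. Every run writes its artifacts plus a manifest recording
the configuration hash and seeds, so a run is reproducible from the manifest
alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as etio
from .cohort import CohortConfig, SyntheticCohort, generate_cohort
from .data import ContingencyTable2x2, ExpressionMatrix, labels_from_phenotype
from .ensemble import build_ensemble, score_table, stratify_by_group_mean
from .harness import SweepConfig, gate_models, permutation_null, run_training_sweep
from .preprocess import preprocess_pipeline
from .routes import MethodRegistry, default_registry, enumerate_specs
from . import stats as etstats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    expression_path: str | None = None
    detection_path: str | None = None
    phenotype_path: str | None = None
    synthetic: CohortConfig | None = None
    filtration: list | None = None
    selection: list | None = None
    reduction: list | None = None
    classifiers: list | None = None
    gate_threshold: float = 0.80
    weight_offset: float = 0.70
    squared_weights: bool = False
    n_iterations: int = 5
    holdout_frac: float = 0.2
    permute: bool = False
    permutation_reps: int = 5
    seed: int = 0
    outdir: str = "ensembletx_run"

    def validate(self) -> "RunConfig":
        has_paths = self.expression_path is not None and self.phenotype_path is not None
        has_synth = self.synthetic is not None
        if has_paths == has_synth:
            raise ValueError("exactly one of (input paths, synthetic config) must be set")
        if self.gate_threshold <= self.weight_offset:
            raise ValueError("gate_threshold must exceed weight_offset")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synthetic", None)
        # YAML 1.1 reads a bare `no` as boolean False; the method id is meant
        for axis in ("filtration", "selection", "reduction", "classifiers"):
            if raw.get(axis):
                raw[axis] = ["no" if v is False else v for v in raw[axis]]
        config = cls(**raw)
        if synth is not None:
            config.synthetic = CohortConfig(**synth)
        return config.validate()

    def to_mapping(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def registry_from_config(config: RunConfig) -> MethodRegistry:
    return default_registry().subset(
        filtration=config.filtration, selection=config.selection,
        reduction=config.reduction, classifiers=config.classifiers)


def load_inputs(config: RunConfig) -> tuple[ExpressionMatrix, pd.DataFrame, dict | None]:
    if config.synthetic is not None:
        cohort = generate_cohort(config.synthetic)
        return cohort.expression, cohort.phenotype, cohort.truth
    em = etio.read_expression(config.expression_path, config.detection_path)
    phenotype = etio.read_phenotype(config.phenotype_path)
    missing = set(em.sample_ids) - set(phenotype["sample_id"])
    if missing:
        raise ValueError(f"expression samples absent from phenotype: {sorted(missing)[:5]}")
    return em, phenotype, None


@dataclass
class PipelineResult:
    gene_matrix: pd.DataFrame  # genes x samples, log2, preprocessed
    phenotype: pd.DataFrame
    sweep: list
    gate_report: object
    ensemble: object | None
    scores: pd.DataFrame | None
    strata: pd.DataFrame | None
    stats_tables: dict = field(default_factory=dict)
    null_distribution: dict | None = None
    artifacts: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    em, phenotype, truth = load_inputs(config)
    processed, filter_report = preprocess_pipeline(em)
    logger.info("preprocess: %s", str(filter_report).replace("\n", " | "))

    matrix = processed.values  # genes x samples
    gene_names = matrix.index.to_numpy()
    train_ids = phenotype.loc[phenotype["split"] == "train", "sample_id"].to_numpy()
    test_ids = phenotype.loc[phenotype["split"] == "test", "sample_id"].to_numpy()
    x_train = matrix[train_ids].to_numpy().T
    x_test = matrix[test_ids].to_numpy().T
    y_train = labels_from_phenotype(phenotype, train_ids)
    y_test = labels_from_phenotype(phenotype, test_ids)

    registry = registry_from_config(config)
    specs = enumerate_specs(registry)
    logger.info("sweeping %d specs on %d training samples x %d genes",
                len(specs), len(train_ids), len(gene_names))
    sweep_config = SweepConfig(n_iterations=config.n_iterations,
                               holdout_frac=config.holdout_frac, seed=config.seed)
    results = run_training_sweep(specs, x_train, y_train, sweep_config,
                                 registry=registry, feature_names=gene_names)
    gated, gate_report = gate_models(
        results, x_train, y_train, x_test, y_test,
        threshold=config.gate_threshold, registry=registry, seed=config.seed,
        train_ids=train_ids, test_ids=test_ids, feature_names=gene_names)
    logger.info("gate: %s", gate_report)

    ensemble_model = None
    scores_frame = None
    stats_tables: dict = {}
    if gated:
        ensemble_model = build_ensemble(gated, x_train,
                                        weight_offset=config.weight_offset,
                                        squared_weights=config.squared_weights)
        all_ids = np.concatenate([train_ids, test_ids])
        x_all = np.vstack([x_train, x_test])
        raw = ensemble_model.raw_predict(x_all)
        rescaled = ensemble_model.predict(x_all)
        dx = phenotype.set_index("sample_id").loc[all_ids, "diagnosis"].to_numpy()
        strata, asd_mean = stratify_by_group_mean(rescaled, dx)
        scores_frame = score_table(all_ids, dx, raw, rescaled, strata)
        scores_frame["split"] = np.concatenate(
            [np.repeat("train", len(train_ids)), np.repeat("test", len(test_ids))])
        stats_tables = downstream_stats(matrix, phenotype, scores_frame, asd_mean)

    null = None
    if config.permute:
        null = permutation_null(x_train, y_train, specs,
                                n_reps=config.permutation_reps,
                                seed=config.seed, registry=registry,
                                feature_names=gene_names)

    artifacts = _write_artifacts(config, outdir, results, gate_report,
                                 scores_frame, stats_tables, null, truth,
                                 ensemble_model)
    return PipelineResult(gene_matrix=matrix, phenotype=phenotype, sweep=results,
                          gate_report=gate_report, ensemble=ensemble_model,
                          scores=scores_frame, strata=scores_frame,
                          stats_tables=stats_tables, null_distribution=null,
                          artifacts=artifacts)


def downstream_stats(gene_matrix: pd.DataFrame, phenotype: pd.DataFrame,
                     scores: pd.DataFrame, asd_mean: float) -> dict:
    """Every defined post-classification statistic, as tidy tables."""
    tables: dict = {}
    pheno = phenotype.set_index("sample_id")
    merged = scores.set_index("sample_id").join(
        pheno[["age_months", "race", "ethnicity", "mutation_carrier",
               "severe_prenatal_event"]])

    # DE: below-mean ASD vs all TD (train split), when both arms are populated
    below_ids = merged.index[(merged["stratum"] == "below") & (merged["split"] == "train")]
    td_ids = merged.index[(merged["diagnosis"] == "TD") & (merged["split"] == "train")]
    if len(below_ids) >= 2 and len(td_ids) >= 2:
        tables["de_below_vs_td"] = etstats.moderated_t_de(
            gene_matrix[list(below_ids)], gene_matrix[list(td_ids)])

    # prenatal-event contingency: strata vs TD
    tables["prenatal"] = prenatal_event_tests(merged)

    # ensemble score by mutation carrier status, within each diagnosis
    rows = []
    for dx in ("ASD", "TD"):
        sub = merged[merged["diagnosis"] == dx]
        carriers = sub.loc[sub["mutation_carrier"], "rescaled_score"]
        others = sub.loc[~sub["mutation_carrier"], "rescaled_score"]
        if len(carriers) >= 2 and len(others) >= 2:
            t, df, p = etstats.welch_t(carriers, others)
            rows.append({"diagnosis": dx, "n_carriers": len(carriers),
                         "n_noncarriers": len(others), "t": t, "df": df, "p_value": p})
    tables["mutation_welch"] = pd.DataFrame(rows)

    # age-bin Games-Howell across diagnosis x age-bin cells
    merged["age_bin"] = etstats.assign_age_bins(merged["age_months"])
    cells = {}
    for (dx, age_bin), sub in merged.groupby(["diagnosis", "age_bin"], observed=True):
        if len(sub) >= 2:
            cells[f"{dx}:{age_bin}"] = sub["rescaled_score"].to_numpy()
    if len(cells) >= 2:
        tables["age_games_howell"] = etstats.games_howell(cells)

    # one-way ANOVA across ethnicity and race, per diagnosis
    rows = []
    for dx in ("ASD", "TD"):
        sub = merged[merged["diagnosis"] == dx]
        for factor in ("ethnicity", "race"):
            groups = [g["rescaled_score"].to_numpy()
                      for _, g in sub.groupby(factor) if len(g) >= 2]
            if len(groups) >= 2:
                f, df1, df2, p = etstats.oneway_anova(groups)
                rows.append({"diagnosis": dx, "factor": factor, "F": f,
                             "df1": df1, "df2": df2, "p_value": p})
    tables["ethnicity_race_anova"] = pd.DataFrame(rows)

    # score ~ group * age regression
    tables["group_age_regression"] = etstats.group_age_regression(
        merged["rescaled_score"], merged["diagnosis"], merged["age_months"])

    # mutation presence/absence classifier
    asd = merged[merged["diagnosis"] == "ASD"]
    td = merged[merged["diagnosis"] == "TD"]
    accuracy, precision, recall, counts = etstats.mutation_classifier_metrics(
        int(asd["mutation_carrier"].sum()), len(asd),
        int(td["mutation_carrier"].sum()), len(td))
    tables["mutation_classifier"] = pd.DataFrame([{
        "accuracy": accuracy, "precision": precision, "recall": recall,
        "tp": counts.tp, "fn": counts.fn, "fp": counts.fp, "tn": counts.tn}])
    return tables


def prenatal_event_tests(merged: pd.DataFrame) -> pd.DataFrame:
    """Fisher exact + CMLE odds ratio of severe prenatal events between the
    ensemble strata, oriented (focal group, reference group)."""
    def counts(mask):
        sub = merged[mask]
        event = int(sub["severe_prenatal_event"].sum())
        return event, len(sub) - event

    below = counts(merged["stratum"] == "below")
    above = counts(merged["stratum"] == "above")
    td = counts(merged["stratum"] == "TD")
    rows = []
    for name, focal, ref in [("below_vs_td", below, td),
                             ("above_vs_td", above, td),
                             ("below_vs_above", below, above)]:
        if sum(focal) == 0 or sum(ref) == 0:
            continue
        res = etstats.fisher_exact_2x2(ContingencyTable2x2(*focal, *ref))
        rows.append({"comparison": name, "odds_ratio": res.odds_ratio,
                     "p_value": res.p_value,
                     "focal_event": focal[0], "focal_none": focal[1],
                     "ref_event": ref[0], "ref_none": ref[1]})
    return pd.DataFrame(rows)


def _write_artifacts(config, outdir: Path, results, gate_report, scores,
                     stats_tables, null, truth, ensemble_model=None) -> dict:
    artifacts = {}
    etio.write_sweep(results, outdir / "sweep.tsv")
    artifacts["sweep"] = outdir / "sweep.tsv"
    with open(outdir / "gate_report.txt", "w") as fh:
        fh.write(f"{gate_report}\n")
    artifacts["gate_report"] = outdir / "gate_report.txt"
    if scores is not None:
        scores.to_csv(outdir / "ensemble_scores.tsv", sep="\t", index=False)
        artifacts["scores"] = outdir / "ensemble_scores.tsv"
    if ensemble_model is not None:
        ensemble_model.save(outdir / "ensemble.bundle")
        artifacts["ensemble"] = outdir / "ensemble.bundle"
    for name, table in stats_tables.items():
        path = outdir / f"stats_{name}.tsv"
        table.to_csv(path, sep="\t")
        artifacts[f"stats_{name}"] = path
    if null is not None:
        pd.DataFrame({"auc_roc": null["auc_roc"], "auc_pr": null["auc_pr"]}).to_csv(
            outdir / "permutation_null.tsv", sep="\t", index=False)
        artifacts["permutation_null"] = outdir / "permutation_null.tsv"
    if truth is not None:
        etio.write_truth(truth, outdir / "truth.json")
        artifacts["truth"] = outdir / "truth.json"
    etio.write_manifest(outdir / "manifest.json", config.to_mapping(),
                        {"seed": config.seed}, artifacts)
    artifacts["manifest"] = outdir / "manifest.json"
    return artifacts
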
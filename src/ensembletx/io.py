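"""Tab-delimited readers/writers binding the pipeline stages together.

Dialects: the expression matrix is written rows = probes, columns = samples,
with leading ``probe_id`` and ``gene_id`` columns; detection p-values go to a
parallel matrix; the phenotype table, sweep results and score tables are
plain TSV; the cohort truth record and the run manifest are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SyntheticCohort
from .data import ExpressionMatrix, validate_phenotype
from .harness import ModelResult
from .routes import ModelSpec


def write_expression(em: ExpressionMatrix, values_path, detection_path=None) -> None:
    frame = em.values.copy()
    frame.insert(0, "gene_id", em.gene_ids.to_numpy())
    frame.index.name = "probe_id"
    frame.to_csv(values_path, sep="\t")
    if detection_path is not None and em.detection_p is not None:
        det = em.detection_p.copy()
        det.insert(0, "gene_id", em.gene_ids.to_numpy())
        det.index.name = "probe_id"
        det.to_csv(detection_path, sep="\t")


def read_expression(values_path, detection_path=None) -> ExpressionMatrix:
    frame = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    gene_ids = frame.pop("gene_id")
    detection = None
    if detection_path is not None and Path(detection_path).exists():
        det = pd.read_csv(detection_path, sep="\t", index_col="probe_id")
        det = det.drop(columns=["gene_id"])
        detection = det
    return ExpressionMatrix(values=frame, gene_ids=gene_ids, detection_p=detection)


def write_phenotype(phenotype: pd.DataFrame, path) -> None:
    phenotype.to_csv(path, sep="\t", index=False)


def read_phenotype(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in ("mutation_carrier", "severe_prenatal_event", "control_prenatal_event"):
        if col in table.columns:
            table[col] = table[col].astype(bool)
    return validate_phenotype(table)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=float)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "detection": outdir / "detection_p.tsv",
        "phenotype": outdir / "phenotype.tsv",
        "truth": outdir / "truth.json",
    }
    write_expression(cohort.expression, paths["expression"], paths["detection"])
    write_phenotype(cohort.phenotype, paths["phenotype"])
    write_truth(cohort.truth, paths["truth"])
    return paths


def sweep_to_frame(results: list[ModelResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "filtration_id": r.spec.filtration_id,
            "selection_id": r.spec.selection_id,
            "reduction_id": r.spec.reduction_id,
            "classifier_id": r.spec.classifier_id,
            "feasible": r.feasible,
            "mean_auc_roc": r.mean_auc_roc,
            "mean_auc_pr": r.mean_auc_pr,
            "per_fold_auc_roc": ";".join(f"{v:.6f}" for v in r.per_fold_auc_roc),
            "per_fold_auc_pr": ";".join(f"{v:.6f}" for v in r.per_fold_auc_pr),
            "test_auc_roc": r.test_auc_roc,
            "test_auc_pr": r.test_auc_pr,
        })
    return pd.DataFrame(rows)


def write_sweep(results: list[ModelResult], path) -> None:
    sweep_to_frame(results).to_csv(path, sep="\t", index=False)


def read_sweep(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def spec_from_row(row) -> ModelSpec:
    return ModelSpec(row["filtration_id"], row["selection_id"],
                     row["reduction_id"], row["classifier_id"])


def config_hash(config_mapping: dict) -> str:
    blob = json.dumps(config_mapping, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, config_mapping: dict, seeds: dict, artifacts: dict) -> None:
    manifest = {
        "config": config_mapping,
        "config_hash": config_hash(config_mapping),
        "seeds": seeds,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
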
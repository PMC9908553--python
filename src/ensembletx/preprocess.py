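"""Probe filtering, quantile normalization, and probe-to-gene collapse.

The entry point is tabular probe intensities with detection p-values. The
stages run in a fixed order: the three-step expression filter on raw
intensities, quantile normalization across samples, collapse of multi-probe
genes to the probe with the highest mean, and finally a log2 transform for
modeling (standard for array intensity data and required for log-fold-change
semantics downstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionMatrix


class NoNegativeProbesError(ValueError):
    """Raised when the negative-probe pool is empty.

    The 95th-percentile background threshold cannot be estimated; the caller
    must supply ``negative_threshold`` explicitly.
    """


@dataclass
class FilterReport:
    n_input_probes: int
    n_after_step1: int
    n_after_step2: int
    n_genes_output: int
    negative_probe_count: int
    negative_95th_percentile: float

    def __str__(self) -> str:
        return (
            "probe filter report\n"
            f"  input probes:            {self.n_input_probes}\n"
            f"  after detection filter:  {self.n_after_step1}\n"
            f"  after background filter: {self.n_after_step2}\n"
            f"  genes represented:       {self.n_genes_output}\n"
            f"  negative probes:         {self.negative_probe_count}\n"
            f"  background threshold:    {self.negative_95th_percentile:.4f}\n"
        )


def filter_probes(
    em: ExpressionMatrix,
    detection_threshold: float = 0.05,
    min_detected_samples: int = 3,
    negative_detection_floor: float = 0.1,
    background_percentile: float = 95.0,
    min_above_background_frac: float = 0.5,
    negative_threshold: float | None = None,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Two-step reliable-expression probe filter.

    Step 1 keeps probes detected (p < 0.05) in at least 3 samples. Step 2
    pools the intensities of negative probes — those with detection p > 0.1
    in every sample — takes their 95th percentile (linear interpolation
    between order statistics), and keeps probes whose intensity exceeds that
    threshold in at least 50% of samples.

    Pass ``negative_threshold`` to skip the pooling and reuse a previously
    estimated background level (needed e.g. to re-apply the filter to a
    matrix whose negative probes were already removed).
    """
    if em.detection_p is None:
        raise ValueError("filter_probes requires detection p-values")
    values = em.values.to_numpy()
    det = em.detection_p.to_numpy()

    step1_keep = (det < detection_threshold).sum(axis=1) >= min_detected_samples

    negative = (det > negative_detection_floor).all(axis=1)
    if negative_threshold is None:
        if not negative.any():
            raise NoNegativeProbesError(
                "no probes have detection p > "
                f"{negative_detection_floor} in every sample; supply "
                "negative_threshold explicitly")
        negative_threshold = float(
            np.percentile(values[negative].ravel(), background_percentile))

    frac_above = (values > negative_threshold).mean(axis=1)
    step2_keep = step1_keep & (frac_above >= min_above_background_frac)

    out = em.subset_probes(em.probe_ids[step2_keep])
    out.detection_p = em.detection_p.loc[out.probe_ids]
    report = FilterReport(
        n_input_probes=em.n_probes,
        n_after_step1=int(step1_keep.sum()),
        n_after_step2=int(step2_keep.sum()),
        n_genes_output=int(out.gene_ids.nunique()),
        negative_probe_count=int(negative.sum()),
        negative_95th_percentile=negative_threshold,
    )
    return out, report


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean empirical distribution.

    After normalization every column's sorted values equal the across-column
    mean of order statistics; within-column rank order is preserved. Ties
    within a column receive the mean of the reference values at their tied
    ranks.
    """
    if values.isna().any().any():
        raise ValueError("quantile_normalize requires a complete matrix")
    if values.shape[1] < 2:
        warnings.warn("single sample: quantile normalization is the identity")
        return values.copy()

    x = values.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    reference = sorted_x.mean(axis=1)

    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        col_sorted = sorted_x[:, j]
        assigned = reference.copy()
        # average the reference over each run of tied values
        start = 0
        for i in range(1, n + 1):
            if i == n or col_sorted[i] != col_sorted[start]:
                if i - start > 1:
                    assigned[start:i] = reference[start:i].mean()
                start = i
        out[order[:, j], j] = assigned
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def collapse_to_genes(em: ExpressionMatrix) -> ExpressionMatrix:
    """One row per gene: the probe with the highest mean across samples.

    Ties break toward the lexicographically smaller probe id. Genes with no
    surviving probes are simply absent. Input is expected to be
    quantile-normalized already.
    """
    means = em.values.mean(axis=1)
    frame = pd.DataFrame({
        "gene": em.gene_ids.to_numpy(),
        "mean": means.to_numpy(),
        "probe": em.probe_ids.to_numpy(),
    })
    # sort so the best probe per gene is first: mean desc, probe id asc
    frame = frame.sort_values(["mean", "probe"], ascending=[False, True], kind="stable")
    best = frame.drop_duplicates("gene", keep="first").sort_values("gene")
    probes = pd.Index(best["probe"])
    out_values = em.values.loc[probes]
    out_values.index = pd.Index(best["gene"].to_numpy(), name="gene_id")
    gene_ids = pd.Series(out_values.index, index=out_values.index, name="gene_id")
    return ExpressionMatrix(values=out_values, gene_ids=gene_ids, detection_p=None)


def log2_transform(values: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount); intensities are non-negative linear scale."""
    if (values.to_numpy() < 0).any():
        raise ValueError("negative intensities; matrix may already be log scale")
    return np.log2(values + pseudocount)


def preprocess_pipeline(
    em: ExpressionMatrix,
    negative_threshold: float | None = None,
) -> tuple[ExpressionMatrix, FilterReport]:
    """filter -> quantile normalize -> collapse -> log2."""
    filtered, report = filter_probes(em, negative_threshold=negative_threshold)
    normalized = quantile_normalize(filtered.values)
    collapsed = collapse_to_genes(
        ExpressionMatrix(values=normalized, gene_ids=filtered.gene_ids))
    logged = log2_transform(collapsed.values)
    out = ExpressionMatrix(values=logged, gene_ids=collapsed.gene_ids)
    return out, report
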